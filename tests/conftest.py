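import numpy as np
import pytest

from whorfnet.architecture import SynapseMap, Network, default_connectivity_graph, sample_synapses
from whorfnet.params import SimulationParams


@pytest.fixture(scope="session")
def params() -> SimulationParams:
    return SimulationParams()


@pytest.fixture(scope="session")
def network(params) -> Network:
    """One full sampled 12-area network (no training)."""
    return sample_synapses(default_connectivity_graph(), params, seed=7)


def make_tiny_network(
    n_e: int,
    ee: list[tuple[int, int, float]],
    ei: list[tuple[int, int, float]] = (),
    ie: list[tuple[int, int, float]] = (),
    params: SimulationParams | None = None,
) -> Network:
    """A hand-wired micro-network (single area) for oracle comparisons."""
    params = params or SimulationParams()

    def build(links):
        if links:
            pre, post, w = zip(*links)
        else:
            pre, post, w = (), (), ()
        return SynapseMap.from_coo(
            np.array(pre, dtype=np.int64), np.array(post, dtype=np.int64),
            np.array(w, dtype=np.float64), n_e, n_e,
        )

    return Network(
        params=params,
        graph=default_connectivity_graph(),
        seed=0,
        ee=build(list(ee)),
        ei=build(list(ei)),
        ie=build(list(ie)),
    )
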