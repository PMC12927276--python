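"""Checkpointing, manifests and result export.

Network snapshots go to HDF5 (weights, graph, seed, params hash); analysis
tables to tidy CSV; every run directory carries an append-only JSON manifest
tying outputs to the configuration and seeds that produced them.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .architecture import ConnectivityGraph, Network, SynapseMap
from .params import SimulationParams, load_params

__all__ = ["save_network", "load_network", "RunManifest"]


def save_network(network: Network, path: str | Path) -> None:
    """Serialize weights, macro graph, seed and parameters to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["seed"] = network.seed
        f.attrs["params_hash"] = network.params.params_hash()
        f.attrs["params_json"] = json.dumps(network.params.to_dict())
        f.attrs["edges"] = json.dumps(sorted(sorted(e) for e in network.graph.edges))
        for name in ("ee", "ei", "ie"):
            m: SynapseMap = getattr(network, name)
            g = f.create_group(name)
            g.create_dataset("indptr", data=m.indptr)
            g.create_dataset("post", data=m.post)
            g.create_dataset("w", data=m.w)
            g.attrs["n_pre"] = m.n_pre
            g.attrs["n_post"] = m.n_post


def load_network(path: str | Path) -> Network:
    with h5py.File(path, "r") as f:
        params = load_params(json.loads(f.attrs["params_json"]))
        graph = ConnectivityGraph.from_pairs(json.loads(f.attrs["edges"]))
        maps = {}
        for name in ("ee", "ei", "ie"):
            g = f[name]
            maps[name] = SynapseMap(
                indptr=g["indptr"][:].astype(np.int64),
                post=g["post"][:].astype(np.int64),
                w=g["w"][:].astype(np.float64),
                n_pre=int(g.attrs["n_pre"]),
                n_post=int(g.attrs["n_post"]),
            )
        return Network(params=params, graph=graph, seed=int(f.attrs["seed"]), **maps)


@dataclass
class RunManifest:
    """Append-only provenance record for one run directory."""

    path: Path
    entries: list[dict] = field(default_factory=list)

    @classmethod
    def open(cls, directory: str | Path) -> "RunManifest":
        p = Path(directory) / "manifest.json"
        entries = json.loads(p.read_text()) if p.exists() else []
        return cls(path=p, entries=entries)

    def record(self, stage: str, **info) -> None:
        self.entries.append({"stage": stage, "time": time.time(), **info})
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self.path.write_text(json.dumps(self.entries, indent=1))
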