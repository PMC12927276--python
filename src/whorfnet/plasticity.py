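"""Discretized Hebbian LTP/LTD rule for plastic e-to-e synapses.

The continuous range of efficacy changes is discretized into +Delta and
-Delta. Given presynaptic cell i and postsynaptic cell j:

* LTP (+Delta):                ``omega_E(i) >= theta_pre`` and ``V(j) >= theta_plus``
* homosynaptic LTD (-Delta):   ``omega_E(i) >= theta_pre`` and ``theta_minus <= V(j) < theta_plus``
* heterosynaptic LTD (-Delta): ``omega_E(i) < theta_pre`` and ``V(j) >= theta_plus``
* otherwise unchanged.

Weights are clipped to [0, w_max]. The full-network application runs inside
the simulation kernel once per timestep after the trace updates (during both
stimulation and the inter-stimulus interval of learning trials); extraction
and recognition runs freeze all weights.
"""

from __future__ import annotations

import numpy as np

from . import _engine
from .architecture import Network
from .dynamics import DynamicState
from .params import SimulationParams

__all__ = ["hebbian_update", "rule_branch", "apply_plasticity"]


def rule_branch(pre_rate: float, post_potential: float, params: SimulationParams) -> str:
    """Which branch of the rule fires for one (pre, post) value pair."""
    pre_active = pre_rate >= params.theta_pre
    if pre_active and post_potential >= params.theta_plus:
        return "LTP"
    if pre_active and params.theta_minus <= post_potential < params.theta_plus:
        return "homosynaptic-LTD"
    if not pre_active and post_potential >= params.theta_plus:
        return "heterosynaptic-LTD"
    return "none"


def hebbian_update(
    pre_rate: float, post_potential: float, weight: float, params: SimulationParams
) -> float:
    """New weight of a single plastic synapse under the rule above."""
    branch = rule_branch(pre_rate, post_potential, params)
    if branch == "LTP":
        weight += params.delta_w
    elif branch != "none":
        weight -= params.delta_w
    return float(min(max(weight, 0.0), params.w_max))


def apply_plasticity(network: Network, state: DynamicState, params: SimulationParams) -> Network:
    """Update every plastic e-to-e synapse of ``network`` in place.

    Uses the current rate estimates ``omega_E`` (presynaptic side) and
    membrane potentials ``V`` (postsynaptic side) of ``state``; non-plastic
    synapse classes are untouched.
    """
    pre_act = state.omega_rate >= params.theta_pre
    ltp = state.V_e >= params.theta_plus
    homo = (state.V_e >= params.theta_minus) & (state.V_e < params.theta_plus)
    eer_indptr, eer_pre, eer_pos = network.ee.to_csr_aux()
    _engine.hebbian_step(
        network.ee.indptr, network.ee.post, network.ee.w,
        eer_indptr, eer_pre, eer_pos,
        pre_act, ltp, homo, params.delta_w, params.w_max,
    )
    return network
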