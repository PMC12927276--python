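"""Non-vectorized reference implementation of the network update.

A deliberately plain, loop-over-everything version of the synchronous
timestep and the Hebbian rule, written against the model equations rather
than against the production engine. Used to verify the compiled engine
trajectory element-wise on tiny circuits under a shared noise stream.
"""

from __future__ import annotations

import numpy as np


class ScalarState:
    def __init__(self, n_e: int, n_areas: int):
        self.V_e = [0.0] * n_e
        self.V_i = [0.0] * n_e
        self.om_a = [0.0] * n_e
        self.om_e = [0.0] * n_e
        self.om_g = [0.0] * n_areas
        self.phi_e = [0.0] * n_e
        self.phi_i = [0.0] * n_e


def scalar_run(
    state: ScalarState,
    ee: list[tuple[int, int, float]],   # (pre, post, weight), mutated in place
    ei: list[tuple[int, int, float]],
    ie: list[tuple[int, int, float]],
    stim: np.ndarray,
    stim_from: int,
    stim_until: int,
    noise: np.ndarray,
    steps: int,
    p,
    learn: bool = False,
) -> list[tuple[int, int, float]]:
    """Advance ``steps`` steps; returns the possibly updated e->e list."""
    n_e = len(state.V_e)
    n_areas = len(state.om_g)
    cpa = n_e // n_areas
    k_noise = p.noise_amplitude
    for t in range(steps):
        # stage 1: inputs from previous outputs
        ve_in = [0.0] * n_e
        vi_in = [0.0] * n_e
        inh = [0.0] * n_e
        for pre, post, w in ee:
            if state.phi_e[pre] > 0:
                ve_in[post] += w
        for pre, post, w in ei:
            if state.phi_e[pre] > 0:
                vi_in[post] += w
        for pre, post, w in ie:
            if state.phi_i[pre] > 0:
                inh[post] += w * state.phi_i[pre]
        for x in range(n_e):
            ve_in[x] *= p.synaptic_gain
        if stim_from <= t < stim_until:
            for x in range(n_e):
                ve_in[x] += stim[x]
        for x in range(n_e):
            ve_in[x] -= p.k_global * state.om_g[x // cpa]
        # stage 2: membrane
        for x in range(n_e):
            state.V_e[x] += (
                -state.V_e[x]
                + p.k1 * ve_in[x]
                - p.ie_gain * inh[x]
                + k_noise * noise[t, x]
            ) / p.tau_e
            state.V_i[x] += (-state.V_i[x] + p.ei_gain * vi_in[x]) / p.tau_i
        # stage 3: outputs
        for x in range(n_e):
            state.phi_e[x] = 1.0 if (state.V_e[x] - p.alpha * state.om_a[x]) > p.thresh else 0.0
            state.phi_i[x] = state.V_i[x] if state.V_i[x] > 0 else 0.0
        # stage 4: traces
        for x in range(n_e):
            state.om_a[x] += (-state.om_a[x] + p.alpha_adapt * state.phi_e[x]) / p.tau_adapt
            state.om_e[x] += (-state.om_e[x] + state.phi_e[x]) / p.tau_favg_learn
        for a in range(n_areas):
            s = sum(state.phi_e[a * cpa:(a + 1) * cpa])
            state.om_g[a] += (-state.om_g[a] + s) / p.tau_glob
        # stage 5: plasticity
        if learn:
            new = []
            for pre, post, w in ee:
                pre_act = state.om_e[pre] >= p.theta_pre
                v = state.V_e[post]
                if pre_act and v >= p.theta_plus:
                    w = min(w + p.delta_w, p.w_max)
                elif pre_act and p.theta_minus <= v < p.theta_plus:
                    w = max(w - p.delta_w, 0.0)
                elif (not pre_act) and v >= p.theta_plus:
                    w = max(w - p.delta_w, 0.0)
                new.append((pre, post, w))
            ee = new
    return ee
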