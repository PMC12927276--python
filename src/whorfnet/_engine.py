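"""Numba time-stepping kernel.

One synchronous update advances every cell of the network by one timestep
(explicit Euler, dt = 1) in a fixed stage order:

1. net input ``V_In`` from the *previous* step's outputs, plus external
   stimulation inside the stimulation window, minus the area's global
   inhibition (e-cells only);
2. membrane integration with fresh uniform noise on e-cells;
3. outputs: all-or-nothing spikes for e-cells (threshold compared against
   ``V - alpha * omega``), rectified-linear graded output for i-cells;
4. low-passed traces: adaptation, rate estimate, per-area global inhibition;
5. optionally, the Hebbian update of all plastic e-to-e synapses from the
   current presynaptic rate estimates and postsynaptic potentials.

The propagation and plasticity loops iterate over active presynaptic cells
only, which keeps the per-step cost proportional to network activity rather
than to the total synapse count.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_steps", "hebbian_step"]


@njit(cache=True)
def hebbian_step(
    ee_indptr, ee_post, ee_w,
    eer_indptr, eer_pre, eer_pos,
    pre_act, ltp, homo,
    delta_w, w_max,
):  # pragma: no cover - exercised through run_steps and apply_plasticity
    """Apply the discretized LTP/LTD rule to every plastic synapse in place.

    Branches per synapse (pre i, post j): LTP (+delta) when the presynaptic
    rate estimate is at threshold and V(j) >= theta_plus; homosynaptic LTD
    (-delta) when pre is active and theta_minus <= V(j) < theta_plus;
    heterosynaptic LTD (-delta) when pre is inactive but V(j) >= theta_plus.
    Weights are clipped to [0, w_max].
    """
    n_pre = ee_indptr.shape[0] - 1
    for pre in range(n_pre):
        if pre_act[pre]:
            for k in range(ee_indptr[pre], ee_indptr[pre + 1]):
                j = ee_post[k]
                if ltp[j]:
                    w = ee_w[k] + delta_w
                    ee_w[k] = w if w < w_max else w_max
                elif homo[j]:
                    w = ee_w[k] - delta_w
                    ee_w[k] = w if w > 0.0 else 0.0
    n_post = eer_indptr.shape[0] - 1
    for j in range(n_post):
        if ltp[j]:
            for k in range(eer_indptr[j], eer_indptr[j + 1]):
                if not pre_act[eer_pre[k]]:
                    pos = eer_pos[k]
                    w = ee_w[pos] - delta_w
                    ee_w[pos] = w if w > 0.0 else 0.0


@njit(cache=True)
def run_steps(
    # state (mutated in place)
    V_e, V_i, om_a, om_e, om_g, phi_e, phi_i,
    # e->e synapses, column-major by pre + row-major auxiliary view
    ee_indptr, ee_post, ee_w,
    eer_indptr, eer_pre, eer_pos,
    # static synapses
    ei_indptr, ei_post, ei_w,
    ie_indptr, ie_post, ie_w,
    # stimulation
    stim, stim_from, stim_until,
    # schedule
    max_steps, gate_areas, gate_thresh,
    # noise, pre-drawn uniform [-0.5, 0.5], shape (max_steps, n_e)
    noise,
    # cell-model constants
    g_syn, ei_gain, ie_gain,
    tau_e, tau_i, k1, k_noise, k_global, thresh, alpha, alpha_adapt,
    tau_adapt, tau_favg, tau_glob,
    # plasticity (applied for learn_from <= t < learn_until)
    learn_from, learn_until, theta_pre, theta_plus, theta_minus, delta_w, w_max,
    # recording buffers ((0, 0)-shaped to disable) and start step
    rec_rate, rec_spikes, rec_from,
):  # pragma: no cover - compiled; equivalence asserted against a scalar oracle
    """Run up to ``max_steps`` steps; returns (steps_executed, peak_area_spikes).

    External drive ``stim`` is applied for ``stim_from <= t < stim_until``.
    After the stimulation window, the trial terminates early at the first step
    where the global inhibition of every area in ``gate_areas`` has fallen
    below ``gate_thresh`` (the inter-stimulus-interval gate); pass an empty
    ``gate_areas`` to always run the full ``max_steps``.
    """
    n_e = V_e.shape[0]
    n_areas = om_g.shape[0]
    cpa = n_e // n_areas
    ve_in = np.zeros(n_e)
    vi_in = np.zeros(n_e)
    inh_e = np.zeros(n_e)
    pre_act = np.zeros(n_e, dtype=np.bool_)
    ltp = np.zeros(n_e, dtype=np.bool_)
    homo = np.zeros(n_e, dtype=np.bool_)
    peak_area_spikes = 0
    steps = 0
    for t in range(max_steps):
        if t >= stim_until and gate_areas.shape[0] > 0:
            quiet = True
            for gi in range(gate_areas.shape[0]):
                if om_g[gate_areas[gi]] >= gate_thresh:
                    quiet = False
                    break
            if quiet:
                break
        # --- stage 1: net input from previous outputs ---
        for x in range(n_e):
            ve_in[x] = 0.0
            vi_in[x] = 0.0
        for pre in range(n_e):
            if phi_e[pre] > 0.0:
                for k in range(ee_indptr[pre], ee_indptr[pre + 1]):
                    ve_in[ee_post[k]] += ee_w[k]
                for k in range(ei_indptr[pre], ei_indptr[pre + 1]):
                    vi_in[ei_post[k]] += ei_w[k]
        for x in range(n_e):
            inh_e[x] = 0.0
        for pre in range(n_e):
            p = phi_i[pre]
            if p > 0.0:
                for k in range(ie_indptr[pre], ie_indptr[pre + 1]):
                    inh_e[ie_post[k]] += ie_w[k] * p
        for x in range(n_e):
            ve_in[x] *= g_syn
        if stim_from <= t < stim_until:
            for x in range(n_e):
                ve_in[x] += stim[x]
        for a in range(n_areas):
            g = k_global * om_g[a]
            if g != 0.0:
                for x in range(a * cpa, (a + 1) * cpa):
                    ve_in[x] -= g
        # --- stage 2: membrane integration (i-cells receive no noise) ---
        for x in range(n_e):
            V_e[x] += (
                -V_e[x] + k1 * ve_in[x] - ie_gain * inh_e[x] + k_noise * noise[t, x]
            ) / tau_e
            V_i[x] += (-V_i[x] + ei_gain * vi_in[x]) / tau_i
        # --- stage 3: outputs (adaptation from the previous step) ---
        for x in range(n_e):
            phi_e[x] = 1.0 if (V_e[x] - alpha * om_a[x]) > thresh else 0.0
            phi_i[x] = V_i[x] if V_i[x] > 0.0 else 0.0
        # --- stage 4: traces ---
        for x in range(n_e):
            om_a[x] += (-om_a[x] + alpha_adapt * phi_e[x]) / tau_adapt
            om_e[x] += (-om_e[x] + phi_e[x]) / tau_favg
        for a in range(n_areas):
            s = 0.0
            for x in range(a * cpa, (a + 1) * cpa):
                s += phi_e[x]
            om_g[a] += (-om_g[a] + s) / tau_glob
            if int(s) > peak_area_spikes:
                peak_area_spikes = int(s)
        # --- stage 5: plasticity ---
        if learn_from <= t < learn_until:
            for x in range(n_e):
                pre_act[x] = om_e[x] >= theta_pre
                ltp[x] = V_e[x] >= theta_plus
                homo[x] = (V_e[x] >= theta_minus) and (V_e[x] < theta_plus)
            hebbian_step(
                ee_indptr, ee_post, ee_w,
                eer_indptr, eer_pre, eer_pos,
                pre_act, ltp, homo, delta_w, w_max,
            )
        # --- recording ---
        if rec_rate.shape[0] > 0 and t >= rec_from:
            row = t - rec_from
            if row < rec_rate.shape[0]:
                for x in range(n_e):
                    rec_rate[row, x] = om_e[x]
        if rec_spikes.shape[0] > 0 and t >= rec_from:
            row = t - rec_from
            if row < rec_spikes.shape[0]:
                for x in range(n_e):
                    rec_spikes[row, x] = np.uint8(phi_e[x] > 0.0)
        steps = t + 1
    return steps, peak_area_spikes
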