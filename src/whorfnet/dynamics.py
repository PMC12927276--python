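"""Network state and the synchronous timestep.

The state of the network is carried by :class:`DynamicState`: per e-cell the
membrane potential ``V``, adaptation ``omega``, rate estimate ``omega_E`` and
binary output ``phi``; per i-cell the potential and graded output; per area
the global-inhibition accumulator ``omega_G``. :func:`step` advances the whole
network one step through the fixed stage order documented in
:mod:`whorfnet._engine`; :func:`run_trial` runs a stimulation trial (the
engine's main entry point used by the learning and recognition protocols).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _engine
from .architecture import CELLS_PER_AREA, N_AREAS, N_E, AREA_INDEX, Network
from .params import SimulationParams

__all__ = ["DynamicState", "StimulusFrame", "step", "run_trial", "lowpass", "reset_potentials"]


@dataclass
class DynamicState:
    """All per-cell and per-area dynamic variables of one network."""

    V_e: np.ndarray
    V_i: np.ndarray
    omega_adapt: np.ndarray
    omega_rate: np.ndarray
    omega_glob: np.ndarray
    phi_e: np.ndarray
    phi_i: np.ndarray

    @classmethod
    def zeros(cls, n_e: int = N_E, n_areas: int = N_AREAS) -> "DynamicState":
        return cls(
            V_e=np.zeros(n_e),
            V_i=np.zeros(n_e),
            omega_adapt=np.zeros(n_e),
            omega_rate=np.zeros(n_e),
            omega_glob=np.zeros(n_areas),
            phi_e=np.zeros(n_e),
            phi_i=np.zeros(n_e),
        )

    def check_finite(self) -> None:
        for name in ("V_e", "V_i", "omega_adapt", "omega_rate", "omega_glob"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                bad = int(np.flatnonzero(~np.isfinite(arr))[0])
                raise FloatingPointError(f"non-finite value in {name} at cell {bad}")


@dataclass
class StimulusFrame:
    """External drive for one trial: a per-e-cell amplitude vector."""

    drive: np.ndarray = field(default_factory=lambda: np.zeros(N_E))

    def add_pattern(self, area: str, cells: np.ndarray, amplitude: float) -> "StimulusFrame":
        self.drive[AREA_INDEX[area] * CELLS_PER_AREA + np.asarray(cells, dtype=np.int64)] += amplitude
        return self

    def add_area_drive(self, area: str, per_cell: np.ndarray) -> "StimulusFrame":
        a = AREA_INDEX[area]
        self.drive[a * CELLS_PER_AREA:(a + 1) * CELLS_PER_AREA] += per_cell
        return self


def lowpass(previous: float, input_signal: float, tau: float, gain: float = 1.0) -> float:
    """One Euler step (dt = 1) of the shared first-order low-pass.

    ``y' = y + (-y + gain * u) / tau`` — used by the adaptation, rate-estimate
    and global-inhibition traces with their respective tau and gain.
    """
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    return previous + (-previous + gain * input_signal) / tau


def reset_potentials(state: DynamicState, full: bool = False) -> DynamicState:
    """Set all membrane potentials (and hence all outputs) to zero in place.

    By default the adaptation, rate and global-inhibition traces persist
    across the reset; ``full=True`` clears them too.
    """
    state.V_e[:] = 0.0
    state.V_i[:] = 0.0
    state.phi_e[:] = 0.0
    state.phi_i[:] = 0.0
    if full:
        state.omega_adapt[:] = 0.0
        state.omega_rate[:] = 0.0
        state.omega_glob[:] = 0.0
    return state


_EMPTY_RATE = np.zeros((0, 0))
_EMPTY_SPIKES = np.zeros((0, 0), dtype=np.uint8)
_EMPTY_GATE = np.zeros(0, dtype=np.int64)


def run_trial(
    network: Network,
    state: DynamicState,
    stim: np.ndarray,
    noise: np.ndarray,
    params: SimulationParams,
    *,
    stim_from: int = 0,
    stim_until: int,
    max_steps: int,
    gate_areas: np.ndarray | None = None,
    learn: bool,
    learn_window: tuple[int, int] | None = None,
    tau_favg: float,
    rec_rate: np.ndarray | None = None,
    rec_spikes: np.ndarray | None = None,
    rec_from: int = 0,
) -> tuple[int, int]:
    """Advance ``state`` through one stimulation trial (mutates in place).

    ``noise`` must be a ``(max_steps, n_e)`` array of uniform [-0.5, 0.5]
    draws from the caller's seeded stream. Returns ``(steps_executed,
    peak_area_spikes)``; raises ``FloatingPointError`` if the state went
    non-finite.
    """
    if not learn:
        learn_from, learn_until = 0, 0
    elif learn_window is not None:
        learn_from, learn_until = learn_window
    else:
        learn_from, learn_until = 0, max_steps
    eer_indptr, eer_pre, eer_pos = network.ee.to_csr_aux()
    steps, peak = _engine.run_steps(
        state.V_e, state.V_i, state.omega_adapt, state.omega_rate,
        state.omega_glob, state.phi_e, state.phi_i,
        network.ee.indptr, network.ee.post, network.ee.w,
        eer_indptr, eer_pre, eer_pos,
        network.ei.indptr, network.ei.post, network.ei.w,
        network.ie.indptr, network.ie.post, network.ie.w,
        stim, stim_from, stim_until,
        max_steps,
        _EMPTY_GATE if gate_areas is None else gate_areas,
        params.isi_inhib_threshold,
        noise,
        params.synaptic_gain, params.ei_gain, params.ie_gain,
        params.tau_e, params.tau_i, params.k1, params.noise_amplitude,
        params.k_global, params.thresh, params.alpha, params.alpha_adapt,
        params.tau_adapt, tau_favg, params.tau_glob,
        learn_from, learn_until, params.theta_pre, params.theta_plus,
        params.theta_minus, params.delta_w, params.w_max,
        _EMPTY_RATE if rec_rate is None else rec_rate,
        _EMPTY_SPIKES if rec_spikes is None else rec_spikes,
        rec_from,
    )
    state.check_finite()
    return steps, peak


def step(
    network: Network,
    state: DynamicState,
    frame: StimulusFrame | None,
    params: SimulationParams,
    rng: np.random.Generator | None = None,
    *,
    noise: np.ndarray | None = None,
    learn: bool = False,
    tau_favg: float | None = None,
) -> DynamicState:
    """Advance the network exactly one synchronous timestep (in place).

    Noise can be supplied explicitly (one uniform [-0.5, 0.5] value per
    e-cell) or drawn from ``rng``; pass neither to run noise-free.
    """
    n_e = state.V_e.shape[0]
    if noise is None:
        noise = rng.random(n_e) - 0.5 if rng is not None else np.zeros(n_e)
    stim = frame.drive if frame is not None else np.zeros(n_e)
    run_trial(
        network, state, stim, noise[None, :], params,
        stim_from=0, stim_until=1, max_steps=1,
        learn=learn,
        tau_favg=params.tau_favg_learn if tau_favg is None else tau_favg,
    )
    return state
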