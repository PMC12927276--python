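"""Model and protocol constants.

:class:`SimulationParams` is the single authoritative home for every constant
of the cell model (membrane, spiking, adaptation, rate estimation, global
inhibition, Hebbian plasticity), the connectivity kernels, and the learning /
recognition protocols. Instances are immutable after validation and
round-trip losslessly through YAML/JSON configuration files.

Units: all time constants are expressed in simulation timesteps; membrane
potentials, thresholds and synaptic weights are in the model's dimensionless
potential units.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = ["KernelSpec", "SimulationParams", "load_params", "dump_params", "ParamError"]


class ParamError(ValueError):
    """Raised for malformed or out-of-range configuration values."""


@dataclass(frozen=True)
class KernelSpec:
    """Clipped-Gaussian synapse-creation kernel.

    ``p(dx, dy) = center_prob * exp(-(dx^2 + dy^2) / (2 sigma^2))`` inside the
    square neighborhood of side ``neighborhood``, and 0 outside it.
    """

    center_prob: float
    sigma: float
    neighborhood: int

    def validate(self, name: str) -> None:
        if not 0.0 <= self.center_prob <= 1.0:
            raise ParamError(f"{name}.center_prob must be in [0, 1], got {self.center_prob}")
        if self.sigma <= 0:
            raise ParamError(f"{name}.sigma must be > 0, got {self.sigma}")
        if self.neighborhood <= 0 or self.neighborhood % 2 == 0:
            raise ParamError(
                f"{name}.neighborhood must be an odd positive integer, got {self.neighborhood}"
            )


def _default_kernel(center: float, sigma: float, n: int):
    return field(default_factory=lambda: KernelSpec(center, sigma, n))


@dataclass(frozen=True)
class SimulationParams:
    # --- membrane / spiking (cell model) ---
    tau_e: float = 2.5          # excitatory membrane time constant
    tau_i: float = 5.0          # inhibitory membrane time constant
    k1: float = 0.01            # total input rescaling factor
    dt: float = 0.15            # discretization constant entering the noise amplitude
    k2: float | None = None     # noise shape factor; None -> 3*sqrt(24/dt)
    synaptic_gain: float = 100.0  # gain on e-to-e weight contributions (see docs)
    ei_gain: float = 20.0       # e-to-i drive gain (i-cell tracks local spiking)
    ie_gain: float = 20.0       # i-to-e feedback gain (local competition strength)
    k_global: float = 2.0       # global inhibition strength k_G
    thresh: float = 0.18        # spiking threshold
    alpha: float = 7.0          # adaptation strength at threshold comparison
    alpha_adapt: float = 0.14   # gain of the adaptation low-pass (see docs)
    tau_adapt: float = 10.0     # adaptation time constant
    tau_favg_learn: float = 30.0   # rate-estimate time constant during learning
    tau_favg_extract: float = 5.0  # rate-estimate time constant during extraction
    tau_glob: float = 12.0      # global-inhibition time constant
    inp_strength: float = 700.0  # sensorimotor input per stimulated cell (Inp)
    noise_input_form: str = "pattern"  # per-trial drive to non-relevant areas

    # --- Hebbian plasticity ---
    theta_plus: float = 0.15    # postsynaptic LTP threshold
    theta_minus: float = 0.14   # postsynaptic homosynaptic-LTD threshold
    theta_pre: float = 0.15     # presynaptic rate-estimate threshold
    delta_w: float = 0.008      # weight increment/decrement per event
    w_init_max: float = 0.1     # upper bound of uniform weight initialization
    w_max: float = 0.225        # hard upper clip for excitatory weights

    # --- cell-assembly extraction ---
    gamma_ca: float = 0.5       # CA membership fraction of the area peak rate
    gamma_responsive: float = 0.2  # 20% rule used for responsive cells (MMN)
    min_peak_rate: float = 0.2  # minimum area peak rate for a CA to exist there

    # --- connectivity kernels ---
    kernel_ee_within: KernelSpec = _default_kernel(0.28, 6.5, 19)
    kernel_ee_between: KernelSpec = _default_kernel(0.15, 4.5, 19)
    kernel_ie: KernelSpec = _default_kernel(0.295, 2.0, 5)
    toroidal: bool = True       # periodic grid neighborhoods (clipped if False)

    # --- trial protocol ---
    stim_steps_learn: int = 16
    learn_during_isi: bool = True  # apply plasticity during the ISI too
    isi_steps: int = 30
    isi_inhib_threshold: float = 0.55
    isi_gate_areas: tuple[str, ...] = ("V1", "TO", "AT", "PFL")
    extract_noise_scale: float = 1.4  # baseline-noise scale during extraction/recognition
    extract_n_trials: int = 3   # reactivation repetitions averaged per extraction
    stim_steps_recog: int = 2
    recog_post_steps: int = 28
    recog_baseline_steps: int = 10
    extract_record_steps: int = 30
    trials_phase1_per_pattern: int = 1000
    trials_phase2_per_pairing: int = 1000
    n_networks: int = 16

    # --- exclusion ceilings (artifact choices, reported per run) ---
    exclude_jaccard: float = 0.8
    exclude_recruitment: float = 0.5

    # ------------------------------------------------------------------
    @property
    def k2_effective(self) -> float:
        """Noise shape factor: explicit ``k2`` override, else ``3*sqrt(24/dt)``."""
        if self.k2 is not None:
            return self.k2
        return 3.0 * math.sqrt(24.0 / self.dt)

    @property
    def noise_amplitude(self) -> float:
        """Amplitude multiplying the uniform [-0.5, 0.5] membrane noise.

        ``k1 * k2`` — about 0.208 at the defaults, i.e. membrane noise
        fluctuations of a few hundredths of a potential unit, keeping
        quiescent cells a little below the plasticity and spiking thresholds.
        """
        return self.k1 * self.k2_effective

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = [
            "tau_e", "tau_i", "dt", "tau_adapt", "tau_favg_learn",
            "tau_favg_extract", "tau_glob", "delta_w",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ParamError(f"{name} must be > 0, got {getattr(self, name)}")
        nonneg = [
            "k1", "k_global", "thresh", "alpha", "alpha_adapt", "inp_strength",
            "theta_plus", "theta_minus", "theta_pre", "w_init_max", "w_max",
            "min_peak_rate", "isi_inhib_threshold", "ei_gain", "ie_gain",
            "extract_noise_scale",
        ]
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ParamError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.k2 is not None and self.k2 < 0:
            raise ParamError(f"k2 must be >= 0, got {self.k2}")
        if self.synaptic_gain < 0:
            raise ParamError(f"synaptic_gain must be >= 0, got {self.synaptic_gain}")
        if self.noise_input_form not in ("pattern", "uniform"):
            raise ParamError(
                f"noise_input_form must be 'pattern' or 'uniform', got {self.noise_input_form!r}"
            )
        if not self.theta_minus < self.theta_plus:
            raise ParamError(
                f"theta_minus ({self.theta_minus}) must be < theta_plus ({self.theta_plus})"
            )
        for frac in ("gamma_ca", "gamma_responsive", "exclude_jaccard", "exclude_recruitment"):
            v = getattr(self, frac)
            if not 0.0 <= v <= 1.0:
                raise ParamError(f"{frac} must be in [0, 1], got {v}")
        if self.w_init_max > self.w_max:
            raise ParamError(
                f"w_init_max ({self.w_init_max}) must not exceed w_max ({self.w_max})"
            )
        for name in ("stim_steps_learn", "isi_steps", "stim_steps_recog", "extract_n_trials",
                     "recog_post_steps", "recog_baseline_steps", "extract_record_steps",
                     "trials_phase1_per_pattern", "trials_phase2_per_pairing", "n_networks"):
            v = getattr(self, name)
            if not isinstance(v, int) or v <= 0:
                raise ParamError(f"{name} must be a positive integer, got {v!r}")
        self.kernel_ee_within.validate("kernel_ee_within")
        self.kernel_ee_between.validate("kernel_ee_between")
        self.kernel_ie.validate("kernel_ie")

    # ------------------------------------------------------------------
    def replace(self, **overrides: Any) -> "SimulationParams":
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, KernelSpec):
                v = dataclasses.asdict(v)
            elif isinstance(v, tuple):
                v = list(v)
            d[f.name] = v
        return d

    @classmethod
    def from_dict(cls, config: dict[str, Any]) -> "SimulationParams":
        known = {f.name: f for f in dataclasses.fields(cls)}
        kwargs: dict[str, Any] = {}
        for key, value in config.items():
            if key not in known:
                raise ParamError(f"unknown configuration key: {key!r}")
            if key.startswith("kernel_"):
                if not isinstance(value, dict):
                    raise ParamError(f"{key} must be a mapping with center_prob/sigma/neighborhood")
                extra = set(value) - {"center_prob", "sigma", "neighborhood"}
                if extra:
                    raise ParamError(f"unknown keys in {key}: {sorted(extra)}")
                value = KernelSpec(**value)
            elif key == "isi_gate_areas":
                value = tuple(value)
            kwargs[key] = value
        return cls(**kwargs)

    def params_hash(self) -> str:
        import hashlib

        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_params(source: str | Path | dict[str, Any] | None = None) -> SimulationParams:
    """Build :class:`SimulationParams` from a YAML/JSON file or a mapping.

    Omitted keys take the model defaults; unknown keys are rejected with a
    :class:`ParamError` naming the offending key.
    """
    if source is None:
        return SimulationParams()
    if isinstance(source, dict):
        return SimulationParams.from_dict(source)
    path = Path(source)
    text = path.read_text()
    if path.suffix in {".json"}:
        config = json.loads(text)
    else:
        config = yaml.safe_load(text)
    if config is None:
        config = {}
    if not isinstance(config, dict):
        raise ParamError(f"configuration root must be a mapping, got {type(config).__name__}")
    return SimulationParams.from_dict(config)


def dump_params(params: SimulationParams, path: str | Path | None = None) -> str:
    """Serialize the effective configuration to YAML (lossless round-trip)."""
    text = yaml.safe_dump(params.to_dict(), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text
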