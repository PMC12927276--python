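"""Learning and stimulation protocols.

Phase 1 (perceptual/phonological pre-exposure) presents the four color
patterns and the three word-form pattern pairs in separate, randomly ordered
trials; phase 2 (semantic learning) co-presents each color with its
language-specific verbal label. A trial stimulates the primary areas for 16
steps and then runs an inter-stimulus interval of at most 30 steps, ended
early once global inhibition has decayed below the gate threshold in V1, TO,
AT and PFL; every trial starts from a membrane-potential reset. Non-relevant
primary areas receive fresh uncorrelated noise drive on every learning trial.

:func:`run_experiment` orchestrates the whole study: per network
instantiation it runs phase 1 once, branches byte-identical English and
Russian copies, trains each, and records extraction (rate) tensors and
recognition (spike) rasters for all four colors and model types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .architecture import (
    AREA_INDEX, CELLS_PER_AREA, N_E,
    ConnectivityGraph, Network, default_connectivity_graph, sample_synapses,
)
from .dynamics import DynamicState, StimulusFrame, reset_potentials, run_trial
from .params import SimulationParams
from .patterns import COLOR_TAGS, PatternSet, fresh_noise_drive, generate_pattern_set

__all__ = [
    "LabelMapping", "ExperimentPlan", "ExperimentResult", "ActivityExplosion",
    "run_phase1", "run_phase2", "run_extraction_trial", "run_recognition_trial",
    "run_experiment",
]

PRIMARIES = ("V1", "M1L", "A1", "M1i")
#: fraction of an area's e-cells firing in a single step that aborts a run
EXPLOSION_FRACTION = 0.95


class ActivityExplosion(RuntimeError):
    """Raised when learning produces sustained full-area firing."""


@dataclass(frozen=True)
class LabelMapping:
    """Language-specific assignment of word-form indices to color tags."""

    language: str
    mapping: dict[str, int]

    def __post_init__(self) -> None:
        missing = set(COLOR_TAGS) - set(self.mapping)
        if missing:
            raise ValueError(f"unmapped color tags: {sorted(missing)}")

    @classmethod
    def english(cls) -> "LabelMapping":
        """One label per color: 'blue' for both blues, 'green' for both greens."""
        return cls("english", {
            "blue_light": 1, "blue_dark": 1, "green_light": 2, "green_dark": 2,
        })

    @classmethod
    def russian(cls) -> "LabelMapping":
        """Distinct labels for the blues (goluboj/sinij), one for the greens."""
        return cls("russian", {
            "blue_light": 1, "blue_dark": 2, "green_light": 3, "green_dark": 3,
        })

    def word_index(self, color_tag: str) -> int:
        return self.mapping[color_tag]


def _gate_indices(params: SimulationParams) -> np.ndarray:
    return np.array([AREA_INDEX[a] for a in params.isi_gate_areas], dtype=np.int64)


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def _learning_trial(
    network: Network,
    state: DynamicState,
    stim: np.ndarray,
    params: SimulationParams,
    noise_rng: np.random.Generator,
    gate: np.ndarray,
) -> int:
    max_steps = params.stim_steps_learn + params.isi_steps
    noise = noise_rng.random((max_steps, N_E)) - 0.5
    reset_potentials(state)
    learn_window = None if params.learn_during_isi else (0, params.stim_steps_learn)
    steps, peak = run_trial(
        network, state, stim, noise, params,
        stim_from=0, stim_until=params.stim_steps_learn,
        max_steps=max_steps, gate_areas=gate,
        learn=True, learn_window=learn_window,
        tau_favg=params.tau_favg_learn,
    )
    if peak >= EXPLOSION_FRACTION * CELLS_PER_AREA:
        raise ActivityExplosion(
            f"{peak} of {CELLS_PER_AREA} e-cells of one area fired in a single "
            f"step; network diverged (seed {network.seed})"
        )
    return steps


def _noise_frame(
    frame: StimulusFrame,
    areas: tuple[str, ...],
    params: SimulationParams,
    rng: np.random.Generator,
) -> StimulusFrame:
    for area in areas:
        frame.add_area_drive(
            area, fresh_noise_drive(rng, params.inp_strength, form=params.noise_input_form)
        )
    return frame


def phase1_stimulus_types(patterns: PatternSet) -> list[str]:
    """The seven phase-1 stimulus labels: four colors and three word pairs."""
    return list(COLOR_TAGS) + [f"word{i}" for i in (1, 2, 3)]


def build_phase1_frame(
    kind: str, patterns: PatternSet, params: SimulationParams, rng: np.random.Generator
) -> StimulusFrame:
    """Stimulus for one phase-1 trial: the driven pattern plus fresh noise
    drive to the non-relevant primary areas."""
    frame = StimulusFrame()
    if kind.startswith("word"):
        idx = int(kind[4:])
        frame.add_pattern("A1", patterns.word(idx, "aud").indices, params.inp_strength)
        frame.add_pattern("M1i", patterns.word(idx, "art").indices, params.inp_strength)
        _noise_frame(frame, ("V1", "M1L"), params, rng)
    else:
        frame.add_pattern("V1", patterns.color(kind).indices, params.inp_strength)
        _noise_frame(frame, ("A1", "M1i", "M1L"), params, rng)
    return frame


def build_phase2_frame(
    color_tag: str,
    patterns: PatternSet,
    mapping: LabelMapping,
    params: SimulationParams,
    rng: np.random.Generator,
) -> StimulusFrame:
    """Stimulus for one semantic trial: color in V1 co-presented with its
    mapped word form in A1 and M1i, noise drive to M1L."""
    w = mapping.word_index(color_tag)
    frame = StimulusFrame()
    frame.add_pattern("V1", patterns.color(color_tag).indices, params.inp_strength)
    frame.add_pattern("A1", patterns.word(w, "aud").indices, params.inp_strength)
    frame.add_pattern("M1i", patterns.word(w, "art").indices, params.inp_strength)
    _noise_frame(frame, ("M1L",), params, rng)
    return frame


def _run_phase(
    network: Network,
    params: SimulationParams,
    labels: list[str],
    trials_per_label: int,
    frame_builder: Callable[[str, np.random.Generator], StimulusFrame],
    seed: int,
    state: DynamicState | None = None,
) -> tuple[DynamicState, np.ndarray]:
    order_ss, noise_ss, frame_ss = np.random.SeedSequence(seed).spawn(3)
    order_rng = np.random.default_rng(order_ss)
    noise_rng = np.random.default_rng(noise_ss)
    frame_rng = np.random.default_rng(frame_ss)
    schedule = np.repeat(np.arange(len(labels)), trials_per_label)
    schedule = order_rng.permutation(schedule)
    gate = _gate_indices(params)
    if state is None:
        state = DynamicState.zeros()
    for label_idx in schedule:
        frame = frame_builder(labels[label_idx], frame_rng)
        _learning_trial(network, state, frame.drive, params, noise_rng, gate)
    return state, schedule


def run_phase1(
    network: Network,
    patterns: PatternSet,
    params: SimulationParams | None = None,
    seed: int = 0,
    trials_per_pattern: int | None = None,
) -> Network:
    """Perceptual and phonological pre-exposure (plasticity on).

    Presents the 4 color patterns and 3 word-form pairs separately,
    ``trials_per_pattern`` times each, in one randomized sequence.
    """
    params = params or network.params
    n = trials_per_pattern if trials_per_pattern is not None else params.trials_phase1_per_pattern
    labels = phase1_stimulus_types(patterns)
    _run_phase(
        network, params, labels, n,
        lambda kind, rng: build_phase1_frame(kind, patterns, params, rng),
        seed,
    )
    return network


def run_phase2(
    network: Network,
    patterns: PatternSet,
    mapping: LabelMapping,
    params: SimulationParams | None = None,
    seed: int = 0,
    trials_per_pairing: int | None = None,
) -> Network:
    """Semantic (label) learning on a phase-1 snapshot (plasticity on)."""
    params = params or network.params
    n = trials_per_pairing if trials_per_pairing is not None else params.trials_phase2_per_pairing
    _run_phase(
        network, params, list(COLOR_TAGS), n,
        lambda tag, rng: build_phase2_frame(tag, patterns, mapping, params, rng),
        seed,
    )
    return network


def run_extraction_trial(
    network: Network,
    pattern,
    params: SimulationParams | None = None,
    seed: int = 0,
    baseline_noise: bool = True,
) -> np.ndarray:
    """Reactivate a learned circuit and record its rate tensor.

    Stimulates the pattern's area for 16 steps from a fully reset state and
    records the per-cell rate estimate (time constant ``tau_favg_extract``)
    over the 30 steps after stimulation offset, for all 12 areas. Plasticity
    is frozen and no noise patterns go to the other primary areas; the
    baseline membrane noise stays on unless disabled.

    Returns an array of shape ``(12, 625, 30)``.
    """
    params = params or network.params
    state = DynamicState.zeros()
    t_stim = params.stim_steps_learn
    t_rec = params.extract_record_steps
    max_steps = t_stim + t_rec
    rng = np.random.default_rng(seed)
    if baseline_noise:
        noise = (rng.random((max_steps, N_E)) - 0.5) * params.extract_noise_scale
    else:
        noise = np.zeros((max_steps, N_E))
    stim = StimulusFrame().add_pattern(pattern.area, pattern.indices, params.inp_strength).drive
    rec = np.zeros((t_rec, N_E))
    run_trial(
        network, state, stim, noise, params,
        stim_from=0, stim_until=t_stim, max_steps=max_steps,
        learn=False, tau_favg=params.tau_favg_extract,
        rec_rate=rec, rec_from=t_stim,
    )
    # (steps, areas*cells) -> (areas, cells, steps)
    return rec.T.reshape(-1, CELLS_PER_AREA, t_rec)


def run_extraction(
    network: Network,
    pattern,
    params: SimulationParams | None = None,
    seed: int = 0,
    n_trials: int | None = None,
    baseline_noise: bool = True,
) -> np.ndarray:
    """Mean rate tensor over repeated reactivation trials.

    Reactivation of a marginally coupled circuit is sensitive to the baseline
    noise realization; averaging the rate tensors of a few repetitions keeps
    consistently reactivated assembly members while one-off noise-driven
    responses are damped below the extraction threshold.
    """
    params = params or network.params
    n = n_trials if n_trials is not None else params.extract_n_trials
    acc = None
    for r in range(n):
        t = run_extraction_trial(
            network, pattern, params, seed=seed + r, baseline_noise=baseline_noise
        )
        acc = t if acc is None else acc + t
    return acc / n


def run_recognition_trial(
    network: Network,
    pattern,
    params: SimulationParams | None = None,
    seed: int = 0,
    baseline_noise: bool = True,
) -> np.ndarray:
    """Record spiking around a brief 2-step stimulation.

    The raster covers a 10-step pre-onset baseline, the 2 stimulation steps,
    and 28 post-offset steps (40 steps total); plasticity is frozen and the
    run starts from a fully reset state.

    Returns a uint8 array of shape ``(40, 7500)``.
    """
    params = params or network.params
    state = DynamicState.zeros()
    t0 = params.recog_baseline_steps
    t_stim = params.stim_steps_recog
    max_steps = t0 + t_stim + params.recog_post_steps
    rng = np.random.default_rng(seed)
    if baseline_noise:
        noise = (rng.random((max_steps, N_E)) - 0.5) * params.extract_noise_scale
    else:
        noise = np.zeros((max_steps, N_E))
    stim = StimulusFrame().add_pattern(pattern.area, pattern.indices, params.inp_strength).drive
    rec = np.zeros((max_steps, N_E), dtype=np.uint8)
    run_trial(
        network, state, stim, noise, params,
        stim_from=t0, stim_until=t0 + t_stim, max_steps=max_steps,
        learn=False, tau_favg=params.tau_favg_extract,
        rec_spikes=rec, rec_from=0,
    )
    return rec


@dataclass
class ExperimentPlan:
    """A full multi-network study at a configurable scale."""

    params: SimulationParams = field(default_factory=SimulationParams)
    master_seed: int = 0
    n_networks: int | None = None          # None -> params.n_networks
    trials_phase1: int | None = None       # None -> params default
    trials_phase2: int | None = None
    languages: tuple[str, ...] = ("english", "russian")
    graph: ConnectivityGraph | None = None
    shared_patterns: bool = True           # identical stimuli for all learners

    def resolved(self) -> tuple[int, int, int]:
        p = self.params
        return (
            self.n_networks if self.n_networks is not None else p.n_networks,
            self.trials_phase1 if self.trials_phase1 is not None else p.trials_phase1_per_pattern,
            self.trials_phase2 if self.trials_phase2 is not None else p.trials_phase2_per_pairing,
        )


@dataclass
class ExperimentResult:
    """Recordings and provenance of one executed plan.

    ``rate_tensors[net][model][color]`` is a ``(12, 625, 30)`` extraction
    tensor; ``rasters[net][model][color]`` a ``(40, 7500)`` recognition
    raster (language models only); ``weight_hashes[net][stage]`` track the
    byte-identity of the shared phase-1 snapshot across branches.
    """

    plan: ExperimentPlan
    patterns: PatternSet
    rate_tensors: list[dict[str, dict[str, np.ndarray]]]
    rasters: list[dict[str, dict[str, np.ndarray]]]
    weight_hashes: list[dict[str, str]]
    diverged: list[bool] = field(default_factory=list)
    networks: list[dict[str, Network]] = field(default_factory=list)

    @property
    def model_types(self) -> tuple[str, ...]:
        return ("perceptual",) + tuple(self.plan.languages)


def _mapping_for(language: str) -> LabelMapping:
    return {"english": LabelMapping.english, "russian": LabelMapping.russian}[language]()


def run_experiment(plan: ExperimentPlan, keep_networks: bool = False,
                   progress: Callable[[str], None] | None = None) -> ExperimentResult:
    """Execute a plan end to end.

    Per instantiation: sample connectivity (distinct seed, shared patterns),
    run phase 1, snapshot it as the perceptual model, branch byte-identical
    copies per language for phase 2, then record extraction tensors for every
    model type and recognition rasters for the trained language models.
    """
    params = plan.params
    n_networks, n_p1, n_p2 = plan.resolved()
    graph = plan.graph or default_connectivity_graph()
    root = np.random.SeedSequence(plan.master_seed)
    pattern_ss, nets_ss = root.spawn(2)
    patterns = generate_pattern_set(_seed_int(pattern_ss))

    rate_tensors, rasters, hashes, diverged, networks = [], [], [], [], []
    for i, net_ss in enumerate(nets_ss.spawn(n_networks)):
        conn_ss, p1_ss, lang_parent, extract_ss, recog_ss = net_ss.spawn(5)
        if not plan.shared_patterns:
            patterns = generate_pattern_set(_seed_int(net_ss.spawn(1)[0]))
        if progress:
            progress(f"network {i}: sampling connectivity")
        net = sample_synapses(graph, params, _seed_int(conn_ss))
        tensors_i: dict[str, dict[str, np.ndarray]] = {}
        rasters_i: dict[str, dict[str, np.ndarray]] = {}
        net_hash: dict[str, str] = {}
        blew_up = False
        try:
            if progress:
                progress(f"network {i}: phase 1 ({n_p1} trials per pattern)")
            run_phase1(net, patterns, params, _seed_int(p1_ss), trials_per_pattern=n_p1)
            net_hash["phase1"] = net.weight_hash()

            models: dict[str, Network] = {"perceptual": net}
            for lang, lang_ss in zip(plan.languages, lang_parent.spawn(len(plan.languages))):
                branch = net.copy()
                net_hash[f"{lang}_start"] = branch.weight_hash()
                if progress:
                    progress(f"network {i}: phase 2 {lang} ({n_p2} trials per pairing)")
                run_phase2(branch, patterns, _mapping_for(lang), params,
                           _seed_int(lang_ss), trials_per_pairing=n_p2)
                models[lang] = branch

            for m, (model, model_net) in enumerate(models.items()):
                tensors_i[model] = {}
                for c, tag in enumerate(COLOR_TAGS):
                    tensors_i[model][tag] = run_extraction(
                        model_net, patterns.color(tag), params,
                        seed=_seed_int(extract_ss) + 101 * m + 7 * c,
                    )
                if model != "perceptual":
                    rasters_i[model] = {}
                    for c, tag in enumerate(COLOR_TAGS):
                        rasters_i[model][tag] = run_recognition_trial(
                            model_net, patterns.color(tag), params,
                            seed=_seed_int(recog_ss) + 101 * m + c,
                        )
        except ActivityExplosion:
            # runaway learning: the instantiation is retained as a record but
            # carries no usable recordings and is excluded downstream
            blew_up = True
            tensors_i, rasters_i = {}, {}
            if progress:
                progress(f"network {i}: diverged; marked for exclusion")
        rate_tensors.append(tensors_i)
        rasters.append(rasters_i)
        hashes.append(net_hash)
        diverged.append(blew_up)
        if keep_networks:
            networks.append(models if not blew_up else {})

    return ExperimentResult(
        plan=plan, patterns=patterns,
        rate_tensors=rate_tensors, rasters=rasters,
        weight_hashes=hashes, diverged=diverged, networks=networks,
    )
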