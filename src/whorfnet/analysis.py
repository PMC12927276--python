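"""Quantification of trained networks.

Cell-assembly (CA) extraction thresholds each area's rate tensor at a
fraction ``gamma`` of the area's peak response; representational similarity
analysis computes Euclidean distances between unthresholded 625-cell mean
activation vectors; CA members are decomposed into neurons shared between the
two shades of a color versus unique to one shade; the mismatch-negativity
proxy isolates the spiking of shade-unique neurons during recognition; and a
network-level exclusion rule drops instantiations whose assemblies merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .architecture import AREA_NAMES, CELLS_PER_AREA, GROUPINGS, AREA_INDEX
from .params import SimulationParams

__all__ = [
    "CellAssembly", "NeuronTypeCounts", "MMNTrace",
    "extract_assembly", "activation_vectors", "compute_rdm",
    "count_shared_unique", "mmn_trace", "exclude_networks",
    "analyze_experiment", "summarize",
]

COLOR_PAIRS = {"blue": ("blue_light", "blue_dark"), "green": ("green_light", "green_dark")}


@dataclass(frozen=True)
class CellAssembly:
    """Per-area member sets and peak rates for one stimulus."""

    tag: str
    members: dict[str, frozenset[int]]
    peaks: dict[str, float]

    def in_region(self, region: str) -> frozenset[int]:
        return self.members.get(region, frozenset())

    def size(self, regions=None) -> int:
        regions = regions if regions is not None else AREA_NAMES
        return sum(len(self.in_region(r)) for r in regions)

    def global_cells(self, regions) -> set[int]:
        out: set[int] = set()
        for r in regions:
            base = AREA_INDEX[r] * CELLS_PER_AREA
            out.update(base + c for c in self.in_region(r))
        return out


def extract_assembly(
    rate_tensor: np.ndarray,
    params: SimulationParams,
    tag: str = "",
    gamma: float | None = None,
) -> CellAssembly:
    """Threshold a ``(12, 625, T)`` extraction tensor into a cell assembly.

    Per area, the membership threshold is ``gamma`` times the peak rate over
    all cells and recorded steps; a cell belongs to the assembly if its rate
    reaches the threshold at any step. Areas whose peak rate falls below
    ``min_peak_rate`` contribute no members.
    """
    gamma = params.gamma_ca if gamma is None else gamma
    members: dict[str, frozenset[int]] = {}
    peaks: dict[str, float] = {}
    for a, name in enumerate(AREA_NAMES):
        cell_peaks = rate_tensor[a].max(axis=1)
        peak = float(cell_peaks.max(initial=0.0))
        peaks[name] = peak
        if peak < params.min_peak_rate:
            members[name] = frozenset()
            continue
        thr = gamma * peak
        members[name] = frozenset(int(c) for c in np.flatnonzero(cell_peaks >= thr))
    return CellAssembly(tag=tag, members=members, peaks=peaks)


def activation_vectors(rate_tensor: np.ndarray) -> np.ndarray:
    """Unthresholded per-cell mean rate over the recorded window, per region.

    Returns a ``(12, 625)`` array of non-negative activation values.
    """
    return rate_tensor.mean(axis=2)


def compute_rdm(
    vectors_by_stimulus: dict[str, np.ndarray],
    grouping: str | tuple[str, ...] = "all_relevant",
    order: tuple[str, ...] | None = None,
    mode: str = "mean_regions",
) -> tuple[np.ndarray, tuple[str, ...]]:
    """4 x 4 representational dissimilarity matrix over the color stimuli.

    Distances are Euclidean; identical representations give 0. For a grouping
    of several regions, ``mean_regions`` (default) averages the per-region
    distances, ``concat`` measures the distance over the concatenated
    vectors.
    """
    regions = GROUPINGS[grouping] if isinstance(grouping, str) else tuple(grouping)
    order = order or tuple(vectors_by_stimulus)
    if len(order) == 0:
        raise ValueError("no stimuli provided")
    missing = [t for t in order if t not in vectors_by_stimulus]
    if missing:
        raise ValueError(f"missing stimuli: {missing}")
    idx = [AREA_INDEX[r] for r in regions]
    n = len(order)
    rdm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vi = vectors_by_stimulus[order[i]][idx]
            vj = vectors_by_stimulus[order[j]][idx]
            if mode == "concat":
                d = float(np.linalg.norm(vi.ravel() - vj.ravel()))
            else:
                d = float(np.mean(np.linalg.norm(vi - vj, axis=1)))
            rdm[i, j] = rdm[j, i] = d
    return rdm, order


@dataclass(frozen=True)
class NeuronTypeCounts:
    """Shared/unique decomposition of two shade assemblies, per region."""

    color: str
    shared: dict[str, int]
    unique_light: dict[str, int]
    unique_dark: dict[str, int]

    def shared_total(self, regions) -> int:
        return sum(self.shared[r] for r in regions)

    def unique_total(self, regions) -> int:
        return sum(self.unique_light[r] + self.unique_dark[r] for r in regions)

    def sharedness(self, regions) -> float:
        """Percentage of shared neurons: shared / (shared + unique) * 100."""
        s = self.shared_total(regions)
        u = self.unique_total(regions)
        if s + u == 0:
            return float("nan")
        return 100.0 * s / (s + u)


def count_shared_unique(
    ca_light: CellAssembly, ca_dark: CellAssembly, color: str = ""
) -> NeuronTypeCounts:
    """Per region: shared = |light ∩ dark|; unique = members of exactly one shade."""
    shared, ul, ud = {}, {}, {}
    for r in AREA_NAMES:
        light, dark = ca_light.in_region(r), ca_dark.in_region(r)
        shared[r] = len(light & dark)
        ul[r] = len(light - dark)
        ud[r] = len(dark - light)
    return NeuronTypeCounts(color=color, shared=shared, unique_light=ul, unique_dark=ud)


@dataclass(frozen=True)
class MMNTrace:
    """Within-assembly spike counts per recorded step for one presented shade.

    ``unique = r_total - r_shared``: the response of neurons responsive to the
    presented shade only, the model's proxy for the (visual) mismatch
    negativity deviant response.
    """

    tag: str
    r_total: np.ndarray
    r_shared: np.ndarray

    @property
    def unique(self) -> np.ndarray:
        return self.r_total - self.r_shared

    def window_mean(self, offset_step: int, lo: int = 2, hi: int = 12) -> float:
        """Mean unique response over post-offset steps [lo, hi) (10 steps)."""
        return float(self.unique[offset_step + lo:offset_step + hi].mean())


def mmn_trace(
    raster: np.ndarray,
    ca_presented: CellAssembly,
    ca_other: CellAssembly,
    regions=GROUPINGS["all_relevant"],
) -> MMNTrace:
    """Total and shared within-CA spike counts per step, summed over regions.

    ``ca_presented``/``ca_other`` are the responsive-cell sets of the
    presented and the sibling shade (the 20% rule aligned with CA
    extraction); shared cells are responsive to both shades.
    """
    resp = sorted(ca_presented.global_cells(regions))
    shared = sorted(ca_presented.global_cells(regions) & ca_other.global_cells(regions))
    r_total = raster[:, resp].sum(axis=1).astype(np.int64) if resp else np.zeros(raster.shape[0], dtype=np.int64)
    r_shared = raster[:, shared].sum(axis=1).astype(np.int64) if shared else np.zeros(raster.shape[0], dtype=np.int64)
    return MMNTrace(tag=ca_presented.tag, r_total=r_total, r_shared=r_shared)


def exclude_networks(
    cas_per_network: list[dict[str, CellAssembly]],
    params: SimulationParams,
    regions=GROUPINGS["all_relevant"],
) -> list[bool]:
    """Flag instantiations whose color assemblies merged or overgrew.

    A network is flagged when any two of its color assemblies exceed the
    Jaccard-overlap ceiling over the relevant regions, or when a single
    stimulus recruits more than the recruitment-ceiling fraction of any
    area's e-cells.
    """
    flags = []
    for cas in cas_per_network:
        flagged = False
        tags = list(cas)
        sets = {t: cas[t].global_cells(regions) for t in tags}
        for i, a in enumerate(tags):
            for b in tags[i + 1:]:
                union = sets[a] | sets[b]
                if union and len(sets[a] & sets[b]) / len(union) > params.exclude_jaccard:
                    flagged = True
        for t in tags:
            for r in AREA_NAMES:
                if len(cas[t].in_region(r)) > params.exclude_recruitment * CELLS_PER_AREA:
                    flagged = True
        flags.append(flagged)
    return flags


# ----------------------------------------------------------------------
# experiment-level aggregation


@dataclass
class ExperimentAnalysis:
    """All derived quantities of one experiment, tidy and per network."""

    assemblies: list[dict[str, dict[str, CellAssembly]]]          # [net][model][tag] gamma_ca
    assemblies_responsive: list[dict[str, dict[str, CellAssembly]]]  # 20% rule
    vectors: list[dict[str, dict[str, np.ndarray]]]
    excluded: list[bool]
    dissimilarity: pd.DataFrame   # network, model, grouping, color, value
    neuron_types: pd.DataFrame    # network, model, grouping, color, shared, unique
    sharedness: pd.DataFrame      # network, model, region, color, pct
    mmn: pd.DataFrame             # network, model, color, unique_response

    def retained(self) -> list[int]:
        return [i for i, x in enumerate(self.excluded) if not x]


def analyze_experiment(result, params: SimulationParams | None = None) -> ExperimentAnalysis:
    """Run the full quantification pipeline over an `ExperimentResult`."""
    params = params or result.plan.params
    n_networks = len(result.rate_tensors)
    offset = params.recog_baseline_steps + params.stim_steps_recog

    assemblies, assemblies_resp, vectors = [], [], []
    diss_rows, type_rows, shard_rows, mmn_rows = [], [], [], []
    diverged = list(getattr(result, "diverged", [])) or [False] * n_networks
    for i in range(n_networks):
        cas_i, resp_i, vec_i = {}, {}, {}
        for model, tensors in result.rate_tensors[i].items():
            cas_i[model] = {
                tag: extract_assembly(t, params, tag=tag) for tag, t in tensors.items()
            }
            resp_i[model] = {
                tag: extract_assembly(t, params, tag=tag, gamma=params.gamma_responsive)
                for tag, t in tensors.items()
            }
            vec_i[model] = {tag: activation_vectors(t) for tag, t in tensors.items()}
        assemblies.append(cas_i)
        assemblies_resp.append(resp_i)
        vectors.append(vec_i)

        for model in cas_i:
            for grouping in GROUPINGS:
                for color, (lt, dk) in COLOR_PAIRS.items():
                    rdm, order = compute_rdm(vec_i[model], grouping, order=(lt, dk))
                    diss_rows.append(
                        dict(network=i, model=model, grouping=grouping,
                             color=color, value=rdm[0, 1])
                    )
            for color, (lt, dk) in COLOR_PAIRS.items():
                counts = count_shared_unique(cas_i[model][lt], cas_i[model][dk], color)
                for grouping, regions in GROUPINGS.items():
                    type_rows.append(
                        dict(network=i, model=model, grouping=grouping, color=color,
                             shared=counts.shared_total(regions),
                             unique=counts.unique_total(regions))
                    )
                for r in GROUPINGS["all_relevant"]:
                    shard_rows.append(
                        dict(network=i, model=model, region=r, color=color,
                             pct=counts.sharedness((r,)))
                    )
        for model, rasters in result.rasters[i].items():
            for color, (lt, dk) in COLOR_PAIRS.items():
                per_shade = []
                for presented, other in ((lt, dk), (dk, lt)):
                    tr = mmn_trace(
                        rasters[presented],
                        resp_i[model][presented], resp_i[model][other],
                    )
                    per_shade.append(tr.window_mean(offset))
                mmn_rows.append(
                    dict(network=i, model=model, color=color,
                         unique_response=float(np.mean(per_shade)))
                )

    # exclusion: a network is dropped if it diverged during learning or its
    # assemblies merged in any trained model type
    flags = list(diverged)
    for model in result.model_types:
        idx = [i for i in range(n_networks) if model in assemblies[i]]
        per_net = [assemblies[i][model] for i in idx]
        for i, f in zip(idx, exclude_networks(per_net, params)):
            flags[i] = flags[i] or f

    return ExperimentAnalysis(
        assemblies=assemblies,
        assemblies_responsive=assemblies_resp,
        vectors=vectors,
        excluded=flags,
        dissimilarity=pd.DataFrame(diss_rows),
        neuron_types=pd.DataFrame(type_rows),
        sharedness=pd.DataFrame(shard_rows),
        mmn=pd.DataFrame(mmn_rows),
    )


def summarize(analysis: ExperimentAnalysis, retained_only: bool = True) -> dict[str, pd.DataFrame]:
    """Per-model mean and sd tables over (retained) networks.

    Returns tidy tables for grouped dissimilarities, shared/unique counts,
    per-region sharedness and the MMN blue-green unique-response contrast.
    The accompanying statistics are descriptive.
    """
    keep = analysis.retained() if retained_only else list(range(len(analysis.excluded)))
    if len(keep) == 0:
        raise ValueError("all networks were excluded")

    def _f(df: pd.DataFrame) -> pd.DataFrame:
        return df[df["network"].isin(keep)]

    diss = (
        _f(analysis.dissimilarity)
        .groupby(["model", "grouping", "color"])["value"]
        .agg(["mean", "std"])
        .reset_index()
    )
    types = (
        _f(analysis.neuron_types)
        .groupby(["model", "grouping", "color"])[["shared", "unique"]]
        .agg(["mean", "std"])
        .reset_index()
    )
    shard = (
        _f(analysis.sharedness)
        .groupby(["model", "region", "color"])["pct"]
        .agg(["mean", "std"])
        .reset_index()
    )
    mmn = (
        _f(analysis.mmn)
        .groupby(["model", "color"])["unique_response"]
        .agg(["mean", "std"])
        .reset_index()
    )
    return {"dissimilarity": diss, "neuron_types": types, "sharedness": shard, "mmn": mmn}
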