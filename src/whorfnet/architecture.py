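"""Macro-architecture: 12 cortical areas and their sparse random synapses.

The network mimics three processing streams of frontotemporal-occipital
cortex, each a chain of a primary, a secondary, and a multimodal hub area:

* ventral visual stream      V1 - TO - AT
* dorsolateral motor stream  M1L - PML - PFL
* auditory stream            A1 - AB - PB
* articulatory stream        M1i - PMi - PFi

The four hubs (AT, PFL, PB, PFi) are fully interconnected, and each stream
additionally carries a "jumping" link from its primary area to its hub. Each
area holds a 25 x 25 grid of excitatory (e) cells, each with a twin graded
inhibitory (i) cell, 15,000 cells in total. Synapses are sampled from
clipped-Gaussian topographic kernels and are initially weak and random; only
e-to-e links are plastic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .params import KernelSpec, SimulationParams

GRID = 25
CELLS_PER_AREA = GRID * GRID

AREA_NAMES = (
    "V1", "TO", "AT", "PFL", "PML", "M1L",
    "A1", "AB", "PB", "PFi", "PMi", "M1i",
)
N_AREAS = len(AREA_NAMES)
N_E = N_AREAS * CELLS_PER_AREA
AREA_INDEX = {name: i for i, name in enumerate(AREA_NAMES)}

PRIMARY_AREAS = ("V1", "M1L", "A1", "M1i")
HUB_AREAS = ("AT", "PFL", "PB", "PFi")
SECONDARY_AREAS = ("TO", "PML", "AB", "PMi")

#: Region groupings used throughout the analyses.
GROUPINGS: dict[str, tuple[str, ...]] = {
    "visual": ("V1", "TO", "AT"),
    "auditory": ("A1", "AB", "PB"),
    "articulatory": ("PFi", "PMi", "M1i"),
    "hubs": HUB_AREAS,
    "all_relevant": ("V1", "TO", "AT", "PFL", "A1", "AB", "PB", "PFi", "PMi", "M1i"),
}


@dataclass(frozen=True)
class ConnectivityGraph:
    """Undirected list of between-area links (projections are reciprocal)."""

    edges: frozenset[frozenset[str]]

    @classmethod
    def default(cls) -> "ConnectivityGraph":
        adjacent = [
            ("V1", "TO"), ("TO", "AT"),
            ("M1L", "PML"), ("PML", "PFL"),
            ("A1", "AB"), ("AB", "PB"),
            ("M1i", "PMi"), ("PMi", "PFi"),
        ]
        jumping = [("V1", "AT"), ("M1L", "PFL"), ("A1", "PB"), ("M1i", "PFi")]
        hub_hub = [
            (a, b) for i, a in enumerate(HUB_AREAS) for b in HUB_AREAS[i + 1:]
        ]
        return cls.from_pairs(adjacent + jumping + hub_hub)

    @classmethod
    def from_pairs(cls, pairs) -> "ConnectivityGraph":
        edges = set()
        for a, b in pairs:
            if a == b:
                raise ValueError(f"self-edge {a!r}")
            if a not in AREA_INDEX or b not in AREA_INDEX:
                raise ValueError(f"unknown area in edge ({a!r}, {b!r})")
            edges.add(frozenset((a, b)))
        return cls(edges=frozenset(edges))

    def directed_pairs(self) -> list[tuple[str, str]]:
        out = []
        for e in self.edges:
            a, b = sorted(e)
            out.append((a, b))
            out.append((b, a))
        return sorted(out)

    def has_edge(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.edges


def default_connectivity_graph() -> ConnectivityGraph:
    return ConnectivityGraph.default()


def kernel_probability(offset: tuple[int, int], kind: str, params: SimulationParams) -> float:
    """Link-creation probability for a cell at grid offset ``(dx, dy)``.

    ``p = center_prob * exp(-(dx^2 + dy^2) / (2 sigma^2))`` within the kernel's
    square neighborhood, 0 outside of it.
    """
    spec: KernelSpec = {
        "ee_within": params.kernel_ee_within,
        "ee_between": params.kernel_ee_between,
        "ie": params.kernel_ie,
    }[kind]
    dx, dy = offset
    half = spec.neighborhood // 2
    if abs(dx) > half or abs(dy) > half:
        return 0.0
    return spec.center_prob * float(np.exp(-(dx * dx + dy * dy) / (2.0 * spec.sigma**2)))


def _kernel_grid(spec: KernelSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Offsets and probabilities over the kernel's neighborhood square."""
    half = spec.neighborhood // 2
    d = np.arange(-half, half + 1)
    dx, dy = np.meshgrid(d, d, indexing="ij")
    p = spec.center_prob * np.exp(-(dx**2 + dy**2) / (2.0 * spec.sigma**2))
    return dx.ravel(), dy.ravel(), p.ravel()


def _target_indices(dx: np.ndarray, dy: np.ndarray, toroidal: bool):
    """Per-source-cell target cell indices for each kernel offset.

    Returns (targets, valid) of shape (625, n_offsets); topography maps cell
    (r, c) of the source area onto cell (r, c) of the target area as the
    neighborhood center.
    """
    r = np.arange(GRID)
    rr, cc = np.meshgrid(r, r, indexing="ij")
    rr = rr.ravel()[:, None] + dx[None, :]
    cc = cc.ravel()[:, None] + dy[None, :]
    if toroidal:
        rr %= GRID
        cc %= GRID
        valid = np.ones(rr.shape, dtype=bool)
    else:
        valid = (rr >= 0) & (rr < GRID) & (cc >= 0) & (cc < GRID)
        rr = np.clip(rr, 0, GRID - 1)
        cc = np.clip(cc, 0, GRID - 1)
    return rr * GRID + cc, valid


@dataclass
class SynapseMap:
    """One synapse class in compressed sparse column (by presynaptic cell) form.

    ``indptr[pre]:indptr[pre+1]`` slices ``post``/``w`` to the outgoing links
    of presynaptic cell ``pre``. Weights are stored non-negative; inhibitory
    contributions acquire their negative sign in the input equation.
    """

    indptr: np.ndarray
    post: np.ndarray
    w: np.ndarray
    n_pre: int
    n_post: int

    @classmethod
    def from_coo(cls, pre, post, w, n_pre: int, n_post: int) -> "SynapseMap":
        m = sp.csc_matrix(
            (np.asarray(w, dtype=np.float64), (np.asarray(post), np.asarray(pre))),
            shape=(n_post, n_pre),
        )
        m.sort_indices()
        return cls(
            indptr=m.indptr.astype(np.int64),
            post=m.indices.astype(np.int64),
            w=m.data,
            n_pre=n_pre,
            n_post=n_post,
        )

    _csr_cache: tuple[np.ndarray, np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    @property
    def nnz(self) -> int:
        return int(self.w.size)

    def to_csr_aux(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Row-major (by postsynaptic cell) view into the column-major data.

        Returns ``(indptr_by_post, pre, datapos)`` where ``datapos`` indexes
        into ``self.w`` so the same weight storage serves both traversals.
        The structure is fixed after sampling, so the view is cached.
        """
        if self._csr_cache is None:
            csc = sp.csc_matrix(
                (np.arange(self.nnz, dtype=np.int64), self.post, self.indptr),
                shape=(self.n_post, self.n_pre),
            )
            csr = csc.tocsr()
            self._csr_cache = (
                csr.indptr.astype(np.int64),
                csr.indices.astype(np.int64),
                csr.data.astype(np.int64),
            )
        return self._csr_cache


@dataclass
class Network:
    """A sampled 12-area network: weights, graph, params, and its seed."""

    params: SimulationParams
    graph: ConnectivityGraph
    seed: int
    ee: SynapseMap   # e -> e, plastic
    ei: SynapseMap   # e -> i, static
    ie: SynapseMap   # i -> e, static (applied with negative sign)

    @property
    def n_cells(self) -> int:
        return 2 * N_E

    def copy(self) -> "Network":
        import copy as _copy

        return Network(
            params=self.params,
            graph=self.graph,
            seed=self.seed,
            ee=_copy.deepcopy(self.ee),
            ei=_copy.deepcopy(self.ei),
            ie=_copy.deepcopy(self.ie),
        )

    def weight_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for m in (self.ee, self.ei, self.ie):
            h.update(m.w.tobytes())
            h.update(m.post.tobytes())
        return h.hexdigest()[:16]


def _sample_block(rng, spec: KernelSpec, toroidal: bool):
    """Sample one 625 x 625 projection block; returns (pre, post) index arrays."""
    dx, dy, p = _kernel_grid(spec)
    targets, valid = _target_indices(dx, dy, toroidal)
    hit = (rng.random(targets.shape) < p[None, :]) & valid
    pre_idx, off_idx = np.nonzero(hit)
    return pre_idx, targets[pre_idx, off_idx]


def sample_synapses(
    graph: ConnectivityGraph, params: SimulationParams, seed: int
) -> Network:
    """Instantiate a network's synapses, reproducibly from ``seed``.

    Within-area e-to-e links use the 19 x 19 / sigma 6.5 kernel (center 0.28),
    between-area e-to-e links (only for area pairs in the graph) the
    19 x 19 / sigma 4.5 kernel (center 0.15), and the local inhibitory loop
    (e-to-i and i-to-e) the 5 x 5 / sigma 2.0 kernel (center 0.295). Created
    weights are uniform in [0, w_init_max].
    """
    if seed is None:
        raise ValueError("a connectivity seed is required (reproducibility is mandatory)")
    rng = np.random.default_rng(seed)
    tor = params.toroidal

    ee_pre, ee_post = [], []
    # within-area e->e
    for a in range(N_AREAS):
        pre, post = _sample_block(rng, params.kernel_ee_within, tor)
        base = a * CELLS_PER_AREA
        ee_pre.append(pre + base)
        ee_post.append(post + base)
    # between-area e->e, in a fixed traversal order
    for src, dst in graph.directed_pairs():
        pre, post = _sample_block(rng, params.kernel_ee_between, tor)
        ee_pre.append(pre + AREA_INDEX[src] * CELLS_PER_AREA)
        ee_post.append(post + AREA_INDEX[dst] * CELLS_PER_AREA)
    ee_pre = np.concatenate(ee_pre)
    ee_post = np.concatenate(ee_post)
    ee_w = rng.uniform(0.0, params.w_init_max, size=ee_pre.size)

    # local inhibitory loop, per area: e->i (mirrored kernel) and i->e
    ei_pre, ei_post, ie_pre, ie_post = [], [], [], []
    for a in range(N_AREAS):
        base = a * CELLS_PER_AREA
        pre, post = _sample_block(rng, params.kernel_ie, tor)
        ei_pre.append(pre + base)
        ei_post.append(post + base)
        pre, post = _sample_block(rng, params.kernel_ie, tor)
        ie_pre.append(pre + base)
        ie_post.append(post + base)
    ei_pre = np.concatenate(ei_pre)
    ei_post = np.concatenate(ei_post)
    ei_w = rng.uniform(0.0, params.w_init_max, size=ei_pre.size)
    ie_pre = np.concatenate(ie_pre)
    ie_post = np.concatenate(ie_post)
    ie_w = rng.uniform(0.0, params.w_init_max, size=ie_pre.size)

    return Network(
        params=params,
        graph=graph,
        seed=int(seed),
        ee=SynapseMap.from_coo(ee_pre, ee_post, ee_w, N_E, N_E),
        ei=SynapseMap.from_coo(ei_pre, ei_post, ei_w, N_E, N_E),
        ie=SynapseMap.from_coo(ie_pre, ie_post, ie_w, N_E, N_E),
    )


def area_slice(name: str) -> slice:
    i = AREA_INDEX[name]
    return slice(i * CELLS_PER_AREA, (i + 1) * CELLS_PER_AREA)


def global_index(area: str, cells: np.ndarray) -> np.ndarray:
    return AREA_INDEX[area] * CELLS_PER_AREA + np.asarray(cells, dtype=np.int64)
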