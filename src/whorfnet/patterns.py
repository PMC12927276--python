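"""Synthetic sensorimotor stimulation patterns.

Four color patterns over V1 with a prescribed overlap structure (two shades of
blue and of green; shades of one color share 5 of their 22 cells, nominally
22.8%, and blue/green patterns share 1 cell, nominally 5%), plus three word
form patterns, each a pair of 22-cell sets in the auditory (A1) and
articulatory (M1i) primary areas with no overlap among words within an area.

All patterns are index sets over the 625 e-cells of their target area and are
deterministic functions of the generation seed, so the same stimuli can be
shared across all simulated learners.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

CELLS_PER_AREA = 625
PATTERN_SIZE = 22
WITHIN_COLOR_SHARED = round(0.228 * PATTERN_SIZE)   # 5 cells
BETWEEN_COLOR_SHARED = round(0.05 * PATTERN_SIZE)   # 1 cell

COLOR_TAGS = ("blue_light", "blue_dark", "green_light", "green_dark")
WORD_TAGS = tuple(f"word{i}_{m}" for i in (1, 2, 3) for m in ("aud", "art"))


@dataclass(frozen=True)
class InputPattern:
    """A 22-cell binary activation pattern over one primary area."""

    area: str
    cells: frozenset[int]
    tag: str

    def __post_init__(self) -> None:
        if len(self.cells) != PATTERN_SIZE:
            raise ValueError(f"{self.tag}: expected {PATTERN_SIZE} cells, got {len(self.cells)}")
        if any(not 0 <= c < CELLS_PER_AREA for c in self.cells):
            raise ValueError(f"{self.tag}: cell index outside 0..{CELLS_PER_AREA - 1}")

    @property
    def indices(self) -> np.ndarray:
        return np.array(sorted(self.cells), dtype=np.int64)


@dataclass(frozen=True)
class PatternSet:
    """The four color patterns, three word-form pattern pairs, and their seed."""

    colors: dict[str, InputPattern]
    words: dict[str, InputPattern]
    seed: int

    def color(self, tag: str) -> InputPattern:
        return self.colors[tag]

    def word(self, index: int, modality: str) -> InputPattern:
        return self.words[f"word{index}_{modality}"]

    def overlap_matrix(self) -> np.ndarray:
        """Pairwise shared-cell counts among the four color patterns."""
        sets = [self.colors[t].cells for t in COLOR_TAGS]
        return np.array([[len(a & b) for b in sets] for a in sets], dtype=np.int64)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "seed": self.seed,
            "colors": {t: {"area": p.area, "cells": sorted(p.cells)} for t, p in self.colors.items()},
            "words": {t: {"area": p.area, "cells": sorted(p.cells)} for t, p in self.words.items()},
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PatternSet":
        payload = json.loads(Path(source).read_text())
        colors = {
            t: InputPattern(d["area"], frozenset(d["cells"]), t)
            for t, d in payload["colors"].items()
        }
        words = {
            t: InputPattern(d["area"], frozenset(d["cells"]), t)
            for t, d in payload["words"].items()
        }
        return cls(colors=colors, words=words, seed=int(payload["seed"]))


def _draw(rng: np.random.Generator, pool: np.ndarray, n: int) -> np.ndarray:
    return rng.choice(pool, size=n, replace=False)


def generate_color_patterns(seed: int) -> dict[str, InputPattern]:
    """Construct the four V1 color patterns honoring the overlap invariants.

    Each shade-pair of one color shares a 5-cell core, and every blue-shade x
    green-shade pair shares exactly one bridge cell of its own, drawn outside
    the within-color cores so the cores stay at exactly 5 shared cells. Each
    shade thus consists of its color's 5-cell core, two cross-color bridge
    cells (one per opposite shade), and 15 private cells.
    """
    rng = np.random.default_rng(seed)
    pool = np.arange(CELLS_PER_AREA)
    # disjoint blocks: two 5-cell cores, four 1-cell bridges, 4 x 15 private
    n_bridge = 2 * BETWEEN_COLOR_SHARED
    n_private = PATTERN_SIZE - WITHIN_COLOR_SHARED - n_bridge
    blocks = _draw(
        rng, pool,
        2 * WITHIN_COLOR_SHARED + 4 * BETWEEN_COLOR_SHARED + 4 * n_private,
    )
    pos = 0

    def take(n: int) -> frozenset[int]:
        nonlocal pos
        out = frozenset(int(c) for c in blocks[pos:pos + n])
        pos += n
        return out

    blue_core = take(WITHIN_COLOR_SHARED)
    green_core = take(WITHIN_COLOR_SHARED)
    # bridge[(i, j)] is shared between blue shade i and green shade j
    bridges = {(i, j): take(BETWEEN_COLOR_SHARED) for i in range(2) for j in range(2)}
    patterns = {}
    for k, (tag, core) in enumerate((
        ("blue_light", blue_core),
        ("blue_dark", blue_core),
        ("green_light", green_core),
        ("green_dark", green_core),
    )):
        if k < 2:  # blue shade k bridges to both green shades
            bridge = bridges[(k, 0)] | bridges[(k, 1)]
        else:      # green shade (k - 2) bridges to both blue shades
            bridge = bridges[(0, k - 2)] | bridges[(1, k - 2)]
        patterns[tag] = InputPattern("V1", core | bridge | take(n_private), tag)
    return patterns


def generate_word_patterns(seed: int) -> dict[str, InputPattern]:
    """Three word-form patterns: pairwise-disjoint 22-cell sets in A1 and M1i."""
    rng = np.random.default_rng(seed)
    words: dict[str, InputPattern] = {}
    for modality, area in (("aud", "A1"), ("art", "M1i")):
        cells = _draw(rng, np.arange(CELLS_PER_AREA), 3 * PATTERN_SIZE)
        for i in range(3):
            tag = f"word{i + 1}_{modality}"
            chunk = frozenset(int(c) for c in cells[i * PATTERN_SIZE:(i + 1) * PATTERN_SIZE])
            words[tag] = InputPattern(area, chunk, tag)
    return words


def generate_pattern_set(seed: int) -> PatternSet:
    """The full stimulus inventory, deterministic from ``seed``.

    Color and word draws use independent substreams of ``seed`` so that either
    half can be regenerated in isolation.
    """
    ss = np.random.SeedSequence(seed).spawn(2)
    colors = generate_color_patterns(int(ss[0].generate_state(1)[0] % (2**31)))
    words = generate_word_patterns(int(ss[1].generate_state(1)[0] % (2**31)))
    return PatternSet(colors=colors, words=words, seed=seed)


def fresh_noise_drive(
    rng: np.random.Generator,
    inp_strength: float,
    n_cells: int = CELLS_PER_AREA,
    form: str = "pattern",
) -> np.ndarray:
    """Uncorrelated drive for a non-relevant primary area, fresh every trial.

    ``form="pattern"`` (default) drives a newly drawn random 22-cell pattern
    at full input strength, mirroring the structure of the learned stimuli
    while remaining uncorrelated across trials. ``form="uniform"`` spreads a
    nonnegative random drive over all cells of the area instead. Either way
    the total delivered strength matches a 22-cell pattern (``22 * Inp``).
    """
    total = PATTERN_SIZE * inp_strength
    if form == "pattern":
        drive = np.zeros(n_cells)
        cells = rng.choice(n_cells, size=PATTERN_SIZE, replace=False)
        drive[cells] = inp_strength
        return drive
    if form != "uniform":
        raise ValueError(f"unknown noise drive form: {form!r}")
    u = rng.random(n_cells)
    s = u.sum()
    if s == 0.0:  # pragma: no cover - probability zero
        return np.full(n_cells, total / n_cells)
    return u * (total / s)
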