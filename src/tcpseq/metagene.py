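"""Metagene heatmaps (length x end position), projections and mode finding.

The central visualisation of translation-complex profiling: footprints from
all genes are pooled, one end (5' or 3') is expressed relative to an anchor
(the start codon or the TSS), and counts are accumulated on a (length,
position) grid. Summing over lengths gives the x-axis projection, whose local
maxima locate the discrete complexes (e.g. the -12 initiation 5' end, or the
+19/+25 pair of 3' ends at start codons).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import TranscriptModel
from .footprints import Footprint, LENGTH_MAX, LENGTH_MIN

DEFAULT_RANGE_START_ANCHOR = (-100, 50)
DEFAULT_RANGE_TSS_ANCHOR = (-10, 150)
DEFAULT_MIN_SEPARATION = 4


@dataclass(frozen=True)
class HeatmapMatrix:
    anchor: str  # "start_codon" | "tss"
    end: str  # "five_prime" | "three_prime"
    pos_range: tuple[int, int]  # inclusive
    len_range: tuple[int, int]
    counts: np.ndarray  # (n_lengths, n_positions), int
    n_excluded: int

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.pos_range[0], self.pos_range[1] + 1)

    @property
    def lengths(self) -> np.ndarray:
        return np.arange(self.len_range[0], self.len_range[1] + 1)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.lengths, columns=self.positions)


@dataclass(frozen=True)
class Projection:
    positions: np.ndarray
    values: np.ndarray

    @property
    def total(self) -> int:
        return int(self.values.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.positions, "count": self.values})


def build_heatmap(
    fps: Sequence[Footprint],
    anchor: str = "start_codon",
    end: str = "five_prime",
    pos_range: tuple[int, int] | None = None,
    models: Mapping[str, TranscriptModel] | None = None,
) -> HeatmapMatrix:
    """Accumulate footprints on a (length, end-position-relative-to-anchor) grid.

    Footprints whose chosen end falls outside ``pos_range`` are excluded and
    counted in ``n_excluded``. TSS anchoring needs the transcript models to
    recover each footprint's TSS offset.
    """
    if anchor not in ("start_codon", "tss"):
        raise ValueError(f"unknown anchor {anchor!r}")
    if end not in ("five_prime", "three_prime"):
        raise ValueError(f"unknown end {end!r}")
    if pos_range is None:
        pos_range = DEFAULT_RANGE_START_ANCHOR if anchor == "start_codon" else DEFAULT_RANGE_TSS_ANCHOR
    if anchor == "tss" and models is None:
        raise ValueError("TSS anchoring requires transcript models")
    lo, hi = pos_range
    if lo > hi:
        raise ValueError("invalid pos_range")
    counts = np.zeros((LENGTH_MAX - LENGTH_MIN + 1, hi - lo + 1), dtype=np.int64)
    excluded = 0
    for fp in fps:
        if anchor == "start_codon":
            x = fp.rel5 if end == "five_prime" else fp.rel3
        else:
            tss = models[fp.transcript_id].tss_pos
            x = (fp.start if end == "five_prime" else fp.start + fp.length - 1) - tss
        if not lo <= x <= hi:
            excluded += 1
            continue
        counts[fp.length - LENGTH_MIN, x - lo] += 1
    return HeatmapMatrix(anchor, end, (lo, hi), (LENGTH_MIN, LENGTH_MAX), counts, excluded)


def project(m: HeatmapMatrix) -> Projection:
    """Column sums of the heatmap (counts per position over all lengths)."""
    return Projection(m.positions.copy(), m.counts.sum(axis=0))


def length_histogram(fps: Sequence[Footprint]) -> Projection:
    """Footprint length histogram over the gel-cut range, as a Projection."""
    lengths = np.arange(LENGTH_MIN, LENGTH_MAX + 1)
    values = np.zeros_like(lengths)
    for fp in fps:
        values[fp.length - LENGTH_MIN] += 1
    return Projection(lengths, values)


def find_modes(
    p: Projection,
    k: int = 1,
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> tuple[list[int], bool]:
    """Top-k local maxima of a projection, greedily spaced >= min_separation.

    Candidates are local maxima of the count vector (plateau edges included);
    they are taken in decreasing height, ties broken toward the smaller
    position. Returns (positions, complete) where ``complete`` is False when
    fewer than k admissible modes exist.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    v = np.asarray(p.values)
    pos = np.asarray(p.positions)
    n = v.size
    cand = [
        i
        for i in range(n)
        if v[i] > 0
        and (i == 0 or v[i] >= v[i - 1])
        and (i == n - 1 or v[i] >= v[i + 1])
    ]
    cand.sort(key=lambda i: (-v[i], pos[i]))
    chosen: list[int] = []
    for i in cand:
        if len(chosen) == k:
            break
        if all(abs(int(pos[i]) - c) >= min_separation for c in chosen):
            chosen.append(int(pos[i]))
    return chosen, len(chosen) == k
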