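"""Per-gene coverage tracks, full footprint span, optionally length-segmented.

Unlike the metagene heatmaps (which place only one footprint end), per-gene
tracks count, at every position, the number of footprints whose whole
``[rel5, rel3]`` span covers it. Tracks are normalised by their own maximum
for plotting; length-segmented tracks share the all-lengths maximum so the
three bins remain comparable on one axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import TranscriptModel
from .footprints import Footprint

BINS = ("short", "mid", "long")
CDS_PLOT_EXTENT = 60  # nt of CDS included in the default plotting region


@dataclass(frozen=True)
class Track:
    transcript_id: str
    library: str
    rel_positions: np.ndarray  # signed nt, start-codon-relative
    coverage: np.ndarray

    def __post_init__(self) -> None:
        if len(self.rel_positions) != len(self.coverage):
            raise ValueError("positions and coverage differ in length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"rel_position": self.rel_positions, "coverage": self.coverage})


def default_region(model: TranscriptModel) -> tuple[int, int]:
    """TSS - 10 to start codon + 60, start-codon-relative (inclusive)."""
    return (-model.utr5_len - 10, CDS_PLOT_EXTENT)


def gene_track(
    fps: Sequence[Footprint],
    model: TranscriptModel,
    region_range: tuple[int, int] | None = None,
) -> Track:
    """Full-span coverage for one transcript/library over a relative range."""
    lo, hi = region_range if region_range is not None else default_region(model)
    diff = np.zeros(hi - lo + 2, dtype=np.int64)
    library = fps[0].library if fps else "NA"
    for fp in fps:
        if fp.transcript_id != model.id:
            raise ValueError(f"footprint on {fp.transcript_id}, track for {model.id}")
        if fp.library != library:
            raise ValueError("gene_track expects a single library")
        a = max(fp.rel5, lo)
        b = min(fp.rel3, hi)
        if a > b:
            continue
        diff[a - lo] += 1
        diff[b - lo + 1] -= 1
    return Track(model.id, library, np.arange(lo, hi + 1), np.cumsum(diff[:-1]))


def normalize_track(t: Track) -> Track:
    """Divide by the track maximum (which becomes 1.0); all-zero is an error."""
    peak = t.coverage.max() if t.coverage.size else 0
    if peak <= 0:
        raise ValueError(f"cannot normalise an all-zero track ({t.transcript_id})")
    return Track(t.transcript_id, t.library, t.rel_positions.copy(), t.coverage / peak)


def length_segmented_tracks(
    fps: Sequence[Footprint],
    model: TranscriptModel,
    region_range: tuple[int, int] | None = None,
    normalize: bool = True,
) -> dict[str, Track]:
    """One track per length bin, all divided by the single all-lengths maximum.

    With ``normalize=False`` the raw integer bin tracks are returned; their
    position-wise sum is exactly the all-lengths track.
    """
    lo_hi = region_range if region_range is not None else default_region(model)
    tracks = {
        b: gene_track([fp for fp in fps if fp.length_bin == b], model, lo_hi) for b in BINS
    }
    library = fps[0].library if fps else "NA"
    tracks = {
        b: Track(model.id, library, t.rel_positions, t.coverage) for b, t in tracks.items()
    }
    if not normalize:
        return tracks
    all_lengths = gene_track(fps, model, lo_hi)
    peak = all_lengths.coverage.max() if all_lengths.coverage.size else 0
    if peak <= 0:
        raise ValueError(f"cannot normalise an all-zero track ({model.id})")
    return {
        b: Track(model.id, library, t.rel_positions, t.coverage / peak)
        for b, t in tracks.items()
    }
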