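"""Occupancy statistics for scanning-subunit data.

* **SSU peak coverage** — per gene, the highest 40S coverage peak in the 5'
  UTR divided by the sum of that peak and the AUG-window peak:
  ``coverage = h_utr / (h_utr + h_aug)``. Values near 0 mean subunits pile up
  only at the initiation site; values near 1 mean the leader dominates.
* **Window fraction** — for a long regulated leader, the fraction of 40S
  footprint 5' ends falling in a distal leader window, per replicate and
  condition, with the treated/untreated fold change and a two-sided paired
  t-test across replicate pairs.
* **Translational efficiency** — CDS-restricted 80S footprint density over
  CDS-restricted RNA-seq density, library-size normalised.
* **Reporter and qPCR arithmetic** — percent-of-reference fluorescence,
  log2 treated/untreated responses with paired t-tests, and
  efficiency-corrected qPCR ratios (ddCq).

The paired t statistic is computed from first principles (mean difference
over its standard error); only the t-distribution tail comes from scipy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .annotation import TranscriptModel
from .footprints import Footprint
from .profiles import Track

AUG_WINDOW = (-12, 35)  # rel5 window treated as "the AUG peak"
MIN_UTR5_FOR_PEAK = 5   # leaders shorter than this have no meaningful UTR peak


@dataclass(frozen=True)
class PeakCoverage:
    transcript_id: str
    h_utr: float
    h_aug: float
    coverage: float | None  # None when not computable

    @property
    def computable(self) -> bool:
        return self.coverage is not None


def ssu_peak_coverage(
    track_40s: Track,
    model: TranscriptModel,
    aug_window: tuple[int, int] = AUG_WINDOW,
) -> PeakCoverage:
    """Peak coverage from a (replicate-merged) 40S full-span coverage track.

    ``h_aug`` is the maximum coverage over rel positions [-12, +35]; ``h_utr``
    the maximum over [-utr5_len, -13]. Genes with leaders shorter than 5 nt,
    or with no signal in either window, are flagged not-computable.
    """
    pos = track_40s.rel_positions
    cov = track_40s.coverage
    if model.utr5_len < MIN_UTR5_FOR_PEAK:
        return PeakCoverage(model.id, 0.0, 0.0, None)
    utr_mask = (pos >= -model.utr5_len) & (pos <= -13)
    aug_mask = (pos >= aug_window[0]) & (pos <= aug_window[1])
    h_utr = float(cov[utr_mask].max()) if utr_mask.any() else 0.0
    h_aug = float(cov[aug_mask].max()) if aug_mask.any() else 0.0
    if h_utr + h_aug == 0:
        return PeakCoverage(model.id, h_utr, h_aug, None)
    return PeakCoverage(model.id, h_utr, h_aug, h_utr / (h_utr + h_aug))


def rank_by_peak_coverage(results: Sequence[PeakCoverage]) -> pd.DataFrame:
    """Computable genes ranked by descending coverage; ties broken by id."""
    rows = [
        {"transcript_id": r.transcript_id, "h_utr": r.h_utr, "h_aug": r.h_aug,
         "coverage": r.coverage}
        for r in results
        if r.computable
    ]
    frame = pd.DataFrame(rows, columns=["transcript_id", "h_utr", "h_aug", "coverage"])
    return frame.sort_values(
        ["coverage", "transcript_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, bool]:
    """Two-sided paired t-test; returns (t, p, degenerate).

    Zero difference variance is reported as p = 1.0 with the degenerate flag
    rather than an error (the paired design carries no information then).
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        return 0.0, 1.0, True
    t = float(d.mean() / (sd / math.sqrt(n)))
    p = float(2.0 * t_dist.sf(abs(t), n - 1))
    return t, p, False


@dataclass(frozen=True)
class WindowFractionStat:
    window: tuple[int, int]
    fractions_untreated: tuple[float, ...]
    fractions_treated: tuple[float, ...]
    fold: float
    t_stat: float | None
    p_value: float | None
    n_pairs: int
    degenerate: bool
    excluded_pairs: int


def _leader_fraction(
    fps: Sequence[Footprint], model: TranscriptModel, window: tuple[int, int]
) -> tuple[int, int]:
    """(5' ends in window, 5' ends anywhere in the 5' UTR) in TSS coordinates."""
    lo, hi = window
    n_win = n_utr = 0
    for fp in fps:
        if fp.transcript_id != model.id:
            continue
        rel_tss = fp.start - model.tss_pos
        if 0 <= rel_tss < model.utr5_len:
            n_utr += 1
            if lo <= rel_tss < hi:
                n_win += 1
    return n_win, n_utr


def window_fraction(
    fps_by_condition: Mapping[str, Sequence[Sequence[Footprint]]],
    model: TranscriptModel,
    window: tuple[int, int] = (720, 1200),
    untreated: str = "untreated",
    treated: str = "treated",
) -> WindowFractionStat:
    """Distal-window occupancy fold change across paired replicates.

    ``fps_by_condition`` maps condition name to a list of per-replicate 40S
    footprint collections (paired by index). Membership is by footprint 5'
    end (half-open window, TSS coordinates); the denominator is all 40S
    footprints with a 5' end in the annotated 5' UTR. Replicate pairs in
    which either denominator is zero are excluded with a count.
    """
    reps_u = fps_by_condition[untreated]
    reps_t = fps_by_condition[treated]
    if len(reps_u) != len(reps_t):
        raise ValueError("conditions must have the same number of replicates")
    fu: list[float] = []
    ft: list[float] = []
    excluded = 0
    for fps_u, fps_t in zip(reps_u, reps_t):
        wu, du = _leader_fraction(fps_u, model, window)
        wt, dt = _leader_fraction(fps_t, model, window)
        if du == 0 or dt == 0:
            excluded += 1
            continue
        fu.append(wu / du)
        ft.append(wt / dt)
    if not fu:
        raise ValueError("no replicate pair with leader footprints in both conditions")
    fold = float(np.mean(ft) / np.mean(fu)) if np.mean(fu) > 0 else math.inf
    if len(fu) >= 2:
        t, p, degenerate = paired_t_test(ft, fu)
    else:
        t, p, degenerate = None, None, False
    return WindowFractionStat(
        window=tuple(window),
        fractions_untreated=tuple(fu),
        fractions_treated=tuple(ft),
        fold=fold,
        t_stat=t,
        p_value=p,
        n_pairs=len(fu),
        degenerate=degenerate,
        excluded_pairs=excluded,
    )


@dataclass(frozen=True)
class TEValue:
    transcript_id: str
    fp_cds_count: int
    rna_cds_count: int
    lib_size_fp: int
    lib_size_rna: int
    te: float | None  # None when RNA coverage is absent


def translational_efficiency(
    transcript_id: str,
    fp_cds: int,
    rna_cds: int,
    lib_size_fp: int,
    lib_size_rna: int,
) -> TEValue:
    """80S footprint density over mRNA density, CDS-restricted.

    ``te = (fp_cds / lib_size_fp) / (rna_cds / lib_size_rna)``; any per-million
    scaling cancels, so TE is invariant under a common rescaling of both
    library sizes.
    """
    if min(fp_cds, rna_cds) < 0 or min(lib_size_fp, lib_size_rna) <= 0:
        raise ValueError("counts must be >= 0 and library sizes > 0")
    if rna_cds == 0:
        return TEValue(transcript_id, fp_cds, rna_cds, lib_size_fp, lib_size_rna, None)
    te = (fp_cds / lib_size_fp) / (rna_cds / lib_size_rna)
    return TEValue(transcript_id, fp_cds, rna_cds, lib_size_fp, lib_size_rna, te)


def reporter_stats(
    fluorescence: Mapping[str, Mapping[str, Sequence[float]]],
    reference_construct: str,
    untreated: str = "untreated",
    treated: str = "treated",
) -> pd.DataFrame:
    """Reporter normalisation and 3-AT response.

    ``fluorescence[construct][condition]`` holds per-replicate values. Each
    construct's untreated signal is expressed as percent of the reference
    construct within the same replicate, then averaged; the response is
    log2(treated/untreated) per replicate, tested against zero with a paired
    t-test on the log2 values.
    """
    ref = fluorescence[reference_construct][untreated]
    if any(v == 0 for v in ref):
        raise ValueError("reference construct has zero fluorescence")
    rows = []
    for construct, data in fluorescence.items():
        u = np.asarray(data[untreated], dtype=float)
        t_ = np.asarray(data[treated], dtype=float)
        pct = float(np.mean([100.0 * v / r for v, r in zip(u, ref)]))
        responses = np.log2(t_ / u)
        if len(responses) >= 2:
            t_stat, p, _ = paired_t_test(np.log2(t_), np.log2(u))
        else:
            t_stat, p = math.nan, math.nan
        rows.append(
            {
                "construct": construct,
                "percent_of_reference": pct,
                "log2_response": float(responses.mean()),
                "t_stat": t_stat,
                "p_value": p,
                "n_replicates": len(responses),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class QPCRMeasurement:
    """Cq values for target and reference amplicons in one control/treated pair."""

    cq_target_control: float
    cq_target_treated: float
    cq_ref_control: float
    cq_ref_treated: float
    efficiency_target: float = 0.9546
    efficiency_ref: float = 1.004

    def __post_init__(self) -> None:
        for v in (self.cq_target_control, self.cq_target_treated,
                  self.cq_ref_control, self.cq_ref_treated):
            if v is None or not v > 0:
                raise ValueError("all Cq values must be present and positive")
        for e in (self.efficiency_target, self.efficiency_ref):
            if not 0.0 < e <= 1.2:
                raise ValueError("PCR efficiencies must be in (0, 1.2]")


def qpcr_ratio(m: QPCRMeasurement, simple: bool = False) -> float:
    """Efficiency-corrected treated/control expression ratio (ddCq logic).

    ``(1+E_target)^(Cq_target_ctrl - Cq_target_trt) /
    (1+E_ref)^(Cq_ref_ctrl - Cq_ref_trt)``; with ``simple=True`` both bases
    are 2 (the classical 2^-ddCq).
    """
    d_target = m.cq_target_control - m.cq_target_treated
    d_ref = m.cq_ref_control - m.cq_ref_treated
    if simple:
        return 2.0 ** d_target / 2.0 ** d_ref
    return (1.0 + m.efficiency_target) ** d_target / (1.0 + m.efficiency_ref) ** d_ref
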