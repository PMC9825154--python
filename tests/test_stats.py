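"""Peak coverage, window fractions, TE, reporter and qPCR arithmetic."""

import math

import numpy as np
import pytest
from scipy.stats import ttest_rel

from tcpseq.footprints import Footprint, length_bin
from tcpseq.profiles import Track, gene_track
from tcpseq.stats import (
    PeakCoverage,
    QPCRMeasurement,
    paired_t_test,
    qpcr_ratio,
    rank_by_peak_coverage,
    reporter_stats,
    ssu_peak_coverage,
    translational_efficiency,
    window_fraction,
)


def _track(model, pairs):
    """Track with given (rel_position, coverage) spikes over the default region."""
    lo, hi = -model.utr5_len - 10, 60
    cov = np.zeros(hi - lo + 1)
    for rel, h in pairs:
        cov[rel - lo] = h
    return Track(model.id, "40S", np.arange(lo, hi + 1), cov)


def _fp(model, rel_tss, length=60):
    start = model.tss_pos + rel_tss
    rel5 = start - model.start_codon_pos
    return Footprint(
        model.id, start, length, "40S", rel5, rel5 + length - 1, length_bin(length), "utr5"
    )


class TestSsuPeakCoverage:
    def test_formula(self, models):
        m = models["gene002"]
        pc = ssu_peak_coverage(_track(m, [(-50, 30.0), (-12, 70.0)]), m)
        assert pc.coverage == pytest.approx(0.3)
        assert (pc.h_utr, pc.h_aug) == (30.0, 70.0)

    def test_boundary_cases(self, models):
        m = models["gene002"]
        assert ssu_peak_coverage(_track(m, [(-12, 70.0)]), m).coverage == 0.0
        assert ssu_peak_coverage(_track(m, [(-50, 30.0)]), m).coverage == 1.0

    def test_all_zero_flagged(self, models):
        m = models["gene002"]
        pc = ssu_peak_coverage(_track(m, []), m)
        assert not pc.computable

    def test_short_leader_flagged(self, models):
        m = models["short_leader_like"]
        t = Track(m.id, "40S", np.arange(-10, 61), np.ones(71))
        assert not ssu_peak_coverage(t, m).computable

    def test_bounds_and_monotonicity(self, models):
        m = models["gene002"]
        prev = -1.0
        for h_utr in (0.0, 10.0, 40.0, 90.0):
            pc = ssu_peak_coverage(_track(m, [(-50, h_utr), (-12, 50.0)]), m)
            assert 0.0 <= pc.coverage <= 1.0
            assert pc.coverage > prev or (pc.coverage == 0.0 and prev < 0)
            prev = pc.coverage

    def test_scanning_accumulation_raises_coverage(self, models, rrna, params, index):
        """An initiation-only gene scores low; adding scanning mass raises it."""
        from tcpseq.pipeline import run_synthetic_library

        m = models["gene002"]
        init_only = run_synthetic_library(
            models, rrna, params, n=4_000, components=("init_ssu",),
            genes=[m.id], index=index,
        )
        t_init = gene_track(init_only.footprints, m)
        low = ssu_peak_coverage(t_init, m)
        assert low.coverage < 0.2
        mixed = run_synthetic_library(
            models, rrna, params, n=4_000, components=("init_ssu", "scanning_ssu"),
            genes=[m.id], index=index,
        )
        t_mix = gene_track(mixed.footprints, m)
        assert ssu_peak_coverage(t_mix, m).coverage > low.coverage


class TestRankByPeakCoverage:
    def test_singleton_identity(self):
        table = rank_by_peak_coverage([PeakCoverage("a", 1.0, 1.0, 0.5)])
        assert list(table["transcript_id"]) == ["a"]

    def test_permutation_invariant_and_tie_break(self):
        res = [
            PeakCoverage("b", 1.0, 1.0, 0.5),
            PeakCoverage("a", 1.0, 1.0, 0.5),
            PeakCoverage("c", 3.0, 1.0, 0.75),
            PeakCoverage("z", 0.0, 0.0, None),
        ]
        fwd = rank_by_peak_coverage(res)
        rev = rank_by_peak_coverage(list(reversed(res)))
        assert list(fwd["transcript_id"]) == ["c", "a", "b"]
        assert list(fwd["transcript_id"]) == list(rev["transcript_id"])


class TestWindowFraction:
    def test_hand_computed_fold_and_t(self, models):
        """Fractions (0.10, 0.12, 0.09) vs (0.38, 0.40, 0.35): fold 3.645, t 41."""
        m = models["fil1_like"]
        # realise the fractions exactly with 100 leader footprints per replicate
        def rep(frac):
            n_in = round(100 * frac)
            return [_fp(m, 800) for _ in range(n_in)] + [
                _fp(m, 100) for _ in range(100 - n_in)
            ]

        byc = {
            "untreated": [rep(0.10), rep(0.12), rep(0.09)],
            "treated": [rep(0.38), rep(0.40), rep(0.35)],
        }
        st = window_fraction(byc, m, window=(720, 1200))
        assert st.fold == pytest.approx(3.6451612903, abs=1e-9)
        assert st.t_stat == pytest.approx(41.0, abs=1e-9)
        # closed form for df=2: two-sided p = 1 - t/sqrt(t^2 + 2)
        assert st.p_value == pytest.approx(1 - 41 / math.sqrt(41**2 + 2), abs=1e-12)
        assert st.p_value == pytest.approx(5.9e-4, rel=2e-2)
        assert st.n_pairs == 3

    def test_identical_pairs_degenerate(self, models):
        m = models["fil1_like"]
        reps = [[_fp(m, 800)] * 2 + [_fp(m, 100)] * 8 for _ in range(3)]
        st = window_fraction({"untreated": reps, "treated": reps}, m)
        assert st.fold == 1.0 and st.p_value == 1.0 and st.degenerate

    def test_zero_denominator_pair_excluded(self, models):
        m = models["fil1_like"]
        good = [_fp(m, 800), _fp(m, 100)]
        byc = {"untreated": [good, []], "treated": [good, good]}
        st = window_fraction(byc, m)
        assert st.n_pairs == 1 and st.excluded_pairs == 1
        assert st.p_value is None  # a single pair carries no test

    def test_fold_invariant_under_depth_scaling(self, models):
        m = models["fil1_like"]
        base_u = [_fp(m, 800)] * 1 + [_fp(m, 100)] * 9
        base_t = [_fp(m, 800)] * 4 + [_fp(m, 100)] * 6
        byc1 = {"untreated": [base_u, base_u], "treated": [base_t, base_t]}
        byc5 = {"untreated": [base_u * 5, base_u * 5], "treated": [base_t * 5, base_t * 5]}
        assert window_fraction(byc1, m).fold == window_fraction(byc5, m).fold


class TestPairedT:
    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(11)
        for n in (2, 3, 5, 8, 20):
            for _ in range(20):
                x = rng.normal(0.3, 1.0, n)
                y = rng.normal(0.0, 1.0, n)
                t, p, degenerate = paired_t_test(x, y)
                ref = ttest_rel(x, y)
                assert not degenerate
                assert t == pytest.approx(ref.statistic, abs=1e-9)
                assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_needs_two_pairs(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0], [2.0])


class TestTranslationalEfficiency:
    def test_ratio(self):
        assert translational_efficiency("g", 200, 100, 1000, 1000).te == pytest.approx(2.0)

    def test_scale_invariance(self):
        a = translational_efficiency("g", 200, 100, 1_000, 2_000).te
        b = translational_efficiency("g", 200, 100, 10_000, 20_000).te
        assert a == pytest.approx(b)

    def test_zero_rna_undefined(self):
        assert translational_efficiency("g", 5, 0, 100, 100).te is None

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            translational_efficiency("g", -1, 10, 100, 100)

    def test_recovers_sampling_rate_ratio(self):
        """Doubling footprint sampling at fixed RNA doubles TE within noise."""
        rng = np.random.default_rng(13)
        n_rna = 2_000
        base_rate, boosted_rate = 0.05, 0.10
        rna = rng.binomial(n_rna, 0.5)
        fp_a = rng.binomial(10_000, base_rate)
        fp_b = rng.binomial(10_000, boosted_rate)
        te_a = translational_efficiency("g", fp_a, rna, 10_000, n_rna).te
        te_b = translational_efficiency("g", fp_b, rna, 10_000, n_rna).te
        sd = 3 * math.sqrt(boosted_rate * (1 - boosted_rate) / 10_000) / base_rate
        assert te_b / te_a == pytest.approx(2.0, abs=2 * sd + 0.2)


class TestReporterStats:
    def _data(self):
        return {
            "6x-mutant": {"untreated": [1000.0, 980.0, 1020.0], "treated": [800.0, 790.0, 815.0]},
            "wt": {"untreated": [11.6, 11.368, 11.832], "treated": [22.0, 21.5, 23.0]},
        }

    def test_reference_is_100_percent(self):
        table = reporter_stats(self._data(), "6x-mutant")
        row = table[table["construct"] == "6x-mutant"].iloc[0]
        assert row["percent_of_reference"] == pytest.approx(100.0)

    def test_weak_construct_percent(self):
        table = reporter_stats(self._data(), "6x-mutant")
        row = table[table["construct"] == "wt"].iloc[0]
        assert row["percent_of_reference"] == pytest.approx(1.16, abs=1e-9)

    def test_no_response_is_zero_log2(self):
        data = {"6x-mutant": {"untreated": [100.0, 100.0], "treated": [100.0, 100.0]}}
        table = reporter_stats(data, "6x-mutant")
        assert table.iloc[0]["log2_response"] == 0.0

    def test_zero_reference_rejected(self):
        data = {"6x-mutant": {"untreated": [0.0], "treated": [1.0]}}
        with pytest.raises(ValueError):
            reporter_stats(data, "6x-mutant")


class TestQpcr:
    def test_no_change_is_unity(self):
        m = QPCRMeasurement(20.0, 20.0, 18.0, 18.0)
        assert qpcr_ratio(m) == pytest.approx(1.0)

    def test_one_cycle_down_perfect_efficiency(self):
        m = QPCRMeasurement(20.0, 21.0, 18.0, 18.0, efficiency_target=1.0)
        assert qpcr_ratio(m) == pytest.approx(0.5)

    def test_paper_efficiency_correction(self):
        m = QPCRMeasurement(20.0, 21.0, 18.0, 18.0)
        assert qpcr_ratio(m) == pytest.approx(1 / 1.9546, abs=1e-9)

    def test_simple_mode_is_two_to_minus_ddcq(self):
        m = QPCRMeasurement(20.0, 19.0, 18.0, 18.5)
        assert qpcr_ratio(m, simple=True) == pytest.approx(2.0 ** 1.0 / 2.0 ** -0.5)

    def test_missing_cq_rejected(self):
        with pytest.raises((ValueError, TypeError)):
            QPCRMeasurement(20.0, None, 18.0, 18.0)
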