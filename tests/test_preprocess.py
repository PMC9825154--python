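"""Read parsing, contaminant filtering, exact mapping and deduplication."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcpseq import GeneratorParams
from tcpseq.io import FastqRead
from tcpseq.preprocess import (
    Alignment,
    ExactIndex,
    dedup,
    filter_contaminants,
    map_exact,
    parse_rnaseq_pair,
    parse_tcp_read,
    parse_tcp_reads,
)
from tcpseq.simulate import emit_tcp_reads, simulate_footprints

ADAPTOR = "TGGAATTCTCGGGTGCCAAGG"


class TestParseTcpRead:
    def test_stated_layout(self):
        insert = "ACGTACGTACGTACGTACGTACGTACGTACGT"  # 32 nt
        read = FastqRead("r1", "ACGT" + insert + "TTAA" + ADAPTOR)
        parsed, reason = parse_tcp_read(read, ADAPTOR)
        assert reason is None
        assert parsed.umi == "ACGTTTAA"
        assert parsed.insert == insert
        assert not parsed.low_confidence

    def test_insert_too_short_rejected(self):
        read = FastqRead("r1", "ACGTACGT" + ADAPTOR[:22])
        parsed, reason = parse_tcp_read(read, ADAPTOR)
        assert parsed is None and reason == "insert_too_short"

    def test_partial_adaptor_at_three_prime_end(self):
        insert = "A" * 70
        full = "ACGT" + insert + "TTAA" + ADAPTOR  # 99 nt... truncate to simulate SE100
        read = FastqRead("r1", full[:92])  # keeps a 14-nt adaptor prefix
        parsed, reason = parse_tcp_read(read, ADAPTOR)
        assert reason is None and parsed.insert == insert

    def test_adaptorless_100nt_read_is_low_confidence(self):
        read = FastqRead("r1", "AC" * 50)
        parsed, reason = parse_tcp_read(read, ADAPTOR)
        assert reason is None and parsed.low_confidence
        assert len(parsed.insert) == 92

    def test_roundtrip_identity_on_synthetic_library(self, models, rrna, params):
        truth = simulate_footprints(models, params, n=2_000, rrna=rrna)
        seqs = {tid: m.sequence for tid, m in models.items()} | rrna
        reads, mults = emit_tcp_reads(truth, seqs, params)
        parsed, rejected = parse_tcp_reads(reads, params.adaptor)
        assert not rejected
        assert len(parsed) == len(reads)
        # adaptor-containing reads recover the exact (umi, insert) of their footprint
        idx = 0
        for i, t in enumerate(truth):
            frag = seqs[t.transcript_id][t.start : t.start + t.length]
            for _ in range(mults[i]):
                p = parsed[idx]
                idx += 1
                if p.low_confidence:
                    continue
                assert p.insert == frag

    def test_short_adaptor_rejected(self):
        with pytest.raises(ValueError):
            parse_tcp_read(FastqRead("r", "A" * 50), "ACGT")


class TestParseRnaseqPair:
    def test_merged_umi(self):
        fwd = FastqRead("p/1", "AAAACCCC" + "A" + "G" * 66)
        rev = FastqRead("p/2", "GGGGTTTT" + "T" + "C" * 66)
        parsed, reason = parse_rnaseq_pair(fwd, rev)
        assert reason is None
        assert parsed.umi == "AAAACCCCGGGGTTTT" and len(parsed.umi) == 16
        assert parsed.insert == "G" * 66 and parsed.insert2 == "C" * 66

    def test_anchor_mismatch_rejected(self):
        fwd = FastqRead("p/1", "AAAACCCC" + "C" + "G" * 66)
        rev = FastqRead("p/2", "GGGGTTTT" + "T" + "C" * 66)
        parsed, reason = parse_rnaseq_pair(fwd, rev)
        assert parsed is None and reason == "anchor_mismatch"

    def test_mate_id_mismatch_rejected(self):
        fwd = FastqRead("p1/1", "AAAACCCC" + "A" + "G" * 66)
        rev = FastqRead("p2/2", "GGGGTTTT" + "T" + "C" * 66)
        assert parse_rnaseq_pair(fwd, rev)[1] == "mate_id_mismatch"


class TestFilterContaminants:
    def test_empty_set_is_identity(self):
        parsed = [
            FastqRead("r", "A")  # placeholder; ParsedRead is what matters below
        ]
        from tcpseq.preprocess import ParsedRead

        reads = [ParsedRead("r1", "AAAACCCC", "ACGTACGTACGTACGT", "tcp_se100")]
        retained, counts = filter_contaminants(reads, {})
        assert retained == reads and not counts

    def test_planted_contaminant_counted_by_name(self, rrna):
        from tcpseq.preprocess import ParsedRead

        hit = ParsedRead("r1", "AAAACCCC", rrna["rRNA_18S"][100:140], "tcp_se100")
        miss = ParsedRead("r2", "AAAACCCC", "ACGT" * 10, "tcp_se100")
        retained, counts = filter_contaminants([hit, miss], rrna)
        assert retained == [miss]
        assert counts == {"rRNA_18S": 1}

    def test_retained_fraction_matches_rrna_frac(self, models, rrna, params):
        truth = simulate_footprints(models, params, n=10_000, rrna=rrna)
        seqs = {tid: m.sequence for tid, m in models.items()} | rrna
        reads, _ = emit_tcp_reads(
            truth, seqs, GeneratorParams(seed=1, n_genes=8, dup_geom_p=1.0)
        )
        parsed, _ = parse_tcp_reads(reads, params.adaptor)
        retained, _ = filter_contaminants(parsed, rrna)
        assert len(retained) / len(parsed) == pytest.approx(0.80, abs=0.02)


class TestMapExact:
    def test_unique_hit_at_planted_coordinate(self, models, index):
        from tcpseq.preprocess import ParsedRead

        tid = "gene002"
        m = models[tid]
        insert = m.sequence[150:190]
        (a,) = map_exact([ParsedRead("r1", "AAAACCCC", insert, "tcp_se100")], models, index=index)
        assert (a.mapq_class, a.transcript_id, a.start, a.length) == ("unique", tid, 150, 40)

    def test_repeated_insert_is_ambiguous(self):
        from tcpseq.annotation import TranscriptModel
        from tcpseq.preprocess import ParsedRead

        poly = "A" * 30
        mk = lambda tid: TranscriptModel(
            id=tid, sequence="G" * 100 + poly + "ATG" + "GGC" * 3 + "TAA" + "TTTT",
            ext_len=100, utr5_len=30, cds_len=15, utr3_len=4,
        )
        two = {"x": mk("x"), "y": mk("y")}
        (a,) = map_exact([ParsedRead("r1", "AAAACCCC", "A" * 20, "tcp_se100")], two)
        assert a.mapq_class == "ambiguous"

    def test_absent_insert_is_unmapped(self, models, index):
        from tcpseq.preprocess import ParsedRead

        (a,) = map_exact(
            [ParsedRead("r1", "AAAACCCC", "ACGT" * 10, "tcp_se100")], models, index=index
        )
        assert a.mapq_class == "unmapped"


def _brute_force_dedup(alignments):
    """Quadratic duplicate finder: keep the smallest read id of every key class."""
    kept = []
    for a in alignments:
        key = (a.transcript_id, a.start, a.length, a.umi)
        better = [
            b
            for b in alignments
            if (b.transcript_id, b.start, b.length, b.umi) == key and b.read_id < a.read_id
        ]
        if not better:
            kept.append(a)
    return kept


class TestDedup:
    def test_three_copies_collapse_to_one(self):
        aln = [Alignment(f"r{i}", "AAAACCCC", "t", 10, 30, "unique") for i in range(3)]
        kept, n_dup = dedup(aln)
        assert [a.read_id for a in kept] == ["r0"] and n_dup == 2

    def test_distinct_umis_kept(self):
        aln = [
            Alignment("r0", "AAAACCCC", "t", 10, 30, "unique"),
            Alignment("r1", "CCCCAAAA", "t", 10, 30, "unique"),
        ]
        kept, n_dup = dedup(aln)
        assert len(kept) == 2 and n_dup == 0

    def test_non_unique_input_rejected(self):
        with pytest.raises(ValueError):
            dedup([Alignment("r0", "A", "*", 0, 20, "unmapped")])

    def test_idempotent(self, models, rrna, params, index):
        from tcpseq.pipeline import run_synthetic_library

        run = run_synthetic_library(models, rrna, params, n=500, index=index)
        aln = [
            Alignment(f.transcript_id + str(i), "AAAA", f.transcript_id, f.start, f.length, "unique")
            for i, f in enumerate(run.footprints)
        ]
        once, _ = dedup(aln)
        twice, n = dedup(once)
        assert twice == once and n == 0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.integers(0, 999),  # read id
                st.sampled_from(["AAAA", "CCCC", "GGGG"]),
                st.sampled_from(["t1", "t2"]),
                st.integers(0, 5),
                st.sampled_from([20, 30]),
            ),
            max_size=60,
        )
    )
    def test_matches_brute_force(self, rows):
        aln = [
            Alignment(f"r{rid:03d}_{i}", umi, tid, start, length, "unique")
            for i, (rid, umi, tid, start, length) in enumerate(rows)
        ]
        kept, n_dup = dedup(aln)
        brute = _brute_force_dedup(aln)
        assert sorted(kept, key=lambda a: a.read_id) == sorted(brute, key=lambda a: a.read_id)
        assert n_dup == len(aln) - len(kept)

    def test_truth_count_recovered_exactly(self, models, rrna, params, index):
        """At error rate 0 the deduplicated count equals the truth count."""
        from tcpseq.pipeline import run_synthetic_library

        run = run_synthetic_library(
            models, rrna, params, n=1_000, components=("scanning_ssu", "tss_ssu"), index=index
        )
        assert run.qc["n_footprints"] == len(run.truth)
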