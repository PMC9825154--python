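"""Read parsing, contaminant filtering, exact mapping and UMI deduplication.

Two custom library layouts are handled. TCP-seq libraries are single-end
100 nt: ``4 random nt + insert + 4 random nt + adaptor``; the eight random
bases form the UMI. RNA-seq libraries are paired-end 75 nt with an anchored
base after the octamer (``RRRRRRRRA...`` forward, ``RRRRRRRRT...`` reverse);
the two octamers are merged into a 16-nt UMI.

Mapping here is sense-strand exact substring search (the synthetic
transcriptome is built 20-mer-collision-free, so gel-cut inserts map
uniquely); externally aligned SAM/BAM in transcriptome coordinates can be
imported in its place via :func:`alignments_from_sam`. Duplicate removal is
post-alignment on the key (transcript, start, length, UMI), keeping the
lexicographically smallest read id, which makes it deterministic and
idempotent.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .annotation import TranscriptModel
from .io import FastqRead

MIN_INSERT_DEFAULT = 15   # lower gel cut, nt
MAX_INSERT_DEFAULT = 100  # upper gel cut, nt
MIN_ADAPTOR_PREFIX = 10


@dataclass(frozen=True)
class ParsedRead:
    read_id: str
    umi: str
    insert: str
    layout: str  # "tcp_se100" | "rnaseq_pe75"
    insert2: str | None = None  # reverse-mate subsequence for paired layouts
    low_confidence: bool = False


@dataclass(frozen=True)
class Alignment:
    read_id: str
    umi: str
    transcript_id: str
    start: int
    length: int
    mapq_class: str  # "unique" | "ambiguous" | "unmapped"


def parse_tcp_read(
    read: FastqRead,
    adaptor: str,
    min_insert: int = MIN_INSERT_DEFAULT,
    max_insert: int = MAX_INSERT_DEFAULT,
) -> tuple[ParsedRead | None, str | None]:
    """Parse one SE100 TCP-seq read; returns (parsed, None) or (None, reason).

    The leftmost full-adaptor occurrence is stripped; failing that, the
    longest adaptor prefix (>= 10 nt) anchored at the read 3' end. A 100-nt
    read with no adaptor at all is treated as adaptor-absent (the insert
    pushed the adaptor off the read): the UMI is taken positionally and the
    result is flagged low-confidence.
    """
    if len(adaptor) < MIN_ADAPTOR_PREFIX:
        raise ValueError("adaptor must be at least 10 nt")
    seq = read.seq
    cut = seq.find(adaptor)
    low_confidence = False
    if cut < 0:
        for plen in range(len(adaptor) - 1, MIN_ADAPTOR_PREFIX - 1, -1):
            if seq.endswith(adaptor[:plen]):
                cut = len(seq) - plen
                break
    if cut < 0:
        if len(seq) == 100:
            cut = len(seq)
            low_confidence = True
        else:
            return None, "adaptor_not_found"
    remainder = seq[:cut]
    if len(remainder) < 8 + min_insert:
        return None, "insert_too_short"
    umi = remainder[:4] + remainder[-4:]
    insert = remainder[4:-4]
    if len(insert) > max_insert:
        return None, "insert_too_long"
    return (
        ParsedRead(read.id, umi, insert, "tcp_se100", low_confidence=low_confidence),
        None,
    )


def parse_tcp_reads(
    reads: Iterable[FastqRead],
    adaptor: str,
    min_insert: int = MIN_INSERT_DEFAULT,
    max_insert: int = MAX_INSERT_DEFAULT,
) -> tuple[list[ParsedRead], Counter]:
    """Bulk :func:`parse_tcp_read`; returns retained reads and rejection counts."""
    parsed: list[ParsedRead] = []
    rejected: Counter = Counter()
    for r in reads:
        p, reason = parse_tcp_read(r, adaptor, min_insert, max_insert)
        if p is None:
            rejected[reason] += 1
        else:
            parsed.append(p)
    return parsed, rejected


def _strip_mate(read_id: str) -> str:
    return read_id.rsplit("/", 1)[0]


def parse_rnaseq_pair(fwd: FastqRead, rev: FastqRead) -> tuple[ParsedRead | None, str | None]:
    """Parse one PE75 pair; anchors (A at forward position 8, T at reverse) must match."""
    if _strip_mate(fwd.id) != _strip_mate(rev.id):
        return None, "mate_id_mismatch"
    if len(fwd.seq) < 10 or len(rev.seq) < 10:
        return None, "read_too_short"
    if fwd.seq[8] != "A" or rev.seq[8] != "T":
        return None, "anchor_mismatch"
    umi = fwd.seq[:8] + rev.seq[:8]
    return (
        ParsedRead(
            _strip_mate(fwd.id), umi, fwd.seq[9:], "rnaseq_pe75", insert2=rev.seq[9:]
        ),
        None,
    )


def filter_contaminants(
    parsed: Sequence[ParsedRead],
    contaminant_set: Mapping[str, str],
) -> tuple[list[ParsedRead], Counter]:
    """Drop inserts that match a substring of any contaminant (e.g. rRNA) sequence.

    Per-contaminant counts are reported, which supports composition checks
    such as the strong 18S enrichment expected of 40S-derived libraries.
    """
    retained: list[ParsedRead] = []
    counts: Counter = Counter()
    names = sorted(contaminant_set)
    for p in parsed:
        hit = None
        for name in names:
            if p.insert in contaminant_set[name]:
                hit = name
                break
        if hit is None:
            retained.append(p)
        else:
            counts[hit] += 1
    return retained, counts


class ExactIndex:
    """Seed-and-verify exact substring index over transcript sense strands."""

    def __init__(self, models: Mapping[str, TranscriptModel], k: int = MIN_INSERT_DEFAULT):
        self.k = k
        self.seqs = {tid: m.sequence for tid, m in models.items()}
        self._seeds: dict[str, list[tuple[str, int]]] = {}
        for tid in sorted(self.seqs):
            s = self.seqs[tid]
            for i in range(len(s) - k + 1):
                self._seeds.setdefault(s[i : i + k], []).append((tid, i))

    def occurrences(self, insert: str) -> list[tuple[str, int]]:
        if len(insert) < self.k:
            return []
        hits = []
        for tid, i in self._seeds.get(insert[: self.k], ()):
            if self.seqs[tid][i : i + len(insert)] == insert:
                hits.append((tid, i))
        return hits


def map_exact(
    parsed: Sequence[ParsedRead],
    models: Mapping[str, TranscriptModel],
    index: ExactIndex | None = None,
) -> list[Alignment]:
    """Map inserts by exact sense-strand search: unique / ambiguous / unmapped.

    For paired layouts the reverse-mate subsequence must also match (reverse
    complement) downstream on the same transcript, else the pair is unmapped.
    """
    from .simulate import revcomp

    idx = index if index is not None else ExactIndex(models)
    out: list[Alignment] = []
    for p in parsed:
        hits = idx.occurrences(p.insert)
        if p.insert2 is not None and len(hits) == 1:
            tid, pos = hits[0]
            if revcomp(p.insert2) not in idx.seqs[tid][pos:]:
                hits = []
        if len(hits) == 1:
            tid, pos = hits[0]
            out.append(Alignment(p.read_id, p.umi, tid, pos, len(p.insert), "unique"))
        elif len(hits) == 0:
            out.append(Alignment(p.read_id, p.umi, "*", 0, len(p.insert), "unmapped"))
        else:
            tid, pos = hits[0]
            out.append(Alignment(p.read_id, p.umi, tid, pos, len(p.insert), "ambiguous"))
    return out


def dedup(alignments: Sequence[Alignment]) -> tuple[list[Alignment], int]:
    """Collapse PCR duplicates on (transcript, start, length, UMI).

    Input must be uniquely mapped. One representative (lexicographically
    smallest read id) is kept per key; the second return value is the number
    of removed duplicates. Idempotent by construction.
    """
    best: dict[tuple[str, int, int, str], Alignment] = {}
    n = 0
    for a in alignments:
        if a.mapq_class != "unique":
            raise ValueError("dedup expects uniquely mapped alignments only")
        n += 1
        key = (a.transcript_id, a.start, a.length, a.umi)
        cur = best.get(key)
        if cur is None or a.read_id < cur.read_id:
            best[key] = a
    kept = sorted(best.values(), key=lambda a: (a.transcript_id, a.start, a.length, a.read_id))
    return kept, n - len(kept)


def alignments_from_sam(path, umi_tag: str = "RX") -> list[Alignment]:
    """Import externally aligned reads (transcriptome coordinates) from SAM/BAM.

    The UMI is taken from the given tag (RX by default). Secondary and
    unmapped records are classed accordingly so downstream handling matches
    the internal mapper's behaviour.
    """
    import pysam

    out: list[Alignment] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                out.append(Alignment(rec.query_name, "", "*", 0, 0, "unmapped"))
                continue
            umi = rec.get_tag(umi_tag) if rec.has_tag(umi_tag) else ""
            cls = "ambiguous" if rec.is_secondary or rec.is_supplementary else "unique"
            out.append(
                Alignment(
                    rec.query_name,
                    str(umi),
                    rec.reference_name,
                    rec.reference_start,
                    rec.query_alignment_length,
                    cls,
                )
            )
    return out
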