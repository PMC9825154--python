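"""Merged-coordinate transcript models and uORF annotation.

TCP-seq reads are mapped against a transcriptome in which each mRNA is the
concatenation of an upstream extension (default 100 nt, so that footprints
whose 5' ends fall upstream of the annotated transcription start can still be
placed), the annotated 5' UTR, the CDS and the 3' UTR. Two anchors matter for
everything downstream: the transcription start site (``tss_pos``, the first
transcribed base) and the first base of the start codon (``start_codon_pos``).
Footprint coordinates are 0-based throughout; a footprint starting at ``s``
with length ``L`` occupies the closed interval ``[s, s + L - 1]``, which makes
the canonical initiation arithmetic exact: a small-subunit footprint with its
5' end 12 nt upstream of the AUG and a length of 32 nt has its 3' end at +19.

The 5' leaders of many transcripts carry upstream open reading frames (uORFs)
that gate scanning subunits; :func:`find_uorfs` enumerates them, optionally
including the near-cognate CUG starts seen on regulated leaders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
NEAR_COGNATE_STARTS = ("ATG", "CTG")
DEFAULT_EXT_LEN = 100


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript in merged (extension + 5'UTR + CDS + 3'UTR) coordinates."""

    id: str
    sequence: str
    ext_len: int
    utr5_len: int
    cds_len: int
    utr3_len: int

    def __post_init__(self) -> None:
        total = self.ext_len + self.utr5_len + self.cds_len + self.utr3_len
        if len(self.sequence) != total:
            raise ValueError(
                f"{self.id}: sequence length {len(self.sequence)} != "
                f"ext+utr5+cds+utr3 = {total}"
            )
        if self.cds_len <= 0 or self.cds_len % 3 != 0:
            raise ValueError(f"{self.id}: CDS length {self.cds_len} not a positive multiple of 3")

    @property
    def tss_pos(self) -> int:
        """0-based index of the first transcribed nucleotide."""
        return self.ext_len

    @property
    def start_codon_pos(self) -> int:
        """0-based index of the A of the AUG start codon."""
        return self.ext_len + self.utr5_len

    @property
    def stop_last_pos(self) -> int:
        """0-based index of the last base of the stop codon."""
        return self.start_codon_pos + self.cds_len - 1

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class UORF:
    """An upstream ORF: start codon in the 5' UTR, first in-frame stop downstream."""

    transcript_id: str
    start_rel_tss: int
    length_nt: int
    start_codon: str
    overlaps_cds: bool

    def __post_init__(self) -> None:
        if self.start_rel_tss < 0:
            raise ValueError("uORF start upstream of the TSS")
        if self.length_nt % 3 != 0 or self.length_nt < 6:
            raise ValueError("uORF length must be a multiple of 3 and >= 6")


def _as_unique_mapping(records, label: str) -> dict:
    """Normalise a mapping or (id, seq) iterable; duplicate ids are a hard error."""
    if isinstance(records, Mapping):
        return {str(k): str(v).upper() for k, v in records.items()}
    out: dict = {}
    for rid, seq in records:
        if rid in out:
            raise ValueError(f"duplicate identifier {rid!r} in {label} set")
        out[str(rid)] = str(seq).upper()
    return out


def build_transcriptome(
    utr5_set,
    cds_set,
    utr3_set,
    ext_set,
    ext_len: int = DEFAULT_EXT_LEN,
) -> dict[str, TranscriptModel]:
    """Merge per-region sequence sets into :class:`TranscriptModel` objects.

    The CDS set defines the gene universe. Transcripts with a CDS but no UTR
    entry get empty UTRs (with a warning); a missing extension is padded with
    N's of length ``ext_len`` (with a warning); a CDS whose length is not a
    multiple of 3 is rejected with a diagnostic rather than raising.
    Output is keyed and ordered by transcript id, so the result is independent
    of input record order.
    """
    utr5 = _as_unique_mapping(utr5_set, "5'UTR")
    cds = _as_unique_mapping(cds_set, "CDS")
    utr3 = _as_unique_mapping(utr3_set, "3'UTR")
    ext = _as_unique_mapping(ext_set, "extension")

    models: dict[str, TranscriptModel] = {}
    for tid in sorted(cds):
        c = cds[tid]
        if len(c) % 3 != 0 or not c:
            warnings.warn(
                f"{tid}: CDS length {len(c)} not a multiple of 3; transcript rejected",
                stacklevel=2,
            )
            continue
        u5 = utr5.get(tid)
        u3 = utr3.get(tid)
        if u5 is None or u3 is None:
            warnings.warn(f"{tid}: missing UTR entry, using empty UTR", stacklevel=2)
            u5 = u5 or ""
            u3 = u3 or ""
        e = ext.get(tid)
        if e is None:
            warnings.warn(f"{tid}: missing extension, padding with N x {ext_len}", stacklevel=2)
            e = "N" * ext_len
        elif len(e) != ext_len:
            raise ValueError(f"{tid}: extension length {len(e)} != ext_len {ext_len}")
        models[tid] = TranscriptModel(
            id=tid,
            sequence=e + u5 + c + u3,
            ext_len=ext_len,
            utr5_len=len(u5),
            cds_len=len(c),
            utr3_len=len(u3),
        )
    return models


def relative_position(model: TranscriptModel, pos: int) -> int:
    """Signed offset of a transcript coordinate from the A of the start codon.

    0 denotes the A of the AUG (a ribosome with its P site over the start
    codon has its footprint 5' end at -12 under this convention).
    """
    if not 0 <= pos < model.length:
        raise ValueError(f"position {pos} outside transcript {model.id} (len {model.length})")
    return pos - model.start_codon_pos


def find_uorfs(
    model: TranscriptModel,
    start_codons: Sequence[str] = ("ATG",),
    min_len: int = 6,
) -> list[UORF]:
    """Enumerate uORFs whose start codon lies in the annotated 5' UTR.

    Every occurrence of a start codon at positions ``tss_pos ..
    start_codon_pos - 1`` is extended in frame to the first stop codon found
    anywhere downstream in the transcript (the stop may lie at or beyond the
    main start codon; such uORFs are flagged ``overlaps_cds`` rather than
    dropped). uORFs with no in-frame stop before the transcript end are
    dropped with a warning. Results are sorted by position; overlapping and
    nested uORFs are all reported.
    """
    if not start_codons:
        raise ValueError("start_codons must be non-empty")
    starts = {c.upper().replace("U", "T") for c in start_codons}
    seq = model.sequence
    out: list[UORF] = []
    for p in range(model.tss_pos, model.start_codon_pos):
        codon = seq[p : p + 3]
        if codon not in starts:
            continue
        stop_at = None
        q = p + 3
        while q + 3 <= model.length:
            if seq[q : q + 3] in STOP_CODONS:
                stop_at = q
                break
            q += 3
        if stop_at is None:
            warnings.warn(
                f"{model.id}: uORF start at {p - model.tss_pos} has no in-frame stop; dropped",
                stacklevel=2,
            )
            continue
        length = stop_at + 3 - p
        if length < min_len:
            continue
        out.append(
            UORF(
                transcript_id=model.id,
                start_rel_tss=p - model.tss_pos,
                length_nt=length,
                start_codon=codon,
                overlaps_cds=stop_at + 2 >= model.start_codon_pos,
            )
        )
    return out
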