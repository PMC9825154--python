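"""Footprints: start-codon-relative coordinates, length bins, regions, frames.

A deduplicated alignment becomes a footprint with signed 5'/3' end offsets
from the A of the start codon (``rel3 == rel5 + length - 1`` under the
closed-interval convention). Lengths are binned as in the length-segmented
track figures: <= 35 nt (roughly full-ribosome protection), 36-59 nt, and
>= 60 nt (extended protection typical of scanning subunits). Reading frame is
inferred by shifting the 5' end by the P-site offset (12 nt, the observed
distance between an initiating ribosome's footprint 5' end and the AUG).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .annotation import TranscriptModel
from .preprocess import Alignment

LENGTH_MIN = 15
LENGTH_MAX = 100
START_SITE_REL5_WINDOW = (-15, 3)
STOP_SITE_REL3_MARGIN = (3, 15)  # nt before/after the stop codon's last base
P_SITE_OFFSET = 12

REGIONS = ("utr5", "start_site", "cds", "stop_site", "utr3")


@dataclass(frozen=True)
class Footprint:
    transcript_id: str
    start: int
    length: int
    library: str  # "40S" | "80S"
    rel5: int
    rel3: int
    length_bin: str  # "short" | "mid" | "long"
    region: str


def length_bin(length: int) -> str:
    """Bin a footprint length: <=35 short, 36-59 mid, >=60 long."""
    if not LENGTH_MIN <= length <= LENGTH_MAX:
        raise ValueError(f"footprint length {length} outside [{LENGTH_MIN}, {LENGTH_MAX}]")
    if length <= 35:
        return "short"
    if length <= 59:
        return "mid"
    return "long"


def _classify(model: TranscriptModel, start: int, length: int) -> str:
    rel5 = start - model.start_codon_pos
    rel3 = rel5 + length - 1
    if START_SITE_REL5_WINDOW[0] <= rel5 <= START_SITE_REL5_WINDOW[1]:
        return "start_site"
    stop_rel3 = model.cds_len - 1  # last stop-codon base, start-codon-relative
    if stop_rel3 - STOP_SITE_REL3_MARGIN[0] <= rel3 <= stop_rel3 + STOP_SITE_REL3_MARGIN[1]:
        return "stop_site"
    mid = start + (length - 1) // 2
    if mid < model.start_codon_pos:
        return "utr5"
    if mid <= model.stop_last_pos:
        return "cds"
    return "utr3"


def classify_region(fp: Footprint, model: TranscriptModel) -> str:
    """Region label: start/stop-site windows take precedence, else by midpoint."""
    return _classify(model, fp.start, fp.length)


def to_footprint(a: Alignment, model: TranscriptModel, library: str) -> Footprint:
    """Convert one uniquely mapped alignment to a footprint."""
    if a.mapq_class != "unique":
        raise ValueError("only uniquely mapped alignments become footprints")
    if a.start < 0 or a.start + a.length > model.length:
        raise ValueError(
            f"alignment [{a.start}, {a.start + a.length}) outside transcript {model.id}"
        )
    rel5 = a.start - model.start_codon_pos
    return Footprint(
        transcript_id=model.id,
        start=a.start,
        length=a.length,
        library=library,
        rel5=rel5,
        rel3=rel5 + a.length - 1,
        length_bin=length_bin(a.length),
        region=_classify(model, a.start, a.length),
    )


def footprints_from_alignments(
    alignments: Sequence[Alignment],
    models: Mapping[str, TranscriptModel],
    library: str,
) -> list[Footprint]:
    return [to_footprint(a, models[a.transcript_id], library) for a in alignments]


def frame_of(fp: Footprint, p_site_offset: int = P_SITE_OFFSET) -> int:
    """Codon frame of the inferred P site (0 = in frame with the CDS).

    Only meaningful for footprints at start sites or in the CDS; calling it
    on UTR footprints is an error.
    """
    if fp.region not in ("cds", "start_site"):
        raise ValueError(f"frame undefined for region {fp.region!r}")
    return (fp.rel5 + p_site_offset) % 3


def footprint_frame(fps: Sequence[Footprint]):
    """Footprint table as a pandas DataFrame (for TSV export)."""
    import pandas as pd

    return pd.DataFrame([f.__dict__ for f in fps])


def footprints_from_frame(frame) -> list[Footprint]:
    """Rebuild footprint objects from a table written by :func:`footprint_frame`."""
    return [
        Footprint(
            transcript_id=str(r.transcript_id),
            start=int(r.start),
            length=int(r.length),
            library=str(r.library),
            rel5=int(r.rel5),
            rel3=int(r.rel3),
            length_bin=str(r.length_bin),
            region=str(r.region),
        )
        for r in frame.itertuples(index=False)
    ]
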