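"""End-to-end drivers: simulate a library, emit reads, and process them back.

These helpers chain the stages the analysis scripts, tests and acceptance
checks all share: ground-truth footprints -> FASTQ-layout reads -> parsing ->
rRNA filtering -> exact mapping -> UMI deduplication -> footprints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .annotation import TranscriptModel
from .footprints import Footprint, footprints_from_alignments
from .io import FastqRead
from .metagene import build_heatmap, find_modes, length_histogram, project
from .preprocess import (
    ExactIndex,
    dedup,
    filter_contaminants,
    map_exact,
    parse_tcp_reads,
)
from .simulate import GeneratorParams, SimulationTruth, emit_tcp_reads, simulate_footprints


@dataclass
class LibraryRun:
    """Everything one synthetic library produced, truth included."""

    library: str
    condition: str
    replicate: int
    truth: list[SimulationTruth]
    reads: list[FastqRead]
    footprints: list[Footprint]
    qc: dict


def process_tcp_reads(
    reads: Sequence[FastqRead],
    models: Mapping[str, TranscriptModel],
    rrna: Mapping[str, str],
    library: str,
    adaptor: str,
    min_insert: int = 15,
    index: ExactIndex | None = None,
) -> tuple[list[Footprint], dict]:
    """Parse, filter, map and deduplicate one TCP-seq library."""
    parsed, rejected = parse_tcp_reads(reads, adaptor, min_insert=min_insert)
    retained, contam = filter_contaminants(parsed, rrna)
    alignments = map_exact(retained, models, index=index)
    unique = [a for a in alignments if a.mapq_class == "unique"]
    kept, n_dup = dedup(unique)
    fps = footprints_from_alignments(kept, models, library)
    qc = {
        "n_reads": len(reads),
        "n_parsed": len(parsed),
        "rejected": dict(rejected),
        "contaminants": dict(contam),
        "n_unique": len(unique),
        "n_ambiguous": sum(a.mapq_class == "ambiguous" for a in alignments),
        "n_unmapped": sum(a.mapq_class == "unmapped" for a in alignments),
        "n_duplicates": n_dup,
        "n_footprints": len(fps),
    }
    return fps, qc


def run_synthetic_library(
    models: Mapping[str, TranscriptModel],
    rrna: Mapping[str, str],
    params: GeneratorParams,
    library: str = "40S",
    condition: str = "untreated",
    replicate: int = 0,
    n: int | None = None,
    components: Sequence[str] | None = None,
    genes: Sequence[str] | None = None,
    index: ExactIndex | None = None,
) -> LibraryRun:
    """Simulate one library and push its reads through the full pipeline."""
    truth = simulate_footprints(
        models, params, condition=condition, replicate=replicate, library=library,
        n=n, components=components, genes=genes, rrna=rrna,
    )
    seqs = {tid: m.sequence for tid, m in models.items()} | dict(rrna)
    read_rng = np.random.default_rng(
        [params.seed % (2**31), 13, {"untreated": 0, "treated": 1}[condition],
         replicate, {"40S": 0, "80S": 1}[library]]
    )
    reads, _ = emit_tcp_reads(truth, seqs, params, rng=read_rng)
    fps, qc = process_tcp_reads(
        reads, models, rrna, library, params.adaptor, index=index
    )
    return LibraryRun(library, condition, replicate, truth, reads, fps, qc)


def initiation_summary(fps: Sequence[Footprint]) -> dict:
    """Start-codon-anchored projection modes and length modes for one library.

    Returns the 5'-end projection mode, the two 3'-end modes (ascending), the
    global length mode, and the secondary length mode (>= 10 nt away).
    """
    m5 = build_heatmap(fps, anchor="start_codon", end="five_prime")
    m3 = build_heatmap(fps, anchor="start_codon", end="three_prime")
    p5 = project(m5)
    p3 = project(m3)
    modes5, _ = find_modes(p5, k=1)
    modes3, _ = find_modes(p3, k=2, min_separation=4)
    hist = length_histogram(fps)
    len_modes, _ = find_modes(hist, k=2, min_separation=10)
    return {
        "mode_5p": modes5[0] if modes5 else None,
        "modes_3p": sorted(modes3),
        "length_mode_primary": len_modes[0] if len_modes else None,
        "length_mode_secondary": max(len_modes) if len(len_modes) > 1 else None,
    }
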