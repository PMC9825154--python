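#!/usr/bin/env python
"""Parse, filter, map and deduplicate the simulated libraries.

Reads the FASTQ files from analysis/02, rebuilds the transcriptome from the
FASTA parts written by analysis/01 (the pipeline sees only files, never the
in-memory truth), and writes per-library footprint tables (scratch/) and a
QC summary (results/preprocess_qc.tsv): rejection reasons, rRNA contaminant
composition, mapping classes and duplicate rates.
"""

import sys
from pathlib import Path

import pandas as pd

from tcpseq import build_transcriptome
from tcpseq.footprints import footprint_frame
from tcpseq.io import read_fasta, read_fastq
from tcpseq.pipeline import process_tcp_reads
from tcpseq.preprocess import ExactIndex
from tcpseq.simulate import DEFAULT_ADAPTOR

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "simdata"
RESULTS = ROOT / "results"

LIBS = (
    ("default_40S", "40S"), ("default_80S", "80S"), ("init40S", "40S"),
    *[(f"fil1_{c}_rep{r}", "40S") for c in ("untreated", "treated") for r in range(3)],
)


def main() -> None:
    models = build_transcriptome(
        read_fasta(SCRATCH / "utr5.fa"),
        read_fasta(SCRATCH / "cds.fa"),
        read_fasta(SCRATCH / "utr3.fa"),
        read_fasta(SCRATCH / "ext.fa"),
    )
    rrna = read_fasta(SCRATCH / "rrna.fa")
    index = ExactIndex(models)

    qc_rows = []
    for tag, lib in LIBS:
        reads = read_fastq(SCRATCH / f"{tag}.fastq")
        fps, qc = process_tcp_reads(reads, models, rrna, lib, DEFAULT_ADAPTOR, index=index)
        footprint_frame(fps).to_csv(SCRATCH / f"{tag}.footprints.tsv", sep="\t", index=False)
        truth_n = len(pd.read_csv(SCRATCH / f"{tag}.truth.tsv", sep="\t"))
        qc_rows.append(
            {"library": tag, "reads": qc["n_reads"], "parsed": qc["n_parsed"],
             "rrna_removed": sum(qc["contaminants"].values()),
             "unique": qc["n_unique"], "duplicates": qc["n_duplicates"],
             "footprints": qc["n_footprints"], "truth_footprints": truth_n}
        )
        print(f"{tag}: {qc['n_reads']} reads -> {qc['n_footprints']} footprints "
              f"({qc['n_duplicates']} PCR duplicates, "
              f"{sum(qc['contaminants'].values())} rRNA)")
    pd.DataFrame(qc_rows).to_csv(RESULTS / "preprocess_qc.tsv", sep="\t", index=False)
    print(f"QC table: {RESULTS / 'preprocess_qc.tsv'}")


if __name__ == "__main__":
    main()
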