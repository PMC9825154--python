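#!/usr/bin/env python
"""Build the synthetic merged transcriptome and annotate its uORFs.

Writes the four FASTA parts (extension, 5'UTR, CDS, 3'UTR) plus the rRNA
contaminant set under scratch/, and the transcript/uORF tables under
results/. The fil1-like gene must carry exactly six uORFs, the first with a
CUG start; uORFs 4-6 sit in the distal half of its 1200-nt leader.
"""

import sys
from pathlib import Path

import pandas as pd

from tcpseq import GeneratorParams, make_transcriptome
from tcpseq.io import write_fasta

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "simdata"
RESULTS = ROOT / "results"


def main(seed: int = 1) -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    params = GeneratorParams(seed=seed, n_genes=8)
    models, uorfs, rrna = make_transcriptome(params)

    parts = {"ext": {}, "utr5": {}, "cds": {}, "utr3": {}}
    rows = []
    for tid, m in models.items():
        s = m.sequence
        parts["ext"][tid] = s[: m.ext_len]
        parts["utr5"][tid] = s[m.ext_len : m.tss_pos + m.utr5_len]
        parts["cds"][tid] = s[m.start_codon_pos : m.stop_last_pos + 1]
        parts["utr3"][tid] = s[m.stop_last_pos + 1 :]
        rows.append(
            {"id": tid, "ext_len": m.ext_len, "utr5_len": m.utr5_len,
             "cds_len": m.cds_len, "utr3_len": m.utr3_len}
        )
    for name, seqs in parts.items():
        write_fasta(SCRATCH / f"{name}.fa", seqs)
    write_fasta(SCRATCH / "rrna.fa", rrna)

    pd.DataFrame(rows).to_csv(RESULTS / "transcripts.tsv", sep="\t", index=False)
    pd.DataFrame([u.__dict__ for u in uorfs]).to_csv(
        RESULTS / "uorfs.tsv", sep="\t", index=False
    )

    fil1 = [u for u in uorfs if u.transcript_id == "fil1_like"]
    print(f"built {len(models)} transcripts (seed {seed})")
    print(f"fil1-like leader: {models['fil1_like'].utr5_len} nt, {len(fil1)} uORFs; "
          f"starts: {[u.start_codon for u in fil1]}")
    print(f"tables: {RESULTS / 'transcripts.tsv'}, {RESULTS / 'uorfs.tsv'}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
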