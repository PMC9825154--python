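#!/usr/bin/env python
"""Simulate TCP-seq libraries and emit UMI-bearing FASTQ reads.

Four library sets are produced (FASTQ + truth tables under scratch/):
  * a default-mix 40S library and a default-mix 80S library (10,000
    footprints each: initiation, scanning, cap-bound, CDS-contaminant and
    rRNA classes for 40S; initiating/elongating ribosomes and rRNA for 80S);
  * a pure initiation-class 40S library (the metagene-mode benchmark);
  * a paired 3-replicate scanning design on the fil1-like leader
    (untreated vs treated, 10,000 scanning footprints each).
"""

import sys
from pathlib import Path

import numpy as np

from tcpseq import GeneratorParams, make_transcriptome
from tcpseq.io import write_fastq
from tcpseq.simulate import emit_tcp_reads, simulate_footprints, truth_frame

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "simdata"

N = 10_000


def _emit(tag, truth, seqs, params, cond="untreated", rep=0, lib="40S"):
    rng = np.random.default_rng(
        [params.seed, 13, {"untreated": 0, "treated": 1}[cond], rep,
         {"40S": 0, "80S": 1}[lib]]
    )
    reads, _ = emit_tcp_reads(truth, seqs, params, rng=rng)
    write_fastq(SCRATCH / f"{tag}.fastq", reads)
    truth_frame(truth).to_csv(SCRATCH / f"{tag}.truth.tsv", sep="\t", index=False)
    print(f"{tag}: {len(truth)} footprints -> {len(reads)} reads")


def main(seed: int = 1) -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    params = GeneratorParams(seed=seed, n_genes=8)
    models, _, rrna = make_transcriptome(params)
    seqs = {tid: m.sequence for tid, m in models.items()} | rrna

    for lib in ("40S", "80S"):
        truth = simulate_footprints(models, params, library=lib, n=N, rrna=rrna)
        _emit(f"default_{lib}", truth, seqs, params, lib=lib)

    truth = simulate_footprints(
        models, params, n=N, components=("init_ssu",), rrna=rrna
    )
    _emit("init40S", truth, seqs, params)

    for cond in ("untreated", "treated"):
        for rep in range(3):
            truth = simulate_footprints(
                models, params, condition=cond, replicate=rep, n=N,
                components=("scanning_ssu",), genes=["fil1_like"], rrna=rrna,
            )
            _emit(f"fil1_{cond}_rep{rep}", truth, seqs, params, cond=cond, rep=rep)


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
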