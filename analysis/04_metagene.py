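#!/usr/bin/env python
"""Metagene heatmaps, projections and modes for the processed libraries.

From the deduplicated footprint tables: start-codon-anchored 5'/3' heatmaps
and projections for the initiation-class 40S library and the default 80S
library, TSS-anchored maps for the default 40S library, footprint length
histograms, and the recovered modes. Tables go to results/, figures to
results/figures/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from tcpseq import build_transcriptome
from tcpseq.footprints import footprints_from_frame
from tcpseq.io import read_fasta
from tcpseq.metagene import build_heatmap, find_modes, length_histogram, project
from tcpseq.pipeline import initiation_summary

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "simdata"
RESULTS = ROOT / "results"
FIGS = RESULTS / "figures"


def _load(tag):
    return footprints_from_frame(pd.read_csv(SCRATCH / f"{tag}.footprints.tsv", sep="\t"))


def _plot_heatmap(m, title, path):
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.imshow(
        m.counts, aspect="auto", origin="lower", cmap="viridis",
        extent=[m.pos_range[0], m.pos_range[1], m.len_range[0], m.len_range[1]],
    )
    ax.set_xlabel("distance to start codon (nt)")
    ax.set_ylabel("footprint length (nt)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def main() -> None:
    FIGS.mkdir(parents=True, exist_ok=True)
    models = build_transcriptome(
        read_fasta(SCRATCH / "utr5.fa"), read_fasta(SCRATCH / "cds.fa"),
        read_fasta(SCRATCH / "utr3.fa"), read_fasta(SCRATCH / "ext.fa"),
    )

    init40 = _load("init40S")
    s = initiation_summary(init40)
    print("40S initiation library:")
    print(f"  5'-end projection mode: {s['mode_5p']} nt (expected -12)")
    print(f"  3'-end projection modes: {s['modes_3p']} nt (expected +19/+25)")
    print(f"  length modes: {s['length_mode_primary']} / {s['length_mode_secondary']} nt "
          f"(expected 32 / ~65)")

    for end, name in (("five_prime", "5p"), ("three_prime", "3p")):
        m = build_heatmap(init40, end=end)
        m.to_frame().to_csv(RESULTS / f"heatmap_40S_start_{name}.tsv", sep="\t")
        project(m).to_frame().to_csv(
            RESULTS / f"projection_40S_start_{name}.tsv", sep="\t", index=False
        )
        _plot_heatmap(m, f"40S initiation library, {name} ends", FIGS / f"heatmap_40S_{name}.png")

    ribo = _load("default_80S")
    m5 = build_heatmap(ribo, end="five_prime", pos_range=(-40, 60))
    p5 = project(m5)
    mode80 = int(p5.positions[p5.values.argmax()])
    inside = [f for f in ribo if f.region in ("cds", "start_site")]
    hist = length_histogram(inside)
    mode_len = int(hist.positions[hist.values.argmax()])
    frame0 = sum((f.rel5 + 12) % 3 == 0 for f in inside) / len(inside)
    print("80S library:")
    print(f"  5'-end mode: {mode80} nt; CDS/start length mode: {mode_len} nt; "
          f"in-frame fraction: {frame0:.2f}")
    m5.to_frame().to_csv(RESULTS / "heatmap_80S_start_5p.tsv", sep="\t")
    _plot_heatmap(m5, "80S library, 5' ends", FIGS / "heatmap_80S_5p.png")

    full40 = _load("default_40S")
    for end, name in (("five_prime", "5p"), ("three_prime", "3p")):
        m = build_heatmap(full40, anchor="tss", end=end, models=models)
        m.to_frame().to_csv(RESULTS / f"heatmap_40S_tss_{name}.tsv", sep="\t")
    print("TSS-anchored 40S heatmaps written (vertical 5' line, diagonal 3' line).")

    hist40 = length_histogram(init40)
    hist40.to_frame().to_csv(RESULTS / "length_hist_40S.tsv", sep="\t", index=False)
    hist.to_frame().to_csv(RESULTS / "length_hist_80S.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
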