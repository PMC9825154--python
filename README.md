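# tcpseq

Analysis of **translation-complex profiling (TCP-seq)** data: from raw
UMI-bearing reads to scanning-subunit footprint statistics.

TCP-seq cross-links translation complexes in vivo, digests unprotected mRNA,
separates 40S (small-subunit) and 80S (full-ribosome) fractions on sucrose
gradients, and sequences the protected fragments (footprints). Unlike
ordinary ribosome profiling it captures *scanning* small subunits, so it can
show where initiation complexes queue at start codons, pile up along 5'
leaders, and bypass upstream open reading frames (uORFs) under stress. This
package implements the complete computational side of such an experiment for
anyone analysing 40S/80S footprint libraries:

- **annotation** — merged-coordinate transcript models
  (100-nt extension + 5'UTR + CDS + 3'UTR) and uORF discovery, including
  near-cognate (CUG) starts;
- **simulate** — a ground-truth synthetic footprint generator encoding the
  known positional/length structure of initiation complexes (common 5' end at
  −12; 3'-end modes +19/+25; a ~65-nt extended-protection class; 31–35 nt 80S
  footprints with triplet periodicity; cap-bound subunits at the TSS; rRNA
  and 60S-loss contaminants; a regulated 6-uORF leader);
- **preprocess** — parsing of the two custom library layouts
  (`RRRR‑insert‑RRRR‑adaptor` single-end; `RRRRRRRRA…`/`RRRRRRRRT…`
  paired-end with merged 16-nt UMIs), adaptor trimming, rRNA filtering,
  exact transcriptome mapping (or SAM/BAM import), UMI deduplication;
- **footprints / metagene / profiles** — start-codon- and TSS-anchored
  (length × end-position) heatmaps with projections and mode finding,
  full-span per-gene coverage tracks, length-segmented tracks;
- **stats** — SSU peak coverage `h_utr / (h_utr + h_aug)` and gene ranking,
  distal-leader window fractions with paired t-tests, translational
  efficiency `(FP_CDS/lib_FP)/(RNA_CDS/lib_RNA)`, reporter normalisation and
  efficiency-corrected qPCR (ddCq) ratios.

## Worked example

Simulate a 40S initiation-class library, push the raw reads blind through the
whole pipeline, and recover the complex structure:

```python
from tcpseq import GeneratorParams, make_transcriptome
from tcpseq.pipeline import initiation_summary, run_synthetic_library

params = GeneratorParams(seed=1, n_genes=8)
models, uorfs, rrna = make_transcriptome(params)
run = run_synthetic_library(models, rrna, params, library="40S",
                            n=10_000, components=("init_ssu",))
print(run.qc["n_footprints"], "footprints after dedup")
print(initiation_summary(run.footprints))
```

```
9998 footprints after dedup
{'mode_5p': -12, 'modes_3p': [19, 25], 'length_mode_primary': 32,
 'length_mode_secondary': 66}
```

Reading: 10,000 simulated footprints became ~15k reads (geometric PCR
duplication); parsing, mapping and UMI deduplication recovered 9,998 of them
(two lost to UMI birthday collisions). The 5'-end metagene projection peaks
at −12 (the P site of an initiating subunit sits over the AUG), the 3'-end
projection is bimodal at +19/+25 (two co-existing initiation complexes), and
the length histogram has its primary mode at 32 nt with a secondary
extended-protection mode near 65 nt.

The numbered scripts under `analysis/` run the full narrative on files
(FASTA/FASTQ in `scratch/`, tables in `results/`):

```sh
python analysis/01_build_transcriptome.py   # transcripts + uORF annotation
python analysis/02_simulate_libraries.py    # FASTQ + truth tables
python analysis/03_preprocess.py            # parse/filter/map/dedup + QC
python analysis/04_metagene.py              # heatmaps, projections, modes
python analysis/05_gene_profiles.py         # per-gene tracks, peak-coverage ranking
python analysis/06_fil1_window.py           # distal-window fold change + paired t
python analysis/07_reporter_qpcr.py         # reporter %-of-reference, ddCq
```

For instance, `06_fil1_window.py` measures, on a 1200-nt six-uORF leader, the
fraction of 40S footprint 5' ends in the distal window [720, 1200) across
three paired replicates and prints:

```
fold change: 3.729 (generator truth 3.8)
paired t = 91.47, two-sided p = 1.19e-04, n_pairs = 3
```

i.e. starvation lets scanning subunits past the repressive uORFs into the
distal half of the leader, and the pipeline recovers the planted 3.8-fold
shift from raw reads.

See `docs/methods.md` for the model, conventions, parameter defaults and
limitations.

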