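# Methods

## Scope and model

`tcpseq` analyses translation-complex profiling (TCP-seq) data: RNase-protected
mRNA fragments (footprints, FPs) from separately purified 40S (small-subunit)
and 80S (full-ribosome) fractions, sequenced with UMI-bearing small-RNA
libraries and mapped to a merged transcriptome. The package implements the
complete desk-side analysis — read parsing, UMI deduplication, footprint
coordinates, metagene heatmaps, per-gene tracks and occupancy statistics —
plus a synthetic footprint generator that encodes the known positional/length
structure of initiation complexes, so that the pipeline can be validated by
blind recovery of generator truth.

## Coordinate conventions

Transcripts are modelled as `extension (100 nt) + 5'UTR + CDS + 3'UTR` in a
single 0-based coordinate system. The extension absorbs footprints whose 5'
ends fall upstream of the annotated TSS. Anchors: `tss_pos = ext_len`,
`start_codon_pos = ext_len + utr5_len`. Footprints occupy the closed interval
`[start, start + length - 1]`; `rel5 = start - start_codon_pos` and
`rel3 = rel5 + length - 1`. This makes the canonical arithmetic exact: an
initiating small subunit with `rel5 = -12` and length 32 has `rel3 = +19`;
length 38 gives `rel3 = +25`. The extension is supplied as explicit sequence
(generator-provided here; genomic upstream sequence in real use) — no genome
lookups are attempted.

## uORF discovery

`find_uorfs` scans the annotated leader for start-codon occurrences (AUG by
default; near-cognate mode adds CUG) and extends each in frame to the first
stop codon anywhere downstream, flagging uORFs whose stop lies at/after the
main start codon (`overlaps_cds`) instead of rejecting them. Overlapping and
nested uORFs are all reported; a uORF with no in-frame stop before the
transcript end is dropped with a warning. Near-cognate scanning is opt-in
because genome-wide non-AUG behaviour is generally unknown; the regulated
fil1-like leader is annotated with it.

## Synthetic data generator

Component classes and their defaults (all config-exposed in
`GeneratorParams`):

| class | placement | lengths |
|---|---|---|
| `init_ssu` (40S) | 5' end at −12 rel. start codon, jitter −1/0/+1 with P = 0.2/0.6/0.2 | mixture: N(32, 1) w 0.45, N(38, 1) w 0.35, N(65, 4) w 0.20 (rounded, clipped to 15–100) |
| `scanning_ssu` (40S) | 5' ends across the 5'UTR | uniform 60–80 nt |
| `tss_ssu` (40S) | 5' end exactly at the TSS | 3' end uniform +20..+80 rel. TSS |
| `cds_contaminant` (40S) | 80S-like, codon boundaries in the CDS | 31–35 nt, mode 32 |
| `ribo_init` (80S) | 5' end at −12 exactly | 31–35 nt, PMF (0.08, 0.55, 0.17, 0.12, 0.08) |
| `ribo_elong` (80S) | 5' = −12 + 3k for codon index k ≥ 1 (triplet periodicity) | as `ribo_init` |
| `rrna` | uniform within 18S/28S-like decoys | 25–70 nt |

Within-library weights are 0.45/0.30/0.15 for init/scanning/tss with the CDS
contaminant at `cds_contaminant_frac = 0.10`, and 0.40/0.60 for
ribo_init/ribo_elong. These mixture weights, the jitter widths and the
duplicate-multiplicity law are generator conventions (chosen so the documented
modes dominate), not measured quantities. `rrna_frac = 0.20` applies as a
top-level mixture, so the rRNA read fraction is exactly 0.20; consequently
`cds_contaminant_frac` is the weight among mRNA-derived components.

The generated transcriptome always contains a fil1-like gene (1200-nt leader,
six planted uORFs — the first CUG-started, uORFs 4–6 in the distal window)
and a leaderless gene (`utr5_len = 0`). The leader is rewritten so ATG/CTG
occur *only* at the planted starts: every spurious occurrence has its middle T
replaced by C. The rewrite terminates (each step removes a T) and cannot
create or destroy a stop codon (all stops need a T at the mutated position),
so the planted reading frames are preserved and "exactly six uORFs" is a
deterministic invariant. All sequences are drawn so that every 20-mer is
unique across transcriptome and rRNA decoys (checked, regenerated on
collision), which makes exact substring mapping of gel-cut inserts (≥ 15 nt)
unambiguous.

The treated condition moves the fraction of fil1-like scanning 5' ends inside
[720, 1200) from 0.10 to 0.38; 0.38 = 3.8 × 0.10 realises the documented
fold change as generator truth.

Reads: `4 random nt + fragment + 4 random nt + adaptor
(TGGAATTCTCGGGTGCCAAGG)`, truncated to 100 nt; PCR multiplicity is geometric
(p = 0.65) and duplicates share UMI and insert. Paired-end RNA-seq fragments
use `8 random nt + A + fragment` / `8 random nt + T + reverse complement`,
75 nt each, the two octamers forming a 16-nt UMI. Sequencing errors default
to 0; a uniform substitution rate exists for robustness experiments only.

What the generator does **not** emulate: base-quality profiles, ligation and
PCR sequence bias, cross-linking efficiency, RNase digestion heterogeneity,
spliced or antisense reads, and realistic expression dispersion. Passing
recovery tests therefore demonstrates the correctness of the pipeline's
bookkeeping and statistics under the stated positional model, not robustness
to every artefact of real libraries.

## Preprocessing

Adaptor location: leftmost full-adaptor match, else the longest adaptor
prefix (≥ 10 nt) anchored at the read 3' end; an adaptorless 100-nt read is
treated as "insert pushed the adaptor out" with a positional UMI and a
low-confidence flag. Inserts outside the 15–100 nt gel cut are rejected with
reason codes. Contaminant filtering removes inserts that match any rRNA
substring exactly, counted per species. Mapping is sense-strand exact
substring search (both chemistries are stranded); multi-hit inserts are
classed ambiguous and discarded. Deduplication keys on
(transcript, start, length, UMI) *after* alignment — tolerant of trimming
ambiguity at read ends and standard UMI practice — keeping the smallest read
id; UMIs are not error-clustered. External aligners can be substituted via
`alignments_from_sam` (RX-style UMI tag).

## Footprint classes and metagenes

Region labels: `start_site` when `rel5 ∈ [−15, +3]`; `stop_site` when the 3'
end lies within [stop − 3, stop + 15]; otherwise 5'UTR/CDS/3'UTR by footprint
midpoint. Both window rules are package conventions (config-exposed); no
published boundary definition exists for them. Length bins: ≤ 35 / 36–59 /
≥ 60 nt. Frame: `(rel5 + 12) mod 3` with the P-site offset fixed at 12.

Heatmaps accumulate (length × end-position) counts for a chosen anchor
(start codon or TSS) and end; default ranges [−100, +50] (start anchor) and
[−10, +150] (TSS anchor). Projections are column sums (exact count
conservation). `find_modes` takes local maxima in decreasing height with a
greedy pairwise separation (default 4 nt — wide enough to keep the +19/+25
pair apart while suppressing 1-nt jitter peaks; 10 nt for length histograms,
which keeps the 32/38 pair merged while resolving the ~65 nt class), ties
broken toward the smaller position. Metagenes pool raw footprints
(footprint-weighted); per-gene equal weighting is left to the caller by
building per-gene heatmaps.

## Per-gene tracks and statistics

Tracks count footprints whose whole span covers each position (not end
counts), matching how single-gene profiles are conventionally drawn;
normalisation is per-library by track maximum, and length-segmented tracks
share the all-lengths maximum so bins remain comparable. Peak height for the
SSU peak-coverage statistic is likewise full-span coverage. The statistic is
`h_utr / (h_utr + h_aug)` with `h_aug = max coverage over rel5 ∈ [−12, +35]`
and `h_utr = max over [−utr5_len, −13]`; the AUG window is chosen so an
initiating footprint (5' = −12, 3' ≤ +52) peaks inside it. Leaders shorter
than 5 nt are flagged not computable.

The distal-window statistic counts footprint 5' ends (unambiguous membership)
in a half-open window in TSS coordinates, here [720, 1200) of a 1200-nt
leader, over all leader 5' ends as denominator. The fold change is the ratio
of condition means across paired replicates; significance is a two-sided
paired t-test on the raw per-replicate fractions (no transformation), with
zero-variance differences reported as p = 1.0 plus a degenerate flag rather
than an error. The t statistic is computed from first principles; scipy
supplies only the t-distribution tail (and serves as an independent oracle in
tests via `ttest_rel`).

Translational efficiency is `(fp_cds / lib_fp) / (rna_cds / lib_rna)`,
CDS-restricted on both sides, undefined at zero RNA counts, and invariant
under common library-depth rescaling. Reporter values are expressed as
percent of a reference construct within replicate and the starvation response
as per-replicate log2 ratios tested against zero. qPCR ratios are
efficiency-corrected, `(1+E_t)^ΔCq_t / (1+E_r)^ΔCq_r` with ΔCq = control −
treated (defaults E_t = 0.9546, E_r = 1.004), with a plain 2^−ddCq mode.

## Problem sizes and determinism

The analysis scripts and acceptance checks use 10,000 footprints per library
(3 paired replicates for the window design), 8 genes, and the default
component mixtures; at these sizes every mode recovery and the window fold
are stable across seeds. All randomness flows from a single integer seed
through per-(condition, replicate, library) child generators, so repeated
runs are byte-identical, including FASTQ output. UMI birthday collisions at
heavily piled positions can merge a handful of distinct footprints per
10,000 (< 0.1%); exact-count assertions are therefore made on dispersed
components, and recovery assertions use a ≥ 99% threshold.

## Known limitations

- The exact mapper requires collision-free sequences and error-free reads;
  real data should be aligned externally and imported.
- Ambiguous reads are discarded rather than rescued; no UMI error correction.
- The distal-window origin is the annotated TSS; with CAGE-refined or
  extended-coordinate origins the window must be re-specified by the caller.
- No differential-expression or differential-TE calling; the package emits
  count tables consumable by dedicated tools.
- Stop-site/termination analyses are out of scope beyond the region label.
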