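"""Synthetic TCP-seq data with per-footprint ground truth.

The generator emulates the positional and length structure of translation
complexes on mRNAs so that the whole downstream pipeline can be exercised and
scored blind against a truth table:

* 40S initiation footprints share a common 5' end 12 nt upstream of the start
  codon (+/- 1 nt jitter) and a trimodal length mixture (narrow modes at 32
  and 38 nt, hence 3' ends near +19 and +25, plus a broad ~65 nt class
  attributed to lingering initiation factors or queued subunits).
* Scanning 40S footprints have 5' ends across the 5' UTR and extended
  protection (>= 60 nt).
* Cap-associated 40S footprints start exactly at the TSS with variable 3'
  ends (a vertical 5' line, a diagonal 3' line in TSS-anchored heatmaps).
* 80S footprints are ~32 nt (31-35), 5' end 12 nt upstream of the P-site
  codon, placed on codon boundaries, so CDS footprints show triplet
  periodicity.
* A fraction of the 40S library is an 80S-like CDS contaminant class
  (60S subunits lost during purification), plus rRNA contaminant reads.
* A fil1-like 1200-nt leader carries six planted uORFs (the first starting
  CUG, the rest AUG); the treated condition moves scanning-footprint mass
  into the distal window [720, 1200), emulating uORF bypass under amino acid
  starvation.

Footprints become single-end 100 nt reads with the small-RNA library layout
``4 random nt + fragment + 4 random nt + adaptor`` (the eight random bases are
the UMI); PCR duplicates are drawn with a geometric multiplicity and share
UMI and insert. Paired-end RNA-seq fragments use the 8+1 anchored layout with
a merged 16-nt UMI. Everything is deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotation import NEAR_COGNATE_STARTS, STOP_CODONS, TranscriptModel, UORF, find_uorfs
from .io import FastqRead

DEFAULT_ADAPTOR = "TGGAATTCTCGGGTGCCAAGG"
FIL1_LIKE_ID = "fil1_like"
SHORT_LEADER_ID = "short_leader_like"

COMPONENTS_40S = ("init_ssu", "scanning_ssu", "tss_ssu", "cds_contaminant")
COMPONENTS_80S = ("ribo_init", "ribo_elong")

_CONDITION_CODE = {"untreated": 0, "treated": 1}
_LIBRARY_CODE = {"40S": 0, "80S": 1}

_BASES = np.array(list("ACGT"))
_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]


@dataclass(frozen=True)
class GeneratorParams:
    """Generator configuration; defaults encode the study conditions."""

    seed: int = 1
    n_genes: int = 8
    reads_per_library: int = 10_000
    ext_len: int = 100
    # 40S initiation complexes
    ssu_init_5p_offset: int = -12
    ssu_init_jitter: tuple[float, float, float] = (0.2, 0.6, 0.2)  # P(-1, 0, +1)
    ssu_len_modes: tuple[int, int] = (32, 38)
    ssu_long_len_mode: int = 65
    ssu_len_weights: tuple[float, float, float] = (0.45, 0.35, 0.20)
    ssu_len_sd: float = 1.0
    ssu_long_len_sd: float = 4.0
    # scanning and cap-associated 40S components
    scanning_len_min: int = 60
    scanning_len_max: int = 80
    tss_3p_range: tuple[int, int] = (20, 80)
    # 80S ribosomes (lengths 31-35, mode 32)
    ribo_len_mode: int = 32
    ribo_len_pmf: tuple[float, ...] = (0.08, 0.55, 0.17, 0.12, 0.08)
    # library composition
    weights_40s: tuple[float, float, float] = (0.45, 0.30, 0.15)  # init, scanning, tss
    cds_contaminant_frac: float = 0.10
    weights_80s: tuple[float, float] = (0.40, 0.60)  # init, elong
    rrna_frac: float = 0.20
    # fil1-like leader and the starvation response
    fil1_utr5_len: int = 1200
    fil1_window: tuple[int, int] = (720, 1200)
    window_mass_untreated: float = 0.10
    window_mass_treated: float = 0.38
    # library prep
    adaptor: str = DEFAULT_ADAPTOR
    dup_geom_p: float = 0.65
    seq_error_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("cds_contaminant_frac", "rrna_frac", "window_mass_untreated",
                     "window_mass_treated", "seq_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        lo, hi = self.fil1_window
        if not (0 <= lo < hi <= self.fil1_utr5_len):
            raise ValueError("fil1_window must lie within [0, fil1_utr5_len)")
        if min(self.ssu_len_modes) <= 0 or self.ssu_long_len_mode <= 0 or self.ribo_len_mode <= 0:
            raise ValueError("length modes must be positive")
        if not 0.0 < self.dup_geom_p <= 1.0:
            raise ValueError("dup_geom_p must be in (0, 1]")

    @property
    def ssu_init_3p_modes(self) -> tuple[int, int]:
        """Implied 3'-end modes of initiation footprints (closed-interval arithmetic)."""
        return tuple(self.ssu_init_5p_offset + m - 1 for m in self.ssu_len_modes)


@dataclass(frozen=True)
class SimulationTruth:
    """One generated footprint with its generative component label."""

    transcript_id: str
    component: str
    start: int
    length: int
    library: str
    condition: str
    replicate: int


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _random_codons(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, len(_NON_STOP_CODONS), n)
    return "".join(_NON_STOP_CODONS[i] for i in idx)


# planted fil1-like uORFs: (start offset rel TSS, start codon, total length nt)
_FIL1_UORFS = (
    (100, "CTG", 30),
    (250, "ATG", 45),
    (430, "ATG", 60),
    (760, "ATG", 45),
    (900, "ATG", 75),
    (1050, "ATG", 36),
)


def _scrub_leader(leader: list[str], planted_starts: set[int]) -> None:
    """Rewrite a leader in place so ATG/CTG occur only at planted uORF starts.

    Each pass replaces the middle T of a spurious ATG/CTG with C. The
    rewriting terminates (every mutation removes a T) and cannot create a stop
    codon (all stops require a T at the mutated position), so planted uORF
    reading frames and stops are preserved.
    """
    n = len(leader)
    while True:
        dirty = False
        for i in range(n - 2):
            tri = leader[i] + leader[i + 1] + leader[i + 2]
            if tri in ("ATG", "CTG") and i not in planted_starts:
                leader[i + 1] = "C"
                dirty = True
        if not dirty:
            return


def _build_fil1_leader(rng: np.random.Generator, utr5_len: int) -> str:
    leader = list(_random_seq(rng, utr5_len))
    planted: set[int] = set()
    for start, codon, length in _FIL1_UORFS:
        body = _random_codons(rng, length // 3 - 2)
        orf = codon + body + "TAA"
        leader[start : start + length] = list(orf)
        planted.add(start)
    _scrub_leader(leader, planted)
    return "".join(leader)


def _kmers_unique(seqs: Iterable[str], k: int = 20) -> bool:
    seen: set[str] = set()
    for s in seqs:
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            if kmer in seen:
                return False
            seen.add(kmer)
    return True


def make_transcriptome(
    params: GeneratorParams,
) -> tuple[dict[str, TranscriptModel], list[UORF], dict[str, str]]:
    """Generate transcript models, their uORF annotation, and rRNA contaminants.

    The gene set always contains one fil1-like transcript (1200-nt leader with
    six planted uORFs, the first starting CUG) and one leaderless transcript
    (``utr5_len == 0``, like ribosomal-protein genes with very short UTRs).
    Sequences are drawn so that every 20-mer is unique across the transcriptome
    and the rRNA set, which makes exact substring mapping unambiguous for any
    insert of gel-cut length. Deterministic under ``params.seed``.
    """
    if params.n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    for attempt in range(20):
        rng = np.random.default_rng([params.seed % (2**31), 7, attempt])
        models = _build_models(params, rng)
        rrna = {
            "rRNA_18S": _random_seq(rng, 1800),
            "rRNA_28S": _random_seq(rng, 3400),
        }
        if _kmers_unique([m.sequence for m in models.values()] + list(rrna.values())):
            uorfs: list[UORF] = []
            for m in models.values():
                codons = NEAR_COGNATE_STARTS if m.id == FIL1_LIKE_ID else ("ATG",)
                uorfs.extend(find_uorfs(m, start_codons=codons))
            return models, uorfs, rrna
    raise RuntimeError("could not build a collision-free transcriptome")


def _build_models(params: GeneratorParams, rng: np.random.Generator) -> dict[str, TranscriptModel]:
    models: dict[str, TranscriptModel] = {}
    for i in range(params.n_genes):
        if i == 0:
            tid = FIL1_LIKE_ID
            utr5 = _build_fil1_leader(rng, params.fil1_utr5_len)
        elif i == 1:
            tid = SHORT_LEADER_ID
            utr5 = ""
        else:
            tid = f"gene{i:03d}"
            utr5 = _random_seq(rng, int(rng.integers(60, 301)))
        n_codons = int(rng.integers(110, 200))
        cds = "ATG" + _random_codons(rng, n_codons - 2) + "TAA"
        utr3 = _random_seq(rng, int(rng.integers(50, 151)))
        ext = _random_seq(rng, params.ext_len)
        models[tid] = TranscriptModel(
            id=tid,
            sequence=ext + utr5 + cds + utr3,
            ext_len=params.ext_len,
            utr5_len=len(utr5),
            cds_len=len(cds),
            utr3_len=len(utr3),
        )
    return models


def _component_weights(params: GeneratorParams, library: str) -> dict[str, float]:
    if library == "40S":
        w = dict(zip(("init_ssu", "scanning_ssu", "tss_ssu"), params.weights_40s))
        w["cds_contaminant"] = params.cds_contaminant_frac
    elif library == "80S":
        w = dict(zip(COMPONENTS_80S, params.weights_80s))
    else:
        raise ValueError(f"unknown library label {library!r}")
    if params.rrna_frac > 0:
        # top-level mixture: P(rrna) == rrna_frac exactly
        w["rrna"] = params.rrna_frac / (1.0 - params.rrna_frac) * sum(w.values())
    return w


def _draw_ssu_length(params: GeneratorParams, rng: np.random.Generator) -> int:
    j = rng.choice(3, p=np.asarray(params.ssu_len_weights) / sum(params.ssu_len_weights))
    if j < 2:
        mode, sd = params.ssu_len_modes[j], params.ssu_len_sd
    else:
        mode, sd = params.ssu_long_len_mode, params.ssu_long_len_sd
    return int(np.clip(round(rng.normal(mode, sd)), 15, 100))


def _draw_ribo_length(params: GeneratorParams, rng: np.random.Generator) -> int:
    lengths = np.arange(params.ribo_len_mode - 1, params.ribo_len_mode + 4)
    p = np.asarray(params.ribo_len_pmf) / sum(params.ribo_len_pmf)
    return int(rng.choice(lengths, p=p))


def simulate_footprints(
    models: Mapping[str, TranscriptModel],
    params: GeneratorParams,
    condition: str = "untreated",
    replicate: int = 0,
    library: str = "40S",
    n: int | None = None,
    components: Sequence[str] | None = None,
    genes: Sequence[str] | None = None,
    rrna: Mapping[str, str] | None = None,
) -> list[SimulationTruth]:
    """Draw ``n`` ground-truth footprints for one library.

    ``components`` restricts the generative mixture (weights renormalised);
    ``genes`` restricts placement to a transcript subset. Draws are seeded by
    (seed, condition, replicate, library), so replicate libraries are
    independent but reproducible.
    """
    if library not in _LIBRARY_CODE:
        raise ValueError(f"unknown library label {library!r}")
    if condition not in _CONDITION_CODE:
        raise ValueError(f"unknown condition {condition!r}")
    n = params.reads_per_library if n is None else int(n)
    rng = np.random.default_rng(
        [params.seed % (2**31), 11, _CONDITION_CODE[condition], replicate, _LIBRARY_CODE[library]]
    )
    weights = _component_weights(params, library)
    if components is not None:
        unknown = set(components) - set(weights)
        if unknown:
            raise ValueError(f"unknown components {sorted(unknown)} for {library} library")
        weights = {c: weights[c] for c in components}
    if "rrna" in weights and rrna is None and len(weights) > 0:
        # caller did not supply rRNA sequences; keep labels valid regardless
        pass
    names = sorted(weights)
    probs = np.asarray([weights[c] for c in names], dtype=float)
    probs /= probs.sum()

    pool = list(genes) if genes is not None else list(models)
    scan_pool = [t for t in pool if models[t].utr5_len > 0]
    rrna_ids = sorted(rrna) if rrna else []
    window_mass = (
        params.window_mass_treated if condition == "treated" else params.window_mass_untreated
    )

    out: list[SimulationTruth] = []
    draws = rng.choice(len(names), size=n, p=probs)
    for c_idx in draws:
        comp = names[c_idx]
        if comp == "rrna":
            if not rrna_ids:
                raise ValueError("rrna component requested but no rRNA sequences supplied")
            rid = rrna_ids[rng.integers(0, len(rrna_ids))]
            length = int(rng.integers(25, 71))
            start = int(rng.integers(0, len(rrna[rid]) - length + 1))
            out.append(SimulationTruth(rid, comp, start, length, library, condition, replicate))
            continue

        if comp == "scanning_ssu":
            tid = scan_pool[rng.integers(0, len(scan_pool))]
        else:
            tid = pool[rng.integers(0, len(pool))]
        m = models[tid]
        scp = m.start_codon_pos

        if comp == "init_ssu":
            jitter = int(rng.choice([-1, 0, 1], p=np.asarray(params.ssu_init_jitter)))
            start = scp + params.ssu_init_5p_offset + jitter
            length = _draw_ssu_length(params, rng)
        elif comp == "scanning_ssu":
            if tid == FIL1_LIKE_ID:
                lo, hi = params.fil1_window
                if rng.random() < window_mass:
                    rel = int(rng.integers(lo, hi))
                else:
                    rel = int(rng.integers(0, lo))
            else:
                rel = int(rng.integers(0, m.utr5_len))
            start = m.tss_pos + rel
            length = int(rng.integers(params.scanning_len_min, params.scanning_len_max + 1))
        elif comp == "tss_ssu":
            start = m.tss_pos
            length = int(rng.integers(params.tss_3p_range[0], params.tss_3p_range[1] + 1)) + 1
        elif comp in ("cds_contaminant", "ribo_elong"):
            k_max = m.cds_len // 3 - 12
            k = int(rng.integers(1, max(2, k_max)))
            start = scp + params.ssu_init_5p_offset + 3 * k
            length = _draw_ribo_length(params, rng)
        elif comp == "ribo_init":
            start = scp + params.ssu_init_5p_offset
            length = _draw_ribo_length(params, rng)
        else:  # pragma: no cover - guarded above
            raise AssertionError(comp)

        start = int(np.clip(start, 0, m.length - length))
        out.append(SimulationTruth(tid, comp, start, length, library, condition, replicate))
    return out


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = str(rng.choice([b for b in "ACGT" if b != chars[i]]))
    return "".join(chars)


def emit_tcp_reads(
    truth: Sequence[SimulationTruth],
    seqs: Mapping[str, str],
    params: GeneratorParams,
    rng: np.random.Generator | None = None,
) -> tuple[list[FastqRead], list[int]]:
    """Turn footprints into SE100 reads in the small-RNA library layout.

    Each footprint yields a geometric number of PCR duplicates that share the
    UMI (4 + 4 random nt flanking the insert) and insert; the read is
    ``UMI5 + fragment + UMI3 + adaptor`` truncated to 100 nt, so long
    fragments push the adaptor (and eventually the 3' UMI) off the read end.
    Returns the reads and the per-footprint multiplicities.
    """
    if not truth:
        raise ValueError("truth is empty")
    if rng is None:
        rng = np.random.default_rng([params.seed % (2**31), 13])
    reads: list[FastqRead] = []
    mults: list[int] = []
    for i, t in enumerate(truth):
        frag = seqs[t.transcript_id][t.start : t.start + t.length]
        umi5 = _random_seq(rng, 4)
        umi3 = _random_seq(rng, 4)
        template = (umi5 + frag + umi3 + params.adaptor)[:100]
        mult = int(rng.geometric(params.dup_geom_p))
        mults.append(mult)
        for j in range(mult):
            seq = _apply_errors(template, params.seq_error_rate, rng)
            reads.append(FastqRead(f"fp{i:07d}.{j}", seq))
    return reads, mults


_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def emit_rnaseq_pairs(
    models: Mapping[str, TranscriptModel],
    abundances: Mapping[str, float],
    params: GeneratorParams,
    n_pairs: int,
    rng: np.random.Generator | None = None,
) -> list[tuple[FastqRead, FastqRead]]:
    """PE75 RNA-seq pairs: ``8 random nt + A + fragment`` / ``8 random nt + T + rc``.

    Fragments are placed uniformly along each transcript (transcripts chosen
    by abundance); the two random octamers jointly form the 16-nt UMI. PCR
    duplicates share fragment and UMI.
    """
    tids = sorted(abundances)
    w = np.asarray([abundances[t] for t in tids], dtype=float)
    if (w <= 0).any():
        raise ValueError("abundances must be positive")
    w /= w.sum()
    if rng is None:
        rng = np.random.default_rng([params.seed % (2**31), 17])
    pairs: list[tuple[FastqRead, FastqRead]] = []
    picks = rng.choice(len(tids), size=n_pairs, p=w)
    for i, ti in enumerate(picks):
        m = models[tids[ti]]
        frag_len = int(min(rng.integers(100, 251), m.length))
        start = int(rng.integers(0, m.length - frag_len + 1))
        frag = m.sequence[start : start + frag_len]
        u1, u2 = _random_seq(rng, 8), _random_seq(rng, 8)
        fwd_seq = (u1 + "A" + frag)[:75]
        rev_seq = (u2 + "T" + revcomp(frag))[:75]
        mult = int(rng.geometric(params.dup_geom_p))
        for j in range(mult):
            pairs.append(
                (FastqRead(f"rp{i:07d}.{j}/1", fwd_seq), FastqRead(f"rp{i:07d}.{j}/2", rev_seq))
            )
    return pairs


def truth_frame(truth: Sequence[SimulationTruth]):
    """Truth records as a pandas DataFrame (for TSV export)."""
    import pandas as pd

    return pd.DataFrame([t.__dict__ for t in truth])
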