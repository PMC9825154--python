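"""FASTA/FASTQ and table IO, thin wrappers over Biopython and pandas."""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass(frozen=True)
class FastqRead:
    """A sequencing read; qualities are constant for synthetic data."""

    id: str
    seq: str


def _open(path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t" if "b" not in mode else mode)
    return open(path, mode)


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence mapping (duplicate ids are an error)."""
    out: dict[str, str] = {}
    with _open(path, "r") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in out:
                raise ValueError(f"duplicate FASTA identifier {rec.id!r} in {path}")
            out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(path, seqs: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with _open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fastq(path) -> list[FastqRead]:
    with _open(path, "r") as fh:
        return [FastqRead(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fastq")]


def write_fastq(path, reads: Iterable[FastqRead]) -> None:
    with _open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


def write_table(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
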