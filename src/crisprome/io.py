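"""Thin I/O wrappers: FASTA/FASTQ via Biopython, TSV via pandas."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

__all__ = ["write_fasta", "read_fasta", "write_fastq", "read_fastq", "write_tsv", "read_tsv"]


def write_fasta(records, path) -> int:
    return SeqIO.write(records, str(path), "fasta")


def read_fasta(path):
    return list(SeqIO.parse(str(path), "fasta"))


def write_fastq(records, path) -> int:
    return SeqIO.write(records, str(path), "fastq")


def read_fastq(path):
    return SeqIO.parse(str(path), "fastq")


def write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
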