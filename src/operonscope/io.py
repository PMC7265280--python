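"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA/FASTQ go through Biopython; tabular files are TSV via pandas.
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

METADATA_COLUMNS = ["sample_id", "genotype", "activity"]
TRUTH_COLUMNS = ["read_id", "species_id", "copy_id", "direction"]


def write_fasta(records: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    """Write (id, sequence) pairs to a FASTA file."""
    seqs = [SeqRecord(Seq(s), id=str(i), description="") for i, s in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def write_fastq(records: Iterable[tuple[str, str]], path: str | os.PathLike, quality: int = 20) -> None:
    """Write (id, sequence) pairs as FASTQ with a flat placeholder quality."""
    seqs = []
    for i, s in records:
        rec = SeqRecord(Seq(s), id=str(i), description="")
        rec.letter_annotations["phred_quality"] = [quality] * len(s)
        seqs.append(rec)
    SeqIO.write(seqs, str(path), "fastq")


def read_sequences(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read FASTA or FASTQ by extension."""
    p = str(path)
    fmt = "fastq" if p.endswith((".fastq", ".fq")) else "fasta"
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(p, fmt)]


def write_metadata(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, columns=METADATA_COLUMNS)


def read_metadata(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata file missing columns: {sorted(missing)}")
    return df


def write_truth(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, columns=TRUTH_COLUMNS)


def read_truth(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"read_id": str, "species_id": str, "direction": str, "copy_id": int})


def write_table(df: pd.DataFrame, path: str | os.PathLike, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path: str | os.PathLike, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
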