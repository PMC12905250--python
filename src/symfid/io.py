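"""File I/O helpers: FASTA, association tables, TSV conventions.

All tables are tab-separated with header rows, UTF-8, '.' decimal.
Coordinates in gene tables are 1-based inclusive.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_fasta(path: str | Path, records: dict[str, str]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path),
        "fasta",
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_single_fasta(path: str | Path) -> str:
    records = read_fasta(path)
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one sequence, found {len(records)}")
    return next(iter(records.values()))


def write_association(path: str | Path, assoc: dict[str, str]) -> None:
    pd.DataFrame(
        {"symbiont_tip": list(assoc), "host_tip": [assoc[k] for k in assoc]}
    ).to_csv(path, sep="\t", index=False)


def read_association(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    for col in ("symbiont_tip", "host_tip"):
        if col not in df.columns:
            raise ValueError(f"{path}: association table lacks column {col!r}")
    return dict(zip(df["symbiont_tip"].astype(str), df["host_tip"].astype(str)))


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)
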