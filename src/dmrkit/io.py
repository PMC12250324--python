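"""Readers and writers for the pipeline's on-disk formats.

Call tables are tab-separated Bismark-coverage-like files (chrom, 1-based
position, strand, coverage, methylated count).  Interval tracks are BED
(half-open, 0-based); repeats are BED6+2 with class and family columns.
Repeat sequences travel as multi-FASTA with the family encoded in the record
id as ``FAMILY|name``.  Expression matrices are TSV with promoters as rows.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .diffmeth import CALL_COLUMNS, MethylationCallSet

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
REPEAT_BED_COLUMNS = BED6_COLUMNS + ["rep_class", "family"]


def read_calltable(path: str | Path, sample: str | None = None,
                   condition: str = "") -> MethylationCallSet:
    df = pd.read_csv(path, sep="\t", header=None, names=CALL_COLUMNS,
                     dtype={"chrom": str, "strand": str})
    name = sample if sample is not None else Path(path).stem
    return MethylationCallSet(df, sample=name, condition=condition)


def write_calltable(callset: MethylationCallSet, path: str | Path) -> None:
    callset.calls[CALL_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path, columns: list[str] | None = None) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype={0: str}, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=columns or BED6_COLUMNS[:3])
    names = columns or (
        REPEAT_BED_COLUMNS if df.shape[1] == 8 else BED6_COLUMNS[: df.shape[1]]
    )
    df.columns = names[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in REPEAT_BED_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_repeat_fasta(path: str | Path) -> dict[str, list[str]]:
    """Multi-FASTA grouped by family: record ids are ``FAMILY|name``."""
    families: dict[str, list[str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        family = rec.id.split("|", 1)[0]
        families.setdefault(family, []).append(str(rec.seq))
    return families


def write_repeat_fasta(families: Mapping[str, list[str]], path: str | Path) -> None:
    records = []
    for family in sorted(families):
        for i, seq in enumerate(families[family], start=1):
            records.append(
                SeqRecord(Seq(seq), id=f"{family}|{family}_{i}", description="")
            )
    SeqIO.write(records, str(path), "fasta")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_directions(path: str | Path) -> pd.Series:
    """Direction map TSV: promoter id, TF symbol, direction."""
    df = pd.read_csv(path, sep="\t")
    if "direction" not in df.columns:
        raise ValueError("direction map needs a 'direction' column")
    idcol = df.columns[0]
    return df.set_index(idcol)["direction"]


def write_directions(directions: pd.Series, path: str | Path,
                     symbols: Mapping[str, str] | None = None) -> None:
    df = pd.DataFrame({"promoter": directions.index, "direction": directions.values})
    df["tf_symbol"] = [
        (symbols or {}).get(p, p.split("@")[-1]) for p in df["promoter"]
    ]
    df[["promoter", "tf_symbol", "direction"]].to_csv(path, sep="\t", index=False)
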