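"""Readers and writers for the pipeline's file formats.

Spot tables are GenePix-results-style tab-delimited files (header row with
Block, Row, Column, ID, F635, B635, F532, B532, Flags; extra columns
ignored).  Expression matrices are TSV, features x samples, with ``NA`` for
missing.  Clinical tables are CSV with sample_id, time_months, event plus
covariate columns.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .preprocess import SPOT_COLUMNS

__all__ = [
    "read_spot_table", "write_spot_table", "read_spot_dir",
    "read_matrix", "write_matrix",
    "read_clinical", "write_clinical",
    "write_cohort",
]


def read_spot_table(path, sample_id: str | None = None) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing spot columns {missing}")
    df = df[SPOT_COLUMNS].copy()
    df.attrs["sample_id"] = sample_id or path.stem
    return df


def write_spot_table(df: pd.DataFrame, path) -> None:
    df[SPOT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_spot_dir(directory) -> list[pd.DataFrame]:
    paths = sorted(Path(directory).glob("*.txt")) + sorted(Path(directory).glob("*.tsv"))
    if not paths:
        raise FileNotFoundError(f"no spot tables (*.txt/*.tsv) in {directory}")
    return [read_spot_table(p) for p in paths]


def read_matrix(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, index_col=0, na_values=["NA"])


def write_matrix(mat: pd.DataFrame, path) -> None:
    mat.to_csv(path, sep="\t", na_rep="NA", index_label="feature_id")


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sample_id", "time_months", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns {sorted(missing)}")
    df["sample_id"] = df["sample_id"].astype(str)
    return df


def write_clinical(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_cohort(spot_tables, clinical, truth, out_dir) -> None:
    """Write a generated cohort: spots/<sample>.txt, clinical.csv, truth.json."""
    out = Path(out_dir)
    (out / "spots").mkdir(parents=True, exist_ok=True)
    for df in spot_tables:
        sid = df.attrs.get("sample_id", "sample")
        write_spot_table(df, out / "spots" / f"{sid}.txt")
    write_clinical(clinical, out / "clinical.csv")
    truth.to_json(out / "truth.json")
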