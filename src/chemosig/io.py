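"""Readers and writers for the package's plain-text formats.

All tables are tab-delimited UTF-8 with '.' decimals and mandatory headers:

* traces: first column ``time_s``, one column per ROI; an optional JSON
  sidecar carries ground-truth labels;
* compound tables: rows = compounds, columns = samples, plus a compound
  metadata TSV (compound_id, class, family) and a sample metadata TSV
  (sample_id, sex, strain, individual);
* protocols: JSON (see :mod:`chemosig.protocol`).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import CompoundTable
from .traces import TraceSet


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def write_traces(traces: TraceSet, path: str | Path) -> None:
    df = pd.DataFrame(traces.dff.T, columns=list(traces.roi_ids))
    df.insert(0, "time_s", traces.time_s)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_traces(path: str | Path) -> TraceSet:
    """Read a trace TSV, validating shape, monotone time and numeric body."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no data rows") from None
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    if df.columns[0] != "time_s":
        raise ValueError(f"{path}: first column must be 'time_s', got {df.columns[0]!r}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            row = int(bad[0]) + 2 if len(bad) else "?"
            raise ValueError(f"{path}: non-numeric cell in column {col!r}, line {row}")
        if df[col].isna().any():
            row = int(df.index[df[col].isna()][0]) + 2
            raise ValueError(f"{path}: missing value in column {col!r}, line {row}")
    time = df["time_s"].to_numpy(dtype=float)
    dup = np.flatnonzero(np.diff(time) == 0)
    if dup.size:
        # report the second of the duplicate pair; +2 header/1-based, +1 pair
        raise ValueError(f"{path}: duplicated timestamp at row {int(dup[0]) + 3}")
    return TraceSet(
        time_s=time,
        dff=df.iloc[:, 1:].to_numpy(dtype=float).T,
        roi_ids=list(df.columns[1:]),
    )


def write_trace_truth(truth: pd.DataFrame, path: str | Path) -> None:
    records = truth.replace({np.nan: None}).to_dict(orient="records")
    Path(path).write_text(json.dumps(records, indent=2) + "\n")


def read_trace_truth(path: str | Path) -> pd.DataFrame:
    return pd.DataFrame(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# compound tables
# ---------------------------------------------------------------------------

def write_compound_table(
    table: CompoundTable,
    table_path: str | Path,
    compound_meta_path: str | Path,
    sample_meta_path: str | Path,
) -> None:
    ab = table.abundance.rename_axis("compound_id")
    ab.to_csv(table_path, sep="\t", float_format="%.10g")
    table.compound_meta.rename_axis("compound_id").to_csv(
        compound_meta_path, sep="\t"
    )
    table.sample_meta.rename_axis("sample_id").to_csv(sample_meta_path, sep="\t")


def read_compound_table(
    table_path: str | Path,
    compound_meta_path: str | Path,
    sample_meta_path: str | Path,
    **table_kwargs,
) -> CompoundTable:
    """Read and cross-validate a compound table with its metadata files."""
    ab = pd.read_csv(table_path, sep="\t", index_col="compound_id")
    for col in ab.columns:
        if not np.issubdtype(ab[col].dtype, np.number):
            bad = ab.index[pd.to_numeric(ab[col], errors="coerce").isna()]
            raise ValueError(
                f"{table_path}: non-numeric abundance for compound "
                f"{bad[0]!r}, sample {col!r}"
            )
    neg = np.argwhere(ab.to_numpy() < 0)
    if neg.size:
        r, c = neg[0]
        raise ValueError(
            f"{table_path}: negative abundance at compound {ab.index[r]!r}, "
            f"sample {ab.columns[c]!r}"
        )
    compound_meta = pd.read_csv(compound_meta_path, sep="\t", index_col="compound_id")
    sample_meta = pd.read_csv(sample_meta_path, sep="\t", index_col="sample_id")
    if "family" not in compound_meta.columns:
        compound_meta["family"] = None
    mismatch = set(ab.columns) ^ set(sample_meta.index)
    if mismatch:
        raise ValueError(
            f"samples differ between {table_path} and {sample_meta_path}: "
            f"{sorted(mismatch)}"
        )
    return CompoundTable(
        abundance=ab,
        compound_meta=compound_meta,
        sample_meta=sample_meta,
        **table_kwargs,
    )


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t")


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
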