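"""Tab-separated file I/O for all tabular interfaces.

All matrices travel as TSV: a header row of sample ids, the first column
feature ids, absent cells encoded as ``NA``. Long tables (Ct values,
sample sheets, target maps) are plain TSV with named columns. Writing is
full precision so a write/read round trip is lossless.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .qpcr import CtTable

NA = "NA"


def _read_tsv(path, **kw) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    try:
        return pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False, **kw)
    except Exception as exc:  # pandas raises a zoo of parse errors
        raise FormatError(f"{path}: {exc}") from exc


def read_matrix(path) -> pd.DataFrame:
    """Read a features x samples matrix TSV.

    Raises :class:`FormatError` for duplicate ids or non-numeric cells
    (other than NA), naming the offending row/column.
    """
    df = _read_tsv(path, index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate feature id {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"{path}: duplicate sample id {dup!r}")
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: non-numeric cell in column {col!r}: {exc}") from exc
    df.index.name = "feature_id"
    return df


def write_matrix(matrix: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = matrix.copy()
    out.index.name = out.index.name or "feature_id"
    out.to_csv(path, sep="\t", na_rep=NA)


def read_sample_sheet(path) -> pd.DataFrame:
    df = _read_tsv(path)
    missing = {"sample_id", "group"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: sample sheet lacks column(s) {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"{path}: duplicate sample id {dup!r}")
    return df[["sample_id", "group"]]


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    sheet.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_ct_table(path, reference_assays, layer: str = "unspecified") -> CtTable:
    df = _read_tsv(path)
    missing = {"sample_id", "assay_id", "ct"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: Ct table lacks column(s) {sorted(missing)}")
    return CtTable(df, reference_assays=tuple(reference_assays), layer=layer)


def write_ct_table(ct: CtTable, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    ct.data.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_target_map(path) -> pd.DataFrame:
    df = _read_tsv(path)
    missing = {"mirna_id", "gene_id"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: target map lacks column(s) {sorted(missing)}")
    return df


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    """Write any long-format result table as TSV (NA for missing)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, na_rep=NA)
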