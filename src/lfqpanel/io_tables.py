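"""Read/write the tabular artifacts used throughout the pipeline.

All files are tab-separated UTF-8 text with a "." decimal separator and no
thousands separators.  Three dialects exist:

* peptide table — long format with columns ``protein, peptide, sample,
  replicate, intensity``;
* abundance matrix — protein accessions in the first column, one column per
  sample (or per ``sample|replicate`` before replicate averaging); a blank
  cell and ``0`` both mean "not detected";
* metadata — columns ``sample, group, replicate``.

Accession strings are opaque; nothing in the pipeline parses them.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import SchemaError, ValidationError

#: Closed set of study groups. DVD is the case group in every contrast.
GROUPS = ("NC", "T2DM", "VD", "DVD")

PEPTIDE_COLUMNS = ("protein", "peptide", "sample", "replicate", "intensity")
META_COLUMNS = ("sample", "group", "replicate")

#: Separator joining sample id and technical-replicate index in the column
#: labels of a per-replicate abundance matrix.
REPLICATE_SEP = "|"

_FLOAT_FMT = "%.8g"  # >= 6 significant digits on round-trip


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")


def read_peptide_table(path) -> pd.DataFrame:
    """Read a long-format peptide intensity table.

    Returns a DataFrame with the five required columns in canonical order,
    preserving row order.  Raises :class:`SchemaError` if a column is
    missing and :class:`ValidationError` on negative intensities or
    duplicated (protein, peptide, sample, replicate) keys.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein": str, "peptide": str, "sample": str})
    _require_columns(df, PEPTIDE_COLUMNS, path)
    df = df.loc[:, list(PEPTIDE_COLUMNS)]
    df["intensity"] = df["intensity"].astype(float)
    df["replicate"] = df["replicate"].astype(int)
    neg = np.flatnonzero(df["intensity"].to_numpy() < 0)
    if neg.size:
        raise ValidationError(f"{path}: negative intensity at data row {neg[0] + 1}")
    if (df["replicate"] < 1).any():
        raise ValidationError(f"{path}: replicate indices must be positive")
    key = ["protein", "peptide", "sample", "replicate"]
    if df.duplicated(key).any():
        dup = df[df.duplicated(key)].iloc[0]
        raise ValidationError(
            f"{path}: duplicate peptide measurement for "
            f"({dup['protein']}, {dup['peptide']}, {dup['sample']}, {dup['replicate']})"
        )
    return df


def write_peptide_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_abundance_matrix(path) -> pd.DataFrame:
    """Read a protein x sample abundance matrix.

    The first column holds protein accessions; remaining columns are sample
    (or ``sample|replicate``) labels.  Blank cells become 0 — the matrix
    format has no NA token, a missing measurement *is* a zero.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "protein"
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicate protein accession {dup!r}")
    if pd.Index(df.columns).duplicated().any():
        raise ValidationError(f"{path}: duplicate sample column label")
    df = df.astype(float).fillna(0.0)
    if (df.to_numpy() < 0).any():
        raise ValidationError(f"{path}: negative abundance value")
    return df


def write_abundance_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata (one row per sample x technical replicate)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "group": str})
    _require_columns(df, META_COLUMNS, path)
    df = df.loc[:, list(META_COLUMNS)]
    df["replicate"] = df["replicate"].astype(int)
    return validate_metadata(df)


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    if (metadata["sample"].str.len() == 0).any():
        raise ValidationError("empty sample id in metadata")
    bad = set(metadata["group"]) - set(GROUPS)
    if bad:
        raise ValidationError(f"unknown group(s) {sorted(bad)}; expected one of {GROUPS}")
    if metadata.duplicated(["sample", "replicate"]).any():
        raise ValidationError("duplicate (sample, replicate) in metadata")
    grp = metadata.drop_duplicates("sample").set_index("sample")["group"]
    per_sample = metadata.groupby("sample")["group"].nunique()
    if (per_sample > 1).any():
        raise ValidationError("a sample is assigned to more than one group")
    del grp
    return metadata


def sample_groups(metadata: pd.DataFrame) -> pd.Series:
    """Map sample id -> group, one entry per biological sample."""
    return metadata.drop_duplicates("sample").set_index("sample")["group"]


def require_min_group_size(metadata: pd.DataFrame, k: int = 2) -> None:
    counts = sample_groups(metadata).value_counts()
    small = counts[counts < k]
    if len(small):
        raise ValidationError(
            f"groups with fewer than {k} samples: {sorted(small.index)}"
        )


def replicate_column(sample: str, replicate: int) -> str:
    return f"{sample}{REPLICATE_SEP}{replicate}"


def split_replicate_column(label: str) -> tuple[str, int]:
    sample, _, rep = str(label).rpartition(REPLICATE_SEP)
    if not sample:
        raise ValidationError(f"column label {label!r} is not of the form sample{REPLICATE_SEP}replicate")
    return sample, int(rep)


def _records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    rows = list(records)
    if rows and dataclasses.is_dataclass(rows[0]):
        rows = [dataclasses.asdict(r) for r in rows]
    return pd.DataFrame(rows)


def write_results_table(records, path) -> None:
    """Write any homogeneous record collection as a TSV.

    Accepts a DataFrame, an iterable of dicts, or an iterable of dataclass
    instances.  Column order is the schema order of the first record and is
    deterministic; floats keep at least six significant digits.  An empty
    collection with no discoverable schema produces a header-less empty file
    only when the input is a schemaless iterable; pass a DataFrame to get a
    header-only file.
    """
    df = _records_to_frame(records)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
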