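"""Peptide-to-protein quantification: identification filter, Top-N
aggregation, summed-intensity normalization, replicate averaging, and
per-group coefficients of variation.

The chain is ``identification_filter -> top_n_abundance ->
normalize_summed_intensity -> average_replicates``; :func:`quantify_study`
runs it end to end.  Zeros mean "not detected" and are data: they are
excluded from Top-N averaging (a zero peptide carries no intensity) but they
*do* participate in replicate averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .io_tables import replicate_column, sample_groups, split_replicate_column


@dataclass
class QuantConfig:
    min_unique_peptides: int = 2
    top_n: int = 3
    normalization: str = "summed_intensity"  # or "none"
    #: Top-N statistic; "mean" is the default, "sum" is available.
    statistic: str = "mean"

    def validate(self) -> None:
        if self.min_unique_peptides < 1:
            raise ValidationError("min_unique_peptides must be >= 1")
        if self.top_n < 1:
            raise ValidationError("top_n must be >= 1")
        if self.normalization not in ("summed_intensity", "none"):
            raise ValidationError(f"unknown normalization {self.normalization!r}")
        if self.statistic not in ("mean", "sum"):
            raise ValidationError(f"unknown Top-N statistic {self.statistic!r}")


def identification_filter(table: pd.DataFrame, min_unique_peptides: int = 2) -> pd.DataFrame:
    """Drop proteins identified by fewer than ``min_unique_peptides`` distinct
    peptide sequences with nonzero intensity in at least one measurement.

    Idempotent; row order preserved.
    """
    nz = table[table["intensity"] > 0]
    counts = nz.groupby("protein")["peptide"].nunique()
    keep = set(counts[counts >= min_unique_peptides].index)
    return table[table["protein"].isin(keep)].reset_index(drop=True)


def top_n_abundance(table: pd.DataFrame, top_n: int = 3, statistic: str = "mean") -> pd.DataFrame:
    """Per-replicate protein abundance: aggregate of the ``top_n`` most
    intense nonzero peptides for each (protein, sample, replicate).

    Fewer than ``top_n`` nonzero peptides -> aggregate of what is available;
    none -> 0.  Columns are labeled ``sample|replicate``.
    """
    cells = table[["sample", "replicate"]].drop_duplicates()
    columns = [replicate_column(s, r) for s, r in zip(cells["sample"], cells["replicate"])]
    proteins = table["protein"].unique()

    nz = table[table["intensity"] > 0]
    if nz.empty:
        out = pd.DataFrame(0.0, index=pd.Index(proteins, name="protein"), columns=columns)
        return out
    # stable sort keeps deterministic top-N under ties
    nz = nz.sort_values("intensity", ascending=False, kind="mergesort")
    top = nz.groupby(["protein", "sample", "replicate"], sort=False).head(top_n)
    agg = getattr(
        top.groupby(["protein", "sample", "replicate"], sort=False)["intensity"], statistic
    )()
    wide = agg.unstack(["sample", "replicate"], fill_value=0.0)
    wide.columns = [replicate_column(s, r) for s, r in wide.columns]
    wide = wide.reindex(index=proteins, columns=columns, fill_value=0.0).fillna(0.0)
    wide.index.name = "protein"
    return wide


def normalize_summed_intensity(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each column so its total equals the mean of the original column
    totals; all-zero columns are left as zero (with a warning)."""
    totals = matrix.sum(axis=0)
    if (totals == 0).all():
        raise ValidationError("cannot normalize: every column sums to zero")
    if (totals == 0).any():
        zero_cols = list(totals.index[totals == 0])
        warnings.warn(f"columns with zero total left unscaled: {zero_cols}")
    target = totals.mean()
    factors = np.where(totals > 0, target / totals.replace(0, np.nan), 1.0)
    return matrix * factors


def average_replicates(matrix: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Collapse ``sample|replicate`` columns to one column per biological
    sample by arithmetic mean (zeros participate: a zero is a measurement of
    non-detection)."""
    by_sample: dict[str, list[str]] = {}
    for col in matrix.columns:
        sample, _ = split_replicate_column(col)
        by_sample.setdefault(sample, []).append(col)
    ordered = list(dict.fromkeys(metadata["sample"]))
    missing = [s for s in ordered if s not in by_sample]
    if missing:
        raise ValidationError(f"samples with no replicate columns: {missing}")
    out = pd.DataFrame(
        {s: matrix[cols].mean(axis=1) for s, cols in ((s, by_sample[s]) for s in ordered)}
    )
    out.index.name = "protein"
    return out


def protein_cv(matrix: pd.DataFrame, metadata: pd.DataFrame, inverse: bool = False) -> pd.DataFrame:
    """Per-(protein, group) coefficient of variation over nonzero abundances.

    CV = sample standard deviation / mean of the group's nonzero values;
    cells with fewer than two nonzero values are omitted.  ``inverse=True``
    reports mean/sd instead, for comparison only.
    """
    groups = sample_groups(metadata)
    rows = []
    for group in groups.unique():
        cols = [s for s in matrix.columns if groups.get(s) == group]
        sub = matrix[cols].to_numpy(dtype=float)
        masked = np.where(sub > 0, sub, np.nan)
        n_nz = np.sum(~np.isnan(masked), axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(masked, axis=1)
            sd = np.nanstd(masked, axis=1, ddof=1)
        ok = n_nz >= 2
        cv = sd / mean if not inverse else mean / sd
        for protein, value in zip(matrix.index[ok], cv[ok]):
            rows.append({"protein": protein, "group": group, "cv": float(value)})
    return pd.DataFrame(rows, columns=["protein", "group", "cv"])


def quantify_study(
    table: pd.DataFrame, metadata: pd.DataFrame, config: QuantConfig | None = None
) -> pd.DataFrame:
    """Full quantification chain from a peptide table to a replicate-averaged,
    normalized protein x sample abundance matrix."""
    config = config or QuantConfig()
    config.validate()
    filtered = identification_filter(table, config.min_unique_peptides)
    per_rep = top_n_abundance(filtered, config.top_n, config.statistic)
    if config.normalization == "summed_intensity" and per_rep.size:
        per_rep = normalize_summed_intensity(per_rep)
    return average_replicates(per_rep, metadata)
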