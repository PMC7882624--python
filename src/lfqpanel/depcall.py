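"""Per-contrast differential-expression calling.

Every contrast compares the DVD case group against one control group (NC,
T2DM, or VD).  For each protein the zero pattern across the two groups is
classified first:

* majority-nonzero in both groups -> ``testable``: fold change from group
  means (zeros included) and a two-sided pooled-variance t-test on log2 of
  the nonzero values;
* majority-zero in one group but majority-nonzero in the other -> the
  protein belongs to one group only (``case_specific`` / ``control_specific``)
  and its p-value is designated 0;
* majority-zero in both -> ``untestable``, no call.

"Majority" is strict: exactly 50% zeros satisfies neither clause.  A protein
is called up-regulated when (p < 0.05 and FC > 1.20) or case-specific, and
down-regulated when (p < 0.05 and FC < 0.83) or control-specific.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ConfigError, ValidationError
from .io_tables import GROUPS, require_min_group_size, sample_groups

CASE_GROUP = "DVD"
CONTROL_GROUPS = ("NC", "T2DM", "VD")

P_THRESHOLD = 0.05
FC_UP = 1.20
FC_DOWN = 0.83


@dataclass(frozen=True)
class ContrastSpec:
    case_group: str = CASE_GROUP
    control_group: str = "NC"

    def __post_init__(self):
        if self.case_group == self.control_group:
            raise ConfigError("case and control groups must differ")
        for g in (self.case_group, self.control_group):
            if g not in GROUPS:
                raise ConfigError(f"unknown group {g!r}")

    @property
    def name(self) -> str:
        return f"{self.case_group}_vs_{self.control_group}"


#: The three contrasts of the four-group design.
DEFAULT_CONTRASTS = tuple(ContrastSpec(CASE_GROUP, g) for g in CONTROL_GROUPS)


@dataclass
class ProteinComparison:
    protein: str
    fc: Optional[float]  # case mean / control mean; inf if control mean 0
    log2fc: Optional[float]
    p_value: Optional[float]  # None when untestable
    status: str  # testable | case_specific | control_specific | untestable
    regulation: str  # up | down | none


def zero_pattern_status(case_values, control_values) -> str:
    """Classify the zero pattern of one protein across the two groups."""
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValidationError("both groups must be nonempty")
    case_nz = np.mean(case != 0)
    ctrl_nz = np.mean(control != 0)
    if case_nz > 0.5 and ctrl_nz > 0.5:
        return "testable"
    if case_nz < 0.5 and ctrl_nz > 0.5:
        return "control_specific"
    if case_nz > 0.5 and ctrl_nz < 0.5:
        return "case_specific"
    return "untestable"


def fold_change(case_values, control_values) -> tuple[Optional[float], Optional[float]]:
    """(FC, log2FC) from group means computed over *all* values, zeros
    included.  Control mean 0 with positive case mean -> (inf, inf); both
    means 0 -> (None, None)."""
    case_mean = float(np.mean(np.asarray(case_values, dtype=float)))
    ctrl_mean = float(np.mean(np.asarray(control_values, dtype=float)))
    if ctrl_mean == 0.0:
        if case_mean == 0.0:
            return None, None
        return math.inf, math.inf
    fc = case_mean / ctrl_mean
    log2fc = math.log2(fc) if fc > 0 else -math.inf
    return fc, log2fc


def ttest_log2(case_values, control_values, welch: bool = False) -> Optional[float]:
    """Two-sided two-sample t-test on log2 of the nonzero values.

    Pooled-variance (Student) by default; ``welch=True`` switches to the
    unequal-variance form.  Returns None when either group has fewer than two
    nonzero values.  Degenerate zero-variance cases: p = 1 for equal means,
    p = 0 otherwise.
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    case = np.log2(case[case > 0])
    control = np.log2(control[control > 0])
    if case.size < 2 or control.size < 2:
        return None
    if np.var(case) == 0.0 and np.var(control) == 0.0:
        return 1.0 if case.mean() == control.mean() else 0.0
    res = stats.ttest_ind(case, control, equal_var=not welch)
    return float(res.pvalue)


def compare_protein(
    protein: str,
    case_values,
    control_values,
    p_threshold: float = P_THRESHOLD,
    fc_up: float = FC_UP,
    fc_down: float = FC_DOWN,
    welch: bool = False,
) -> ProteinComparison:
    status = zero_pattern_status(case_values, control_values)
    fc, log2fc = fold_change(case_values, control_values)
    p: Optional[float] = None
    regulation = "none"
    if status == "case_specific":
        p, regulation = 0.0, "up"
    elif status == "control_specific":
        p, regulation = 0.0, "down"
    elif status == "testable":
        p = ttest_log2(case_values, control_values, welch=welch)
        if p is None:
            status = "untestable"  # <2 nonzero values in a group
        elif fc is not None:
            if p < p_threshold and fc > fc_up:
                regulation = "up"
            elif p < p_threshold and fc < fc_down:
                regulation = "down"
    return ProteinComparison(protein, fc, log2fc, p, status, regulation)


def call_deps(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    contrast: ContrastSpec,
    p_threshold: float = P_THRESHOLD,
    fc_up: float = FC_UP,
    fc_down: float = FC_DOWN,
    welch: bool = False,
) -> list[ProteinComparison]:
    """DEP calls for every protein of a replicate-averaged matrix."""
    groups = sample_groups(metadata)
    require_min_group_size(metadata[metadata["group"].isin([contrast.case_group, contrast.control_group])])
    case_cols = [s for s in matrix.columns if groups.get(s) == contrast.case_group]
    ctrl_cols = [s for s in matrix.columns if groups.get(s) == contrast.control_group]
    if not case_cols or not ctrl_cols:
        raise ConfigError(f"contrast {contrast.name}: a group has no samples in the matrix")
    case = matrix[case_cols].to_numpy(dtype=float)
    ctrl = matrix[ctrl_cols].to_numpy(dtype=float)
    return [
        compare_protein(protein, case[i], ctrl[i], p_threshold, fc_up, fc_down, welch)
        for i, protein in enumerate(matrix.index)
    ]


def results_frame(results: Sequence[ProteinComparison]) -> pd.DataFrame:
    """Result collection -> table mirroring the published column layout."""
    return pd.DataFrame(
        [
            {
                "Accession": r.protein,
                "FC": r.fc,
                "Log2FC": r.log2fc,
                "P_value": r.p_value,
                "Regulate": r.regulation,
                "Status": r.status,
            }
            for r in results
        ],
        columns=["Accession", "FC", "Log2FC", "P_value", "Regulate", "Status"],
    )


def dep_set(results: Sequence[ProteinComparison]) -> set[str]:
    return {r.protein for r in results if r.regulation != "none"}


@dataclass
class CommonDeps:
    common: set[str]
    dep_sets: dict[str, set[str]]
    exclusive: dict[str, int]  # per-contrast count of DEPs in no other contrast

    def summary_frame(self) -> pd.DataFrame:
        rows = [{"set": "common", "count": len(self.common)}]
        for name in self.dep_sets:
            rows.append({"set": name, "count": len(self.dep_sets[name])})
            rows.append({"set": f"{name}_exclusive", "count": self.exclusive[name]})
        return pd.DataFrame(rows, columns=["set", "count"])


def common_deps(results_by_contrast: Mapping[str, Sequence[ProteinComparison]]) -> CommonDeps:
    """Intersection of DEP sets across contrasts, plus per-contrast exclusive
    counts for a Venn-style summary."""
    if len(results_by_contrast) < 2:
        raise ValidationError("need results for at least two contrasts")
    sets = {name: dep_set(res) for name, res in results_by_contrast.items()}
    common = set.intersection(*sets.values())
    exclusive = {}
    for name, s in sets.items():
        others = set.union(*(t for n, t in sets.items() if n != name)) if len(sets) > 1 else set()
        exclusive[name] = len(s - others)
    return CommonDeps(common=common, dep_sets=sets, exclusive=exclusive)


def volcano_coordinates(results: Sequence[ProteinComparison]) -> pd.DataFrame:
    """Plot coordinates (log2FC vs -log10 p) for testable proteins with a
    finite p-value; p = 0 sentinel rows (group-specific) are excluded."""
    rows = []
    for r in results:
        if r.status != "testable" or r.p_value is None or r.p_value == 0.0:
            continue
        rows.append(
            {
                "protein": r.protein,
                "log2fc": r.log2fc,
                "neg_log10_p": -math.log10(r.p_value),
                "regulation": r.regulation,
            }
        )
    return pd.DataFrame(rows, columns=["protein", "log2fc", "neg_log10_p", "regulation"])
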