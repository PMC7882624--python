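"""Diagnostic-marker evaluation: ROC curves, AUC with DeLong confidence
intervals and Wilcoxon rank-sum significance, the closest-to-(0,1) squared
Euclidean cutpoint index, sensitivity at fixed specificity, and two-marker
logistic composites.

Scores are evaluated for the DVD case group against the three control groups
pooled (label 1 = case).  The positivity rule is "score >= threshold predicts
case"; a marker whose raw AUC falls below 0.5 is sign-flipped (and flagged)
before evaluation.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._errors import ValidationError
from .io_tables import sample_groups

CASE_GROUP = "DVD"


@dataclass
class LabeledScores:
    """One score per sample plus binary labels (1 = DVD case)."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.scores.shape != self.labels.shape or self.scores.ndim != 1:
            raise ValidationError("scores and labels must be 1-D and of equal length")
        if np.isnan(self.scores).any():
            raise ValidationError("scores must not contain missing values")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValidationError("labels must be 0/1")
        if self.n_cases == 0 or self.n_controls == 0:
            raise ValidationError("need at least one case and one control")

    @property
    def cases(self) -> np.ndarray:
        return self.scores[self.labels == 1]

    @property
    def controls(self) -> np.ndarray:
        return self.scores[self.labels == 0]

    @property
    def n_cases(self) -> int:
        return int(self.labels.sum())

    @property
    def n_controls(self) -> int:
        return int(len(self.labels) - self.labels.sum())


@dataclass
class MarkerEval:
    variable: str
    cutpoint: float
    sensitivity: float
    one_minus_specificity: float
    euclid_index: float
    auc: float
    ci_low: float
    ci_high: float
    wilcoxon_p: float
    sens_at_95spec: float
    flipped: bool = False
    separation: bool = False


@dataclass
class CompositePair:
    marker_a: str
    marker_b: str
    intercept: float
    coef_a: float
    coef_b: float
    scores: np.ndarray
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    separation: bool = False


def roc_points(data: LabeledScores) -> list[tuple[float, float, float]]:
    """ROC curve as (threshold, Se, Sp) triples, one per distinct score plus
    the (+inf, 0, 1) and (-inf, 1, 0) endpoints, ordered by decreasing
    threshold (Se nondecreasing)."""
    thresholds = np.unique(data.scores)[::-1]
    cases, controls = data.cases, data.controls
    points = [(math.inf, 0.0, 1.0)]
    for t in thresholds:
        se = float(np.mean(cases >= t))
        sp = float(np.mean(controls < t))
        points.append((float(t), se, sp))
    points.append((-math.inf, 1.0, 0.0))
    return points


def trapezoid_auc(points: Sequence[tuple[float, float, float]]) -> float:
    """Area under the ROC polygon in (1-Sp, Se) coordinates."""
    fpr = np.array([1.0 - sp for _, _, sp in points])
    tpr = np.array([se for _, se, _ in points])
    order = np.argsort(fpr, kind="mergesort")
    return float(np.trapezoid(tpr[order], fpr[order]))


def _delong_variance(cases: np.ndarray, controls: np.ndarray) -> tuple[float, float]:
    """(auc, var) via DeLong's structural components (midranks)."""
    m, n = len(cases), len(controls)
    combined = np.concatenate([cases, controls])
    tz = stats.rankdata(combined)
    tx = stats.rankdata(cases)
    ty = stats.rankdata(controls)
    v01 = (tz[:m] - tx) / n  # per-case placement values
    v10 = 1.0 - (tz[m:] - ty) / m  # per-control placement values
    auc = float(v01.mean())
    if m < 2 or n < 2:
        return auc, math.nan
    var = np.var(v01, ddof=1) / m + np.var(v10, ddof=1) / n
    return auc, float(var)


def auc(data: LabeledScores, ci_method: str = "delong", alpha: float = 0.05) -> tuple[float, float, float, float]:
    """(AUC, CI low, CI high, Wilcoxon p).

    AUC is the tie-corrected Mann-Whitney statistic U/(n1*n0).  The CI is
    DeLong's by default ("hanley" selects Hanley-McNeil); the p-value comes
    from the two-sided normal-approximation Wilcoxon rank-sum test.  With
    fewer than two observations in a class the CI is NaN.
    """
    cases, controls = data.cases, data.controls
    a, var = _delong_variance(cases, controls)
    m, n = len(cases), len(controls)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    if ci_method == "hanley":
        q1 = a / (2.0 - a)
        q2 = 2.0 * a**2 / (1.0 + a)
        var = (a * (1.0 - a) + (m - 1) * (q1 - a**2) + (n - 1) * (q2 - a**2)) / (m * n)
    elif ci_method != "delong":
        raise ValidationError(f"unknown CI method {ci_method!r}")
    if math.isnan(var):
        lo = hi = math.nan
    else:
        half = z * math.sqrt(max(var, 0.0))
        lo, hi = max(0.0, a - half), min(1.0, a + half)
    p = float(
        stats.mannwhitneyu(
            cases, controls, alternative="two-sided", method="asymptotic", use_continuity=False
        ).pvalue
    )
    return a, lo, hi, p


def euclidean_index(sensitivity: float, one_minus_specificity: float) -> float:
    """Squared Euclidean distance of an ROC point from the perfect corner:
    (1 - Se)^2 + (1 - Sp)^2."""
    return (1.0 - sensitivity) ** 2 + one_minus_specificity**2


def optimal_cutpoint_euclid(
    points: Sequence[tuple[float, float, float]]
) -> tuple[float, float, float, float]:
    """(cutpoint, Se, 1-Sp, index) minimizing the Euclidean index over the
    finite thresholds; ties broken by higher Se, then lower threshold."""
    finite = [(t, se, sp) for t, se, sp in points if math.isfinite(t)]
    if not finite:
        raise ValidationError("ROC curve has no finite thresholds")
    best = min(finite, key=lambda p: (euclidean_index(p[1], 1.0 - p[2]), -p[1], p[0]))
    t, se, sp = best
    return t, se, 1.0 - sp, euclidean_index(se, 1.0 - sp)


def sensitivity_at_specificity(
    points: Sequence[tuple[float, float, float]], spec_floor: float = 0.95
) -> float:
    """Maximum sensitivity among ROC points with specificity >= the floor."""
    eligible = [se for _, se, sp in points if sp >= spec_floor]
    return max(eligible, default=0.0)


def fit_composite(
    a: LabeledScores, b: LabeledScores, name_a: str = "a", name_b: str = "b"
) -> CompositePair:
    """Two-marker composite: z-standardize each marker over all samples, fit a
    maximum-likelihood logistic regression of the label on the pair, and score
    every sample by its fitted probability.

    Perfect separation is flagged; the diverging fit's probabilities are
    clamped away from {0, 1} and reported with a warning.
    """
    if not np.array_equal(a.labels, b.labels):
        raise ValidationError("composite markers must share the same samples/labels")
    mean_a, sd_a = float(a.scores.mean()), float(a.scores.std(ddof=0))
    mean_b, sd_b = float(b.scores.mean()), float(b.scores.std(ddof=0))
    if sd_a == 0 or sd_b == 0:
        raise ValidationError("cannot standardize a constant marker")
    za = (a.scores - mean_a) / sd_a
    zb = (b.scores - mean_b) / sd_b
    X = sm.add_constant(np.column_stack([za, zb]))
    y = a.labels
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0)
        except Exception:  # perfect separation or non-convergence under Newton
            separation = True
            fit = sm.Logit(y, X).fit(method="bfgs", maxiter=500, disp=0)
        if not separation and not fit.mle_retvals.get("converged", True):
            separation = True
    probs = np.clip(np.asarray(fit.predict(X)), 1e-12, 1.0 - 1e-12)
    if separation:
        warnings.warn(
            f"logistic fit for {name_a}+{name_b} did not converge cleanly "
            "(perfect separation?); probabilities clamped"
        )
    params = np.asarray(fit.params, dtype=float)
    return CompositePair(
        marker_a=name_a,
        marker_b=name_b,
        intercept=float(params[0]),
        coef_a=float(params[1]),
        coef_b=float(params[2]),
        scores=probs,
        mean_a=mean_a,
        sd_a=sd_a,
        mean_b=mean_b,
        sd_b=sd_b,
        separation=separation,
    )


def evaluate_scores(
    name: str, data: LabeledScores, spec_floor: float = 0.95, auto_flip: bool = True,
    separation: bool = False,
) -> MarkerEval:
    """Full single-score evaluation; flips the score sign when AUC < 0.5."""
    a0, *_ = auc(data)
    flipped = False
    if auto_flip and a0 < 0.5:
        data = LabeledScores(-data.scores, data.labels)
        flipped = True
    a, lo, hi, p = auc(data)
    points = roc_points(data)
    cut, se, fpr, index = optimal_cutpoint_euclid(points)
    se95 = sensitivity_at_specificity(points, spec_floor)
    return MarkerEval(
        variable=name,
        cutpoint=cut,
        sensitivity=se,
        one_minus_specificity=fpr,
        euclid_index=index,
        auc=a,
        ci_low=lo,
        ci_high=hi,
        wilcoxon_p=p,
        sens_at_95spec=se95,
        flipped=flipped,
        separation=separation,
    )


def marker_scores(matrix: pd.DataFrame, metadata: pd.DataFrame, protein: str) -> LabeledScores:
    """Abundance row of one protein as DVD-vs-pooled-others labeled scores."""
    if protein not in matrix.index:
        raise ValidationError(f"protein {protein!r} not in matrix")
    groups = sample_groups(metadata)
    labels = np.array([1 if groups.get(s) == CASE_GROUP else 0 for s in matrix.columns])
    return LabeledScores(matrix.loc[protein].to_numpy(dtype=float), labels)


def candidate_filter(
    common: set[str],
    results_by_contrast,
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
) -> tuple[list[str], list[str]]:
    """Select candidate markers from the common DEPs.

    Keeps proteins expressed in all groups (zero fraction strictly below 50%
    in every group) whose regulation direction agrees across all contrasts;
    returns (upregulated, downregulated) accession lists in matrix order.
    Proteins with inconsistent direction are excluded.
    """
    groups = sample_groups(metadata)
    direction: dict[str, set[str]] = {}
    for res in results_by_contrast.values():
        for r in res:
            if r.protein in common:
                direction.setdefault(r.protein, set()).add(r.regulation)
    up, down = [], []
    for protein in matrix.index:
        if protein not in common:
            continue
        ok = True
        for group in groups.unique():
            cols = [s for s in matrix.columns if groups.get(s) == group]
            values = matrix.loc[protein, cols].to_numpy(dtype=float)
            if np.mean(values == 0) >= 0.5:
                ok = False
                break
        if not ok:
            continue
        dirs = direction.get(protein, set())
        if dirs == {"up"}:
            up.append(protein)
        elif dirs == {"down"}:
            down.append(protein)
        # mixed direction across contrasts -> excluded
    return up, down


def evaluate_panel(
    candidates: Sequence[str],
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    spec_floor: float = 0.95,
) -> list[MarkerEval]:
    """Evaluate every single candidate and every unordered pair composite.

    Returns k + k*(k-1)/2 rows (k singles first, then pairs named "A+B").
    """
    singles = {p: marker_scores(matrix, metadata, p) for p in candidates}
    rows = [evaluate_scores(p, data, spec_floor) for p, data in singles.items()]
    for pa, pb in itertools.combinations(candidates, 2):
        pair = fit_composite(singles[pa], singles[pb], pa, pb)
        data = LabeledScores(pair.scores, singles[pa].labels)
        rows.append(
            evaluate_scores(f"{pa}+{pb}", data, spec_floor, separation=pair.separation)
        )
    return rows


def panel_frame(rows: Sequence[MarkerEval]) -> pd.DataFrame:
    """Panel report mirroring the published column layout."""
    return pd.DataFrame(
        [
            {
                "Variable": r.variable,
                "Optimal cutpoint": r.cutpoint,
                "Sensitivity": r.sensitivity,
                "1-Specificity": r.one_minus_specificity,
                "Euclidean's index": r.euclid_index,
                "AUC": r.auc,
                "CI.low": r.ci_low,
                "CI.high": r.ci_high,
                "P-value": r.wilcoxon_p,
                "Se@95%Sp": r.sens_at_95spec,
                "Flipped": r.flipped,
                "Separation": r.separation,
            }
            for r in rows
        ],
        columns=[
            "Variable",
            "Optimal cutpoint",
            "Sensitivity",
            "1-Specificity",
            "Euclidean's index",
            "AUC",
            "CI.low",
            "CI.high",
            "P-value",
            "Se@95%Sp",
            "Flipped",
            "Separation",
        ],
    )
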