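import itertools
import math

import numpy as np
import pandas as pd
import pytest

from lfqpanel import ValidationError
from lfqpanel.markers import (
    LabeledScores,
    auc,
    candidate_filter,
    euclidean_index,
    evaluate_panel,
    evaluate_scores,
    fit_composite,
    marker_scores,
    optimal_cutpoint_euclid,
    panel_frame,
    roc_points,
    sensitivity_at_specificity,
    trapezoid_auc,
)
from conftest import make_labeled


def brute_force_auc(cases, controls):
    """Exhaustive concordant-pair oracle: (wins + ties/2) / pairs."""
    wins = ties = 0
    for c in cases:
        for k in controls:
            if c > k:
                wins += 1
            elif c == k:
                ties += 1
    return (wins + 0.5 * ties) / (len(cases) * len(controls))


def scan_cutpoint(data):
    """Exhaustive threshold-scan oracle for the Euclidean cutpoint."""
    best = None
    for t in np.unique(data.scores):
        se = np.mean(data.cases >= t)
        sp = np.mean(data.controls < t)
        e = (1 - se) ** 2 + (1 - sp) ** 2
        key = (e, -se, t)
        if best is None or key < best[0]:
            best = (key, t, se, 1 - sp, e)
    return best[1:]


class TestLabeledScores:
    def test_rejects_mismatched_lengths(self):
        with pytest.raises(ValidationError):
            LabeledScores([1.0, 2.0], [1])

    def test_rejects_single_class(self):
        with pytest.raises(ValidationError):
            LabeledScores([1.0, 2.0], [1, 1])

    def test_rejects_nan(self):
        with pytest.raises(ValidationError):
            LabeledScores([1.0, float("nan")], [1, 0])


class TestRocPoints:
    def test_endpoints_present(self):
        data = LabeledScores([3.0, 1.0, 2.0], [1, 0, 0])
        points = roc_points(data)
        assert points[0][1:] == (0.0, 1.0)
        assert points[-1][1:] == (1.0, 0.0)

    def test_perfect_separation_passes_through_corner(self):
        data = LabeledScores([10.0, 9.0, 1.0, 2.0], [1, 1, 0, 0])
        assert any(se == 1.0 and sp == 1.0 for _, se, sp in roc_points(data))

    def test_sensitivity_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        data = make_labeled(rng)
        points = roc_points(data)
        ses = [se for _, se, _ in points]
        assert all(a <= b for a, b in zip(ses, ses[1:]))

    def test_attainable_values_are_count_fractions(self):
        # 12 cases / 57 controls: Se on a 1/12 grid, 1-Sp on a 1/57 grid
        rng = np.random.default_rng(1)
        data = make_labeled(rng, n_cases=12, n_controls=57)
        for _, se, sp in roc_points(data):
            assert (se * 12) == pytest.approx(round(se * 12), abs=1e-9)
            assert ((1 - sp) * 57) == pytest.approx(round((1 - sp) * 57), abs=1e-9)

    def test_shuffled_labels_auc_near_half(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(0, 1, 400)
        labels = rng.permutation([1] * 80 + [0] * 320)
        a, *_ = auc(LabeledScores(scores, labels))
        assert a == pytest.approx(0.5, abs=0.08)

    def test_all_identical_scores_degenerate(self):
        data = LabeledScores([5.0, 5.0, 5.0], [1, 0, 0])
        coords = {(se, sp) for _, se, sp in roc_points(data)}
        assert coords == {(0.0, 1.0), (1.0, 0.0)}


class TestAuc:
    def test_perfect_marker(self):
        data = LabeledScores([10.0, 9.0, 1.0, 2.0], [1, 1, 0, 0])
        a, lo, hi, p = auc(data)
        assert a == 1.0

    def test_identical_score_sets_give_half(self):
        data = LabeledScores([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], [1, 1, 1, 0, 0, 0])
        a, *_ = auc(data)
        assert a == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(0, 1, 16), 1)  # rounding forces ties
        labels = np.array([1] * 8 + [0] * 8)
        data = LabeledScores(scores, labels)
        a, *_ = auc(data)
        assert a == pytest.approx(brute_force_auc(data.cases, data.controls), abs=1e-12)

    def test_trapezoid_equals_mann_whitney_tie_free(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(0, 1, 40)  # continuous -> tie-free a.s.
        labels = np.array([1] * 15 + [0] * 25)
        data = LabeledScores(scores, labels)
        a, *_ = auc(data)
        assert trapezoid_auc(roc_points(data)) == pytest.approx(a, abs=1e-9)

    def test_sign_reversal_maps_auc(self):
        rng = np.random.default_rng(4)
        data = make_labeled(rng)
        a, *_ = auc(data)
        b, *_ = auc(LabeledScores(-data.scores, data.labels))
        assert b == pytest.approx(1.0 - a, abs=1e-12)

    def test_ci_brackets_auc(self):
        rng = np.random.default_rng(5)
        data = make_labeled(rng)
        a, lo, hi, p = auc(data)
        assert lo <= a <= hi
        assert 0.0 <= p <= 1.0

    def test_hanley_ci_also_brackets(self):
        rng = np.random.default_rng(6)
        data = make_labeled(rng)
        a, lo, hi, _ = auc(data, ci_method="hanley")
        assert lo <= a <= hi

    def test_wilcoxon_p_significant_for_strong_marker(self):
        rng = np.random.default_rng(7)
        data = make_labeled(rng, shift=2.0)
        *_, p = auc(data)
        assert p < 0.001


class TestEuclideanCutpoint:
    def test_printed_single_marker_index(self):
        # Se 0.917 / 1-Sp 0.386 must give index 0.155885
        assert euclidean_index(0.917, 0.386) == pytest.approx(0.155885, abs=1e-9)

    def test_perfect_marker_index_zero(self):
        assert euclidean_index(1.0, 0.0) == 0.0

    def test_cutpoint_matches_exhaustive_scan(self):
        rng = np.random.default_rng(8)
        for seed in range(5):
            data = make_labeled(np.random.default_rng(seed), n_cases=15, n_controls=15)
            cut, se, fpr, e = optimal_cutpoint_euclid(roc_points(data))
            ocut, ose, ofpr, oe = scan_cutpoint(data)
            assert cut == pytest.approx(ocut)
            assert e == pytest.approx(oe)

    def test_tie_break_prefers_higher_sensitivity(self):
        # two thresholds with equal index: (Se=1, Sp=0.8) vs (Se=0.8, Sp=1)
        points = [
            (math.inf, 0.0, 1.0),
            (3.0, 0.8, 1.0),
            (1.0, 1.0, 0.8),
            (-math.inf, 1.0, 0.0),
        ]
        cut, se, fpr, e = optimal_cutpoint_euclid(points)
        assert se == 1.0 and cut == 1.0


class TestSensitivityAtSpecificity:
    def test_perfect_marker(self):
        data = LabeledScores([10.0, 9.0, 1.0, 2.0], [1, 1, 0, 0])
        assert sensitivity_at_specificity(roc_points(data)) == 1.0

    def test_uninformative_curve_gives_zero(self):
        data = LabeledScores([5.0, 5.0, 5.0], [1, 0, 0])
        assert sensitivity_at_specificity(roc_points(data), 0.95) == 0.0

    def test_matches_brute_force(self):
        data = make_labeled(np.random.default_rng(9), n_cases=20, n_controls=40)
        points = roc_points(data)
        expected = max((se for _, se, sp in points if sp >= 0.9), default=0.0)
        assert sensitivity_at_specificity(points, 0.9) == pytest.approx(expected)


class TestComposite:
    def test_duplicate_marker_adds_nothing(self):
        rng = np.random.default_rng(10)
        a = make_labeled(rng, n_cases=20, n_controls=40)
        b = LabeledScores(a.scores.copy(), a.labels.copy())
        pair = fit_composite(a, b)
        composite_auc, *_ = auc(LabeledScores(pair.scores, a.labels))
        single_auc, *_ = auc(a)
        assert composite_auc == pytest.approx(single_auc, abs=1e-9)

    def test_constant_scores_auc_half(self):
        # zero coefficients -> every sample scores the prevalence -> AUC 0.5
        data = LabeledScores(np.full(30, 0.25), np.array([1] * 6 + [0] * 24))
        a, *_ = auc(data)
        assert a == pytest.approx(0.5)

    def test_composite_beats_singles_with_independent_signal(self):
        rng = np.random.default_rng(11)
        n = 500
        labels = np.array([1] * n + [0] * n)
        sa = np.concatenate([rng.normal(1.0, 1, n), rng.normal(0, 1, n)])
        sb = np.concatenate([rng.normal(1.0, 1, n), rng.normal(0, 1, n)])
        a = LabeledScores(sa, labels)
        b = LabeledScores(sb, labels)
        pair = fit_composite(a, b)
        ca, *_ = auc(LabeledScores(pair.scores, labels))
        assert ca > auc(a)[0] and ca > auc(b)[0]

    def test_scores_are_probabilities(self):
        rng = np.random.default_rng(12)
        a = make_labeled(rng)
        b = make_labeled(rng)
        pair = fit_composite(a, b)
        assert ((pair.scores > 0) & (pair.scores < 1)).all()

    def test_perfect_separation_flagged(self):
        labels = np.array([1] * 5 + [0] * 5)
        sa = np.array([10.0, 11, 12, 13, 14, 0, 1, 2, 3, 4])
        sb = sa + 0.1
        with pytest.warns(UserWarning):
            pair = fit_composite(LabeledScores(sa, labels), LabeledScores(sb, labels))
        assert pair.separation
        a, *_ = auc(LabeledScores(pair.scores, labels))
        assert a == 1.0

    def test_mismatched_labels_rejected(self):
        a = LabeledScores([1.0, 2.0], [1, 0])
        b = LabeledScores([1.0, 2.0], [0, 1])
        with pytest.raises(ValidationError):
            fit_composite(a, b)


class TestEvaluatePanel:
    @pytest.mark.parametrize("k,pairs", [(9, 36), (2, 1), (1, 0)])
    def test_row_counts(self, small_matrix, k, pairs):
        matrix, meta, _ = small_matrix
        candidates = list(matrix.index[:k])
        rows = evaluate_panel(candidates, matrix, meta)
        assert len(rows) == k + pairs

    def test_panel_frame_columns(self, small_matrix):
        matrix, meta, _ = small_matrix
        frame = panel_frame(evaluate_panel(list(matrix.index[:2]), matrix, meta))
        assert frame.columns[0] == "Variable"
        assert "Euclidean's index" in frame.columns

    def test_euclid_index_consistent_with_reported_se_sp(self, small_matrix):
        matrix, meta, _ = small_matrix
        for r in evaluate_panel(list(matrix.index[:3]), matrix, meta):
            assert r.euclid_index == pytest.approx(
                (1 - r.sensitivity) ** 2 + r.one_minus_specificity**2
            )
            assert r.ci_low <= r.auc <= r.ci_high


class TestCandidateFilter:
    def test_majority_zero_group_excluded(self, small_matrix):
        from lfqpanel.depcall import DEFAULT_CONTRASTS, call_deps, common_deps
        from lfqpanel.io_tables import sample_groups

        matrix, meta, _ = small_matrix
        results = {c.name: call_deps(matrix, meta, c) for c in DEFAULT_CONTRASTS}
        cd = common_deps(results)
        up, down = candidate_filter(cd.common, results, matrix, meta)
        groups = sample_groups(meta)
        for protein in up + down:
            for g in ("NC", "T2DM", "VD", "DVD"):
                cols = [s for s in matrix.columns if groups[s] == g]
                frac0 = np.mean(matrix.loc[protein, cols].to_numpy() == 0)
                assert frac0 < 0.5

    def test_planted_markers_among_upregulated(self, small_matrix):
        from lfqpanel.depcall import DEFAULT_CONTRASTS, call_deps, common_deps

        matrix, meta, truth = small_matrix
        results = {c.name: call_deps(matrix, meta, c) for c in DEFAULT_CONTRASTS}
        cd = common_deps(results)
        up, _ = candidate_filter(cd.common, results, matrix, meta)
        recovered = sum(1 for p in truth.marker_proteins if p in up)
        assert recovered >= 0.6 * len(truth.marker_proteins)

    def test_synthetic_zero_heavy_protein_excluded(self, tiny_metadata):
        # 60% zeros in NC -> excluded even if called up everywhere
        from lfqpanel.depcall import compare_protein

        samples = ["NC1", "NC2", "T2DM1", "T2DM2", "VD1", "VD2", "DVD1", "DVD2"]
        meta = pd.DataFrame({"sample": samples,
                             "group": [s.rstrip("12") for s in samples],
                             "replicate": [1] * 8})
        matrix = pd.DataFrame([[0.0, 0.0, 5, 6, 5, 6, 50, 60]],
                              index=pd.Index(["P1"], name="protein"), columns=samples)
        fake = {"c": [compare_protein("P1", [50, 60], [5, 6])]}
        up, down = candidate_filter({"P1"}, fake, matrix, meta)
        assert up == [] and down == []


def test_marker_scores_labels(small_matrix):
    matrix, meta, _ = small_matrix
    data = marker_scores(matrix, meta, matrix.index[0])
    assert data.n_cases == 12
    assert data.n_controls == 57
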