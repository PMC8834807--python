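"""Reliability, sampling adequacy, PCA and oblimin rotation.

Every numerical routine is checked against an independently coded oracle:
textbook sum formulas for Pearson correlation, the variance formula and the
Spearman-Brown closed form for Cronbach's alpha, regression-residual
partial correlations for KMO, the determinant closed form for Bartlett, and
random-oblique-rotation brute force for the oblimin criterion.
"""

import math

import numpy as np
import pytest

from hevindex.robustness import (
    ItemMatrix,
    SingularMatrixError,
    analyze_block,
    bartlett,
    cronbach_alpha,
    drop_suggestions,
    item_total,
    kmo,
    oblimin_criterion,
    oblimin_rotate,
    pca,
    pearson_matrix,
)
from hevindex.scoring import DomainError


# ---------------------------------------------------------------------------
# Pearson correlations
# ---------------------------------------------------------------------------

def _pearson_sum_formula(x, y):
    """Textbook oracle: r = [n Sxy - Sx Sy] / sqrt([n Sxx - Sx^2][n Syy - Sy^2])."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx, syy, sxy = sum(v * v for v in x), sum(v * v for v in y), sum(
        a * b for a, b in zip(x, y))
    return (n * sxy - sx * sy) / math.sqrt(
        (n * sxx - sx**2) * (n * syy - sy**2))


class TestPearson:
    def test_self_correlation_is_one(self, rng):
        x = rng.normal(size=20)
        corr, _, _ = pearson_matrix(np.column_stack([x, x]))
        assert corr[0, 1] == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=15)
        corr, _, _ = pearson_matrix(np.column_stack([x, 2 * x + 3]))
        assert corr[0, 1] == pytest.approx(1.0)

    def test_hand_matrix_matches_sum_formula_oracle(self):
        data = np.array(
            [[1.0, 2.0, 0.5], [2.0, 1.5, 1.0], [3.0, 3.5, 0.0], [4.0, 2.5, 2.0]]
        )
        corr, labels, dropped = pearson_matrix(data)
        for i in range(3):
            for j in range(i + 1, 3):
                expected = _pearson_sum_formula(data[:, i], data[:, j])
                assert corr[i, j] == pytest.approx(expected, abs=1e-12)
        assert np.allclose(corr, corr.T) and np.allclose(np.diag(corr), 1.0)
        assert not dropped

    def test_too_few_rows_rejected(self):
        with pytest.raises(DomainError):
            pearson_matrix(np.ones((2, 3)))

    def test_constant_column_dropped_with_label(self, rng):
        data = np.column_stack([rng.normal(size=10), np.full(10, 3.0),
                                rng.normal(size=10)])
        m = ItemMatrix(data, ("a", "flat", "b"))
        corr, labels, dropped = pearson_matrix(m)
        assert dropped == ("flat",) and labels == ("a", "b")
        assert corr.shape == (2, 2)


# ---------------------------------------------------------------------------
# Cronbach's alpha and item-total
# ---------------------------------------------------------------------------

def _alpha_variance_formula(data):
    """Oracle: k/(k-1) * (1 - sum s_i^2 / s_total^2), coded independently."""
    k = data.shape[1]
    item_vars = [np.var(data[:, i], ddof=1) for i in range(k)]
    total_var = np.var(data.sum(axis=1), ddof=1)
    return k / (k - 1) * (1 - sum(item_vars) / total_var)


class TestCronbach:
    def test_identical_items_give_one(self, rng):
        x = rng.normal(size=30)
        assert cronbach_alpha(np.column_stack([x, x, x])) == pytest.approx(1.0)

    def test_orthogonal_equal_variance_items_give_zero(self):
        x = np.array([1.0, 0.0, -1.0, 0.0])
        y = np.array([0.0, 1.0, 0.0, -1.0])
        assert cronbach_alpha(np.column_stack([x, y])) == pytest.approx(0.0)

    def test_hand_matrix_matches_variance_formula(self):
        data = np.array(
            [[2, 3, 4], [4, 4, 5], [1, 2, 2], [3, 4, 4], [5, 4, 5]], dtype=float
        )
        assert cronbach_alpha(data) == pytest.approx(_alpha_variance_formula(data))

    def test_matches_pingouin_on_random_data(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        data = rng.normal(size=(40, 5)) + rng.normal(size=(40, 1))
        ours = cronbach_alpha(data)
        theirs = pingouin.cronbach_alpha(data=pd.DataFrame(data))[0]
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_spearman_brown_closed_form_on_equicorrelated_data(self):
        """alpha on unit-variance equicorrelated data approaches
        k*r / (1 + (k-1)*r)."""
        rng = np.random.default_rng(2024)
        k, r, n = 5, 0.5, 2000
        cov = np.full((k, k), r) + (1 - r) * np.eye(k)
        data = rng.multivariate_normal(np.zeros(k), cov, size=n)
        expected = k * r / (1 + (k - 1) * r)
        assert cronbach_alpha(data) == pytest.approx(expected, abs=0.02)

    def test_zero_total_variance_rejected(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.raises(DomainError):
            cronbach_alpha(np.column_stack([x, -x]))


class TestItemTotal:
    def test_item_duplicating_rest_sum_correlates_one(self, rng):
        a, b = rng.normal(size=20), rng.normal(size=20)
        data = np.column_stack([a, b, a + b])
        result = item_total(data)
        assert result["item3"]["item_total"] == pytest.approx(1.0)

    def test_noise_item_flagged_and_alpha_improves_without_it(self):
        rng = np.random.default_rng(7)
        n = 1000
        common = rng.normal(size=n)
        related = np.column_stack(
            [0.8 * common + 0.6 * rng.normal(size=n) for _ in range(4)]
        )
        noise = rng.normal(size=n)
        data = np.column_stack([related, noise])
        result = item_total(ItemMatrix(data, ("a", "b", "c", "d", "noise")))
        assert abs(result["noise"]["item_total"]) < 0.1
        assert result["noise"]["flagged"]
        assert result["noise"]["alpha_if_deleted"] > result["noise"]["overall_alpha"]

    def test_needs_three_items(self):
        with pytest.raises(DomainError):
            item_total(np.ones((5, 2)))


# ---------------------------------------------------------------------------
# KMO and Bartlett
# ---------------------------------------------------------------------------

def _partial_corr_regression_oracle(data, i, j):
    """Partial correlation of columns i, j controlling the rest, by
    regressing each on the remaining columns and correlating residuals."""
    rest = [c for c in range(data.shape[1]) if c not in (i, j)]
    X = np.column_stack([np.ones(len(data)), data[:, rest]])
    ri = data[:, i] - X @ np.linalg.lstsq(X, data[:, i], rcond=None)[0]
    rj = data[:, j] - X @ np.linalg.lstsq(X, data[:, j], rcond=None)[0]
    return float(np.corrcoef(ri, rj)[0, 1])


class TestKMO:
    def test_two_variables_force_half(self, rng):
        x = rng.normal(size=50)
        y = 0.6 * x + 0.8 * rng.normal(size=50)
        corr, _, _ = pearson_matrix(np.column_stack([x, y]))
        overall, per_var = kmo(corr)
        # with p=2 the partial correlation equals the correlation
        assert overall == pytest.approx(0.5)
        assert per_var == pytest.approx([0.5, 0.5])

    def test_three_variable_matrix_matches_regression_oracle(self, rng):
        data = rng.normal(size=(200, 3)) + 0.8 * rng.normal(size=(200, 1))
        corr, _, _ = pearson_matrix(data)
        overall, _ = kmo(corr)
        r2 = a2 = 0.0
        for i in range(3):
            for j in range(3):
                if i != j:
                    r2 += corr[i, j] ** 2
                    a2 += _partial_corr_regression_oracle(data, i, j) ** 2
        assert overall == pytest.approx(r2 / (r2 + a2), abs=1e-6)

    def test_near_identity_matrix_keeps_half_structure(self):
        eps = 1e-6
        corr = np.eye(3)
        corr[0, 1] = corr[1, 0] = eps
        corr[0, 2] = corr[2, 0] = eps
        corr[1, 2] = corr[2, 1] = eps
        overall, per_var = kmo(corr)
        assert overall == pytest.approx(0.5, abs=1e-3)
        assert np.allclose(per_var, per_var[0])

    def test_singular_matrix_advises_removal(self):
        corr = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(SingularMatrixError, match="remove"):
            kmo(corr)


class TestBartlett:
    def test_identity_matrix_gives_zero_chi2(self):
        chi2, df, p = bartlett(np.eye(4), n=30)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_df_for_17_variables(self):
        chi2, df, p = bartlett(np.eye(17) * 1.0, n=25)
        assert df == 136  # p(p-1)/2

    def test_closed_form_two_variables(self):
        corr = np.array([[1.0, 0.5], [0.5, 1.0]])
        chi2, df, p = bartlett(corr, n=25)
        # -(25 - 1 - (2*2+5)/6) * ln(1 - 0.25) evaluated by hand
        assert chi2 == pytest.approx(-(25 - 1 - 9 / 6) * math.log(0.75))
        assert df == 1

    def test_sample_too_small_rejected(self):
        with pytest.raises(DomainError):
            bartlett(np.eye(5), n=5)

    def test_agrees_with_determinant_oracle_on_random_pd_matrices(self):
        rng = np.random.default_rng(11)
        for p in (4, 5, 6):
            A = rng.normal(size=(50, p))
            corr, _, _ = pearson_matrix(A)
            chi2, df, pval = bartlett(corr, n=50)
            expected = -(50 - 1 - (2 * p + 5) / 6) * math.log(np.linalg.det(corr))
            assert chi2 == pytest.approx(expected, rel=1e-9)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

class TestPCA:
    def test_two_variable_eigenvalues_closed_form(self, rng):
        x = rng.normal(size=500)
        y = 0.6 * x + 0.8 * rng.normal(size=500)
        corr, _, _ = pearson_matrix(np.column_stack([x, y]))
        r = corr[0, 1]
        res = pca(np.column_stack([x, y]))
        assert res.eigenvalues == pytest.approx([1 + r, 1 - r])

    def test_eigenvalues_sum_to_variable_count(self, rng):
        data = rng.normal(size=(60, 8)) + rng.normal(size=(60, 1))
        res = pca(data)
        assert res.eigenvalues.sum() == pytest.approx(8.0, abs=1e-8)
        assert res.cumulative[-1] == pytest.approx(100.0, abs=1e-8)
        assert np.all(np.diff(res.cumulative) >= -1e-12)

    def test_eigenvalue_rule_keeps_components_above_one(self, rng):
        # two clear factors -> exactly two eigenvalues above 1
        n = 400
        f1, f2 = rng.normal(size=n), rng.normal(size=n)
        data = np.column_stack(
            [0.9 * f1 + 0.4 * rng.normal(size=n) for _ in range(3)]
            + [0.9 * f2 + 0.4 * rng.normal(size=n) for _ in range(3)]
        )
        res = pca(data, rule="eigenvalue")
        assert res.n_components == int(np.sum(res.eigenvalues > 1.0)) == 2

    def test_variance_rule(self, rng):
        data = rng.normal(size=(60, 6))
        res = pca(data, rule="variance", variance_threshold=0.75)
        assert res.cumulative[res.n_components - 1] >= 75.0
        if res.n_components > 1:
            assert res.cumulative[res.n_components - 2] < 75.0

    def test_full_retention_gives_unit_communalities(self, rng):
        data = rng.normal(size=(50, 4))
        res = pca(data, n_components=4)
        assert res.communalities == pytest.approx(np.ones(4), abs=1e-8)

    def test_loadings_reproduce_correlation_matrix(self, rng):
        data = rng.normal(size=(80, 5)) + rng.normal(size=(80, 1))
        corr, _, _ = pearson_matrix(data)
        res = pca(data)
        assert np.allclose(res.loadings @ res.loadings.T, corr, atol=1e-8)


# ---------------------------------------------------------------------------
# oblimin rotation
# ---------------------------------------------------------------------------

def _random_oblique_rotations(A, n, rng):
    """Brute-force oracle: criterion of n random oblique rotations of A."""
    best = np.inf
    k = A.shape[1]
    for _ in range(n):
        X = rng.normal(size=(k, k))
        T = X / np.sqrt((X**2).sum(axis=0))
        try:
            L = A @ np.linalg.inv(T).T
        except np.linalg.LinAlgError:
            continue
        best = min(best, oblimin_criterion(L))
    return best


TOY_LOADINGS = np.array(
    [[0.8, 0.1], [0.7, 0.2], [0.6, 0.0], [0.1, 0.8], [0.2, 0.7], [0.0, 0.6]]
)


class TestOblimin:
    def test_structure_equals_pattern_times_phi(self, rng):
        Q, _ = np.linalg.qr(rng.normal(size=(2, 2)))
        pattern, structure, phi = oblimin_rotate(TOY_LOADINGS @ Q)
        assert np.allclose(structure, pattern @ phi, atol=1e-8)
        assert np.allclose(np.diag(phi), 1.0, atol=1e-8)

    def test_communalities_preserved(self, rng):
        Q, _ = np.linalg.qr(rng.normal(size=(2, 2)))
        A = TOY_LOADINGS @ Q
        pattern, structure, phi = oblimin_rotate(A)
        before = (A**2).sum(axis=1)
        after = np.diag(pattern @ phi @ pattern.T)
        assert np.allclose(before, after, atol=1e-6)

    def test_criterion_beats_random_rotations(self, rng):
        Q, _ = np.linalg.qr(rng.normal(size=(2, 2)))
        A = TOY_LOADINGS @ Q
        pattern, _, _ = oblimin_rotate(A, kaiser=False)
        ours = oblimin_criterion(pattern)
        best_random = _random_oblique_rotations(A, 200, rng)
        assert ours <= best_random + 1e-10

    def test_orthogonal_factors_yield_near_diagonal_phi(self):
        rng = np.random.default_rng(3)
        n = 1000
        f1, f2 = rng.normal(size=n), rng.normal(size=n)
        data = np.column_stack(
            [0.8 * f1 + 0.6 * rng.normal(size=n) for _ in range(3)]
            + [0.8 * f2 + 0.6 * rng.normal(size=n) for _ in range(3)]
        )
        res = pca(data)
        assert res.n_components == 2
        _, _, phi = oblimin_rotate(res.loadings[:, :2])
        assert abs(phi[0, 1]) < 0.1

    def test_sign_convention_is_reproducible(self, rng):
        Q, _ = np.linalg.qr(rng.normal(size=(2, 2)))
        A = TOY_LOADINGS @ Q
        p1, _, _ = oblimin_rotate(A, seed=0)
        p2, _, _ = oblimin_rotate(A, seed=0)
        assert np.array_equal(p1, p2)
        for j in range(p1.shape[1]):
            assert p1[np.argmax(np.abs(p1[:, j])), j] > 0

    def test_single_component_rejected(self):
        with pytest.raises(DomainError):
            oblimin_rotate(TOY_LOADINGS[:, :1])


class TestDropSuggestions:
    def test_strong_loading_not_dropped(self):
        pattern = np.array([[0.9, 0.0], [0.1, -0.2], [0.5, 0.1]])
        drops = drop_suggestions(pattern, ("a", "b", "c"))
        assert drops == ["b"]

    def test_threshold_zero_drops_nothing(self):
        pattern = np.array([[0.01, 0.0], [0.0, 0.0]])
        assert drop_suggestions(pattern, threshold=0.0) == []

    def test_custom_component_set(self):
        pattern = np.array([[0.1, 0.9], [0.1, 0.1]])
        assert drop_suggestions(pattern, pcs=[0]) == ["item1", "item2"]


# ---------------------------------------------------------------------------
# full block report
# ---------------------------------------------------------------------------

class TestAnalyzeBlock:
    def test_synthetic_vulnerability_block_report(self, survey42, scenario_pair):
        from hevindex.robustness import indicator_item_matrix

        dataset, _ = survey42
        trend, _ = scenario_pair
        matrix = indicator_item_matrix(dataset, trend, component=None)
        report = analyze_block(matrix, seed=0)
        assert report.n == 25 and len(report.items) == 17
        assert report.eigenvalues.sum() == pytest.approx(17.0, abs=1e-8)
        assert any("small sample" in w for w in report.warnings)
        assert report.bartlett_df == 136
        assert report.structure == pytest.approx(
            report.pattern @ report.component_correlations, abs=1e-8)
        # indicators correlate positively with the equal-weight pillar score
        # for the dominant (adaptive) block
        for vid in ("V12", "V13", "V14"):
            assert report.indicator_pillar_correlations[vid] > 0
        # serializable
        import json

        json.dumps(report.as_dict())

    def test_block_alpha_contrast(self, survey42, scenario_pair):
        """Homogeneous policy-checklist (adaptive) block is far more
        internally consistent than the heterogeneous sensitivity block."""
        from hevindex.robustness import indicator_item_matrix

        dataset, _ = survey42
        trend, _ = scenario_pair
        a_adaptive = cronbach_alpha(
            indicator_item_matrix(dataset, trend, component="adaptive"))
        a_sensitivity = cronbach_alpha(
            indicator_item_matrix(dataset, trend, component="sensitivity"))
        assert a_adaptive > 0.7 > a_sensitivity
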