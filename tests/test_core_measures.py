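"""Unit tests for standardization, the SVD spectrum and the severity measures."""

import numpy as np
import pytest

from ubva.data import DataMatrix, standardize
from ubva.measures import (expected_scaled_severity, global_summary,
                           left_severity, mp_support, right_severity,
                           severity_bounds, svd_spectrum, vif)

from conftest import make_correlated_pair


class TestStandardize:
    def test_collinear_columns_become_identical(self):
        X = np.column_stack([[1, 2, 3, 4], [2, 4, 6, 8]])
        dm = standardize(X, "columns")
        np.testing.assert_allclose(dm.values[:, 0], dm.values[:, 1], atol=1e-12)
        np.testing.assert_allclose(dm.values.mean(0), 0, atol=1e-12)
        np.testing.assert_allclose(dm.values.var(0, ddof=1), 1, atol=1e-12)

    def test_idempotent(self, rng):
        dm = standardize(rng.standard_normal((10, 4)), "columns")
        again = standardize(dm.values, "columns")
        np.testing.assert_allclose(again.values, dm.values, atol=1e-12)

    def test_seeded_draw_moments(self):
        X = np.random.default_rng(7).standard_normal((5, 3))
        dm = standardize(X, "columns")
        # independent mean/variance computation
        for j in range(3):
            col = dm.values[:, j]
            assert abs(sum(col) / 5) < 1e-12
            assert abs(sum((c - sum(col) / 5) ** 2 for c in col) / 4 - 1) < 1e-12

    def test_constant_column_named_in_error(self):
        X = np.column_stack([[1, 2, 3, 4], [5, 5, 5, 5]])
        with pytest.raises(ValueError, match="constant column.*(vB|1)"):
            standardize(X, "columns", variable_names=["vA", "vB"])

    def test_missing_values_rejected(self):
        X = np.ones((4, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            standardize(X, "columns")

    def test_row_mode(self, rng):
        dm = standardize(rng.standard_normal((4, 10)), "rows")
        assert dm.df == 9
        np.testing.assert_allclose(dm.values.mean(1), 0, atol=1e-12)
        np.testing.assert_allclose(dm.values.var(1, ddof=1), 1, atol=1e-10)


class TestSpectrum:
    def test_identical_columns_rank_one(self, rng):
        x = rng.standard_normal(5)
        dm = standardize(np.column_stack([x, 2 * x + 1]), "columns")
        spec = svd_spectrum(dm)
        assert spec.singular_values[0] ** 2 == pytest.approx(8.0, rel=1e-10)
        assert spec.singular_values[1] == pytest.approx(0.0, abs=1e-10)
        assert spec.rank == 1

    def test_sum_of_squares_conservation(self, rng):
        n, p = 60, 100
        dm = standardize(rng.standard_normal((n, p)), "columns")
        spec = svd_spectrum(dm)
        assert spec.singular_values.size == n - 1
        assert (spec.singular_values ** 2).sum() == pytest.approx(
            (n - 1) * p, rel=1e-8)

    def test_orthonormal_vectors(self, rng):
        dm = standardize(rng.standard_normal((6, 4)), "columns")
        spec = svd_spectrum(dm)
        for M in (spec.left_vectors, spec.right_vectors):
            np.testing.assert_allclose(M.T @ M, np.eye(M.shape[1]), atol=1e-10)

    def test_nonfinite_rejected(self):
        dm = standardize(np.random.default_rng(0).standard_normal((5, 3)))
        dm.values[0, 0] = np.inf
        with pytest.raises(ValueError):
            svd_spectrum(dm)


class TestRightSeverity:
    @pytest.mark.parametrize("r", [0.0, 0.3, -0.7, 0.95])
    def test_two_column_closed_form(self, r):
        X = make_correlated_pair(12, r)
        prof = right_severity(svd_spectrum(standardize(X, "columns")))
        np.testing.assert_allclose(prof.scaled, [1 + r ** 2] * 2, atol=1e-10)

    def test_duplicate_plus_orthogonal_triplet(self):
        # x1, x2 = x1, x3 exactly orthogonal to x1 -> sR = (2, 2, 1)
        x1 = np.array([1.0, -1.0, 1.0, -1.0, 0.0])
        x3 = np.array([1.0, 1.0, 0.0, 0.0, -2.0])
        assert x1 @ x3 == 0 and x1.sum() == 0 and x3.sum() == 0
        dm = standardize(np.column_stack([x1, x1, x3]), "columns")
        prof = right_severity(svd_spectrum(dm))
        np.testing.assert_allclose(prof.scaled, [2, 2, 1], atol=1e-10)

    def test_scaled_is_raw_over_df_squared(self, small_standardized):
        prof = right_severity(svd_spectrum(small_standardized))
        np.testing.assert_allclose(prof.scaled, prof.raw / 29 ** 2, rtol=0)

    def test_scaled_at_least_one(self, rng):
        dm = standardize(rng.standard_normal((20, 50)), "columns")
        prof = right_severity(svd_spectrum(dm))
        assert (prof.scaled >= 1 - 1e-8).all()


class TestLeftSeverity:
    def test_symmetric_matrix_left_equals_right(self, rng):
        A = rng.standard_normal((8, 8))
        S = A + A.T
        S = S - S.mean(0, keepdims=True) - S.mean(1, keepdims=True) + S.mean()
        S = (S + S.T) / 2                      # doubly centered, symmetric
        dm = DataMatrix(S)                     # unstandardized on purpose
        spec = svd_spectrum(dm)
        np.testing.assert_allclose(left_severity(spec).raw,
                                   right_severity(spec).raw, rtol=1e-8)

    def test_sum_matches_right_sum(self, small_standardized):
        spec = svd_spectrum(small_standardized)
        assert left_severity(spec).raw.sum() == pytest.approx(
            right_severity(spec).raw.sum(), rel=1e-8)

    def test_advisory_flag_under_column_standardization(self, small_standardized):
        spec = svd_spectrum(small_standardized)
        assert left_severity(spec).advisory
        assert not left_severity(spec, row_standardized=True).advisory


class TestBounds:
    def test_data_rich_lower_bound_is_one(self, rng):
        dm = standardize(rng.standard_normal((100, 5)), "columns")
        b = severity_bounds(svd_spectrum(dm))
        np.testing.assert_allclose(b[:, 0], 1.0, atol=1e-8)

    def test_identical_columns_upper_bound_attained(self, rng):
        x = rng.standard_normal(6)
        dm = standardize(np.tile(x[:, None], (1, 4)), "columns")
        spec = svd_spectrum(dm)
        b = severity_bounds(spec)
        np.testing.assert_allclose(b[:, 1], 4.0, atol=1e-8)
        np.testing.assert_allclose(right_severity(spec).scaled, 4.0, atol=1e-8)

    def test_bounds_contain_observed_high_dimensional(self, rng):
        dm = standardize(rng.standard_normal((100, 300)), "columns")
        spec = svd_spectrum(dm)
        s = right_severity(spec).scaled
        b = severity_bounds(spec)
        assert (s >= b[:, 0] - 1e-8).all()
        assert (s <= b[:, 1] + 1e-8).all()
        # under n < p the lower bounds exceed 1
        assert (b[:, 0] > 1).all()


class TestExpectedSeverity:
    def test_identity(self):
        E = expected_scaled_severity(np.eye(20), n=101)
        np.testing.assert_allclose(E, (20 + 101) / 100, rtol=1e-12)

    def test_compound_symmetric_symbolic(self):
        p, rho, n = 6, 0.4, 50
        Sigma = rho * np.ones((p, p)) + (1 - rho) * np.eye(p)
        E = expected_scaled_severity(Sigma, n)
        expected = p / (n - 1) + n * (1 + (p - 1) * rho ** 2) / (n - 1)
        np.testing.assert_allclose(E, expected, rtol=1e-12)

    def test_non_unit_diagonal_rejected(self):
        with pytest.raises(ValueError, match="unit diagonal"):
            expected_scaled_severity(2 * np.eye(3), n=10)

    def test_warns_when_n_below_p(self):
        with pytest.warns(RuntimeWarning, match="underestimat"):
            expected_scaled_severity(np.eye(10), n=5)

    def test_monte_carlo_agreement(self):
        # small-scale simulation oracle for the expectation formula
        from ubva.simulate import sample_gaussian
        n, p, rho, reps = 200, 10, 0.3, 200
        Sigma = rho * np.ones((p, p)) + (1 - rho) * np.eye(p)
        means = []
        for s in range(reps):
            X = standardize(sample_gaussian(Sigma, n, seed=1000 + s))
            means.append(right_severity(svd_spectrum(X)).scaled.mean())
        means = np.asarray(means)
        mc_se = means.std(ddof=1) / np.sqrt(reps)
        expected = expected_scaled_severity(Sigma, n).mean()
        assert abs(means.mean() - expected) < 3 * mc_se + 1e-12


class TestGlobalSummary:
    def test_identical_columns_everything_one(self, rng):
        x = rng.standard_normal(50)
        dm = standardize(np.tile(x[:, None], (1, 10)), "columns")
        spec = svd_spectrum(dm)
        g = global_summary(right_severity(spec), spec)
        assert g.BsRs == pytest.approx(1.0, abs=1e-10)
        assert g.LsRs == pytest.approx(1.0, abs=1e-10)
        assert g.sRs == pytest.approx(1.0, abs=1e-10)
        assert g.red == pytest.approx(1.0, abs=1e-10)
        assert np.isinf(g.condition_number)

    def test_orthogonal_columns_everything_zero(self):
        # Helmert contrast columns: mutually orthogonal, each sums to zero,
        # so orthogonality survives standardization exactly
        n, p = 20, 5
        B = np.zeros((n, p))
        for j in range(p):
            B[: j + 1, j] = 1.0
            B[j + 1, j] = -(j + 1.0)
        dm = standardize(B, "columns")
        G = dm.values.T @ dm.values
        assert np.abs(G - np.diag(np.diag(G))).max() < 1e-10
        spec = svd_spectrum(dm)
        g = global_summary(right_severity(spec), spec)
        assert g.sRs == pytest.approx(0.0, abs=1e-10)
        assert g.red == pytest.approx(0.0, abs=1e-10)
        v = vif(dm)
        np.testing.assert_allclose(v.vif, 1.0, atol=1e-8)

    def test_red_matches_trace_route(self, rng):
        n, p = 200, 20
        dm = standardize(rng.standard_normal((n, p)), "columns")
        spec = svd_spectrum(dm)
        g = global_summary(right_severity(spec), spec)
        M = dm.values.T @ dm.values
        red_direct = np.sqrt((np.trace(M @ M) - (n - 1) ** 2 * p)
                             / (p * (p - 1) * (n - 1) ** 2))
        assert g.red == pytest.approx(red_direct, rel=1e-10)

    def test_composition_identity(self, small_standardized):
        spec = svd_spectrum(small_standardized)
        g = global_summary(right_severity(spec), spec)
        w = (g.w1 + g.w2) / 2
        assert g.sRs == pytest.approx(g.BsRs * w + g.LsRs * (1 - w), abs=1e-14)
        assert g.BsRs == pytest.approx(g.red ** 2, rel=1e-10)
        for val in (g.sRs, g.BsRs, g.LsRs, g.w1, g.w2):
            assert 0.0 <= val <= 1.0

    def test_effective_df_flag(self, rng):
        n, p = 200, 10
        dm = standardize(rng.standard_normal((n, p)), "columns")
        spec = svd_spectrum(dm)
        g = global_summary(right_severity(spec), spec)
        assert g.effective_df_sum == pytest.approx(
            np.sum(1 / right_severity(spec).scaled), rel=1e-12)
        # near-independent data rich: sum 1/sR ~ p/(1+p/n) << 0.3 n
        assert not g.effective_df_flag


class TestVif:
    def test_invalid_when_n_le_p(self, rng):
        dm = standardize(rng.standard_normal((10, 20)), "columns")
        assert not vif(dm).valid

    @pytest.mark.parametrize("r", [0.2, 0.9])
    def test_pair_closed_form(self, r):
        X = make_correlated_pair(30, r)
        v = vif(standardize(X, "columns"))
        np.testing.assert_allclose(v.vif, 1 / (1 - r ** 2), rtol=1e-10)

    def test_collinear_pair_exceeds_detection_threshold(self):
        from ubva.simulate import run_scenario
        res = run_scenario("collinear_pair", n=500, p=50, seed=11)
        assert res.vif is not None
        above = np.nonzero(res.vif > 5)[0]
        assert set(above) == {0, 1}


class TestMpSupport:
    def test_identity_case_anchors(self):
        sup = mp_support(500, 1000)
        assert round(sup["sR"][0], 2) == 2.00
        assert round(sup["sR"][1], 2) == 5.83
        assert round(sup["sL"][1], 2) == 2.91
        assert sup["sL"][0] == 1.0
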