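"""Cognition ranking, pairwise lag-1 fits, driving scores, permutation tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from qtmflow.pseudotime_gca import (
    PseudoTimeSeries,
    build_pseudotime,
    driving_scores,
    fit_pairwise_gca,
    gca_matrix,
    permutation_significance,
    rank_subjects,
)


def cohort_frame(mmse, recall, ids=None):
    ids = ids or [f"S{k}" for k in range(len(mmse))]
    return pd.DataFrame(
        {"subject_id": ids, "mmse": mmse, "ravlt_immediate": recall}
    )


def null_series(n, r, seed):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, r))
    X = (X - X.mean(0)) / X.std(0)
    return PseudoTimeSeries([f"S{k:03d}" for k in range(n)], X, [f"R{k}" for k in range(r)])


class TestRanking:
    def test_recall_breaks_mmse_ties(self):
        df = cohort_frame([30, 28, 28], [2, 7, 3], ids=["s1", "s2", "s3"])
        assert rank_subjects(df) == ["s1", "s2", "s3"]

    def test_distinct_mmse_sorts_descending(self):
        df = cohort_frame([25, 30, 27], [1, 1, 1], ids=["a", "b", "c"])
        assert rank_subjects(df) == ["b", "c", "a"]

    def test_full_ties_fall_back_to_id(self):
        df = cohort_frame([28, 28, 28], [5, 5, 5], ids=["z", "a", "m"])
        assert rank_subjects(df) == ["a", "m", "z"]
        assert rank_subjects(df) == rank_subjects(df)

    def test_missing_mmse_rejected(self):
        df = cohort_frame([30, np.nan], [1, 1])
        with pytest.raises(ValueError, match="MMSE"):
            rank_subjects(df)


class TestPairwiseFit:
    def test_exact_lag_dependence(self, rng):
        x = rng.standard_normal(20)
        y = np.zeros(20)
        y[1:] = x[:-1]
        a, b, rv = fit_pairwise_gca(x, y)
        assert abs(a - 1) < 1e-12 and abs(b) < 1e-12 and rv < 1e-24

    def test_constant_series_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            fit_pairwise_gca(rng.standard_normal(10), np.ones(10))

    def test_six_point_toy_matches_normal_equations(self):
        """Printed toy series agree with an independently coded
        normal-equations solution."""
        i = np.array([0.1, 0.5, -0.3, 0.8, -0.2, 0.4])
        j = np.array([0.0, 0.2, 0.6, -0.1, 0.7, -0.3])
        X = np.column_stack([i[:-1], j[:-1]])
        y = j[1:]
        # 2x2 normal equations by explicit inversion
        G = X.T @ X
        beta = np.array(
            [
                [G[1, 1], -G[0, 1]],
                [-G[0, 1], G[0, 0]],
            ]
        ) @ (X.T @ y) / (G[0, 0] * G[1, 1] - G[0, 1] ** 2)
        a, b, _ = fit_pairwise_gca(i, j)
        np.testing.assert_allclose([a, b], beta, rtol=1e-12)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            fit_pairwise_gca(np.arange(3.0), np.arange(3.0) ** 2)


class TestGcaMatrix:
    def test_two_regions_give_two_cross_coefficients(self):
        ps = null_series(30, 2, 0)
        g = gca_matrix(ps)
        assert np.isnan(g.A[0, 0]) and np.isnan(g.A[1, 1])
        assert np.isfinite(g.A[0, 1]) and np.isfinite(g.A[1, 0])

    def test_matrix_matches_pairwise_fits(self, rng):
        X = rng.standard_normal((40, 5))
        X = (X - X.mean(0)) / X.std(0)
        ps = PseudoTimeSeries([f"S{k}" for k in range(40)], X, list("abcde"))
        g = gca_matrix(ps)
        for i in range(5):
            for j in range(5):
                if i == j:
                    continue
                a, b, rv = fit_pairwise_gca(X[:, i], X[:, j])
                np.testing.assert_allclose(g.A[i, j], a, atol=1e-10)
                np.testing.assert_allclose(g.B[i, j], b, atol=1e-10)
                np.testing.assert_allclose(g.resid_var[i, j], rv, atol=1e-10)

    def test_planted_var_coefficient_estimated_unbiased(self):
        """VAR(1) with cross coefficient 0.6: mean estimate over seeds falls
        within +/-0.1 of truth."""
        ests = []
        for s in range(100):
            rng = np.random.default_rng(s)
            n = 150
            x = rng.standard_normal(n)
            y = np.empty(n)
            y[0] = rng.standard_normal()
            for t in range(1, n):
                y[t] = 0.6 * x[t - 1] + np.sqrt(1 - 0.36) * rng.standard_normal()
            X = np.column_stack([x, y])
            X = (X - X.mean(0)) / X.std(0)
            ps = PseudoTimeSeries([f"S{k}" for k in range(n)], X, ["x", "y"])
            ests.append(gca_matrix(ps).A[0, 1])
        assert abs(np.mean(ests) - 0.6) <= 0.1

    def test_duplicated_region_flagged(self, rng):
        x = rng.standard_normal(30)
        X = np.column_stack([x, x, rng.standard_normal(30)])
        ps = PseudoTimeSeries([f"S{k}" for k in range(30)], X, ["a", "b", "c"])
        with pytest.warns(UserWarning, match="degenerate"):
            g = gca_matrix(ps)
        assert g.flagged[0, 1] and g.flagged[1, 0]
        assert np.isnan(g.A[0, 1])


class TestDrivingScores:
    def test_zero_matrix_gives_zero_scores(self):
        ps = null_series(20, 3, 1)
        g = gca_matrix(ps)
        g.A[~np.isnan(g.A)] = 0.0
        t = driving_scores(g).table
        assert (t[["total", "positive", "negative"]] == 0).all().all()

    def test_forced_arithmetic_row(self):
        ps = null_series(20, 4, 2)
        g = gca_matrix(ps)
        g.A[0, 1:] = [0.2, -0.1, 0.3]
        t = driving_scores(g).table.set_index("region")
        assert np.isclose(t.loc["R0", "total"], 0.4)
        assert np.isclose(t.loc["R0", "positive"], 0.5)
        assert np.isclose(t.loc["R0", "negative"], -0.1)

    def test_random_matrix_matches_brute_force(self, rng):
        ps = null_series(40, 6, 3)
        g = gca_matrix(ps)
        t = driving_scores(g).table
        for k, row in t.iterrows():
            pos = neg = 0.0
            for j in range(6):
                if j == k:
                    continue
                v = g.A[k, j]
                if v >= 0:
                    pos += v
                else:
                    neg += v
            assert row["positive"] == pos and row["negative"] == neg
            assert row["total"] == pos + neg

    def test_identity_total_is_pos_plus_neg(self, rng):
        ps = null_series(60, 8, 4)
        t = driving_scores(gca_matrix(ps)).table
        np.testing.assert_array_equal(
            t["total"].to_numpy(), (t["positive"] + t["negative"]).to_numpy()
        )

    def test_region_subset_restricts_sums(self):
        ps = null_series(40, 5, 5)
        g = gca_matrix(ps)
        sub = driving_scores(g, regions=["R1", "R3"]).table.set_index("region")
        assert np.isclose(sub.loc["R1", "total"], g.A[1, 3])
        assert np.isclose(sub.loc["R3", "total"], g.A[3, 1])


class TestPermutation:
    def test_seeded_determinism(self):
        ps = null_series(60, 5, 6)
        a = permutation_significance(ps, n_perm=200, seed=3)
        b = permutation_significance(ps, n_perm=200, seed=3)
        pd.testing.assert_frame_equal(a.scores.table, b.scores.table)
        np.testing.assert_array_equal(a.coefficient_p, b.coefficient_p)

    def test_p_values_respect_add_one_bounds(self):
        ps = null_series(50, 4, 7)
        res = permutation_significance(ps, n_perm=150, seed=0)
        lo = 1.0 / 151
        t = res.scores.table
        assert (t["p_pos"] >= lo).all() and (t["p_pos"] <= 1.0).all()
        assert (t["p_neg"] >= lo).all() and (t["p_neg"] <= 1.0).all()
        cp = res.coefficient_p[~np.isnan(res.coefficient_p)]
        assert (cp >= lo).all() and (cp <= 1.0).all()

    def test_min_permutations_enforced(self):
        ps = null_series(30, 3, 8)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_significance(ps, n_perm=50)

    def test_null_coefficient_p_values_uniform(self):
        """Under exchangeable null data the coefficient p-values are close
        to uniform (Kolmogorov-Smirnov screen)."""
        pool = []
        for rep in range(50):
            ps = null_series(120, 6, 3000 + rep)
            res = permutation_significance(ps, n_perm=199, seed=rep)
            pool.extend(res.coefficient_p[~np.isnan(res.coefficient_p)].ravel())
        assert stats.kstest(pool, "uniform").pvalue > 0.01

    def test_ordering_hash_recorded_and_order_sensitive(self, default_cohort):
        ps = build_pseudotime(default_cohort)
        res = permutation_significance(ps, n_perm=100, seed=0)
        assert res.ordering_hash == ps.ordering_hash
        reversed_ps = PseudoTimeSeries(
            list(reversed(ps.ordering)), ps.matrix[::-1].copy(), ps.region_names
        )
        assert reversed_ps.ordering_hash != ps.ordering_hash

    def test_constant_region_excluded_with_warning(self, rng):
        X = rng.standard_normal((40, 3))
        X[:, 1] = 2.0
        ps = PseudoTimeSeries([f"S{k}" for k in range(40)], X, ["a", "b", "c"])
        with pytest.warns(UserWarning, match="constant"):
            res = permutation_significance(ps, n_perm=100, seed=0)
        assert res.scores.table["region"].tolist() == ["a", "c"]


class TestBuildPseudotime:
    def test_rows_follow_cognition_ordering(self, default_cohort):
        ps = build_pseudotime(default_cohort)
        mmse = default_cohort.set_index("subject_id").loc[ps.ordering, "mmse"]
        assert (mmse.diff().dropna() <= 0).all()
        assert ps.matrix.shape == (150, 26)

    def test_standardization(self, default_cohort):
        ps = build_pseudotime(default_cohort)
        np.testing.assert_allclose(ps.matrix.mean(0), 0, atol=1e-12)
        np.testing.assert_allclose(ps.matrix.std(0), 1, atol=1e-12)

    def test_needs_two_regions(self, default_cohort):
        with pytest.raises(ValueError):
            build_pseudotime(default_cohort, region_cols=["vel_MCATL"])
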