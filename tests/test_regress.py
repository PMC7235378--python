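import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from imageprops.io import RatingTable
from imageprops.regress import (
    backward_aic,
    best_subsets,
    compare_feature_distributions,
    fit_mlr,
    spearman_matrix,
)


def frame(X):
    return pd.DataFrame(X, columns=[f"x{j}" for j in range(X.shape[1])])


class TestFitMlr:
    def test_exact_linear_combination(self, rng):
        X = frame(rng.standard_normal((40, 2)))
        y = 2 * X["x0"] - X["x1"]
        fit = fit_mlr(X, y)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)
        assert fit.coefficients["x0"] == pytest.approx(2.0)
        assert fit.coefficients["x1"] == pytest.approx(-1.0)

    def test_single_predictor_std_beta_is_pearson_r(self, rng):
        x = rng.standard_normal(80)
        y = 0.6 * x + rng.standard_normal(80)
        fit = fit_mlr(frame(x[:, None]), y)
        r = stats.pearsonr(x, y)[0]
        assert fit.std_betas["x0"] == pytest.approx(r, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(20):
            X = frame(rng.standard_normal((50, 5)))
            y = rng.standard_normal(50)
            fit = fit_mlr(X, y)
            A = np.column_stack([np.ones(50), X.to_numpy()])
            beta = np.linalg.solve(A.T @ A, A.T @ y)
            assert fit.intercept == pytest.approx(beta[0], abs=1e-8)
            for j in range(5):
                assert fit.coefficients[f"x{j}"] == pytest.approx(beta[j + 1], abs=1e-8)

    def test_adjusted_r2_formula(self, rng):
        X = frame(rng.standard_normal((60, 4)))
        y = X["x0"] + rng.standard_normal(60)
        fit = fit_mlr(X, y)
        expected = 1 - (1 - fit.r2) * (60 - 1) / (60 - 4 - 1)
        assert fit.r2_adj == pytest.approx(expected, abs=1e-12)
        assert fit.r2_adj <= fit.r2 <= 1.0

    def test_std_betas_invariant_to_affine_rescaling(self, rng):
        X = frame(rng.standard_normal((60, 3)))
        y = X["x0"] - 0.5 * X["x2"] + rng.standard_normal(60)
        a = fit_mlr(X, y)
        X2 = X.copy()
        X2["x1"] = 100 * X2["x1"] + 3
        b = fit_mlr(X2, 5 * y - 2)
        for c in X.columns:
            assert a.std_betas[c] == pytest.approx(b.std_betas[c], abs=1e-10)

    def test_exact_collinearity_names_columns(self, rng):
        X = frame(rng.standard_normal((40, 3)))
        X["x2"] = 2 * X["x0"] - X["x1"]
        with pytest.raises(ValueError, match="x2"):
            fit_mlr(X, rng.standard_normal(40))


class TestBackwardAic:
    def test_aic_strictly_decreasing_along_path(self, rng):
        X = frame(rng.standard_normal((200, 8)))
        y = X["x0"] + 0.5 * X["x1"] + rng.standard_normal(200)
        full = fit_mlr(X, y)
        red = backward_aic(X, y)
        aics = [full.aic] + [a for _, a in red.elimination_path]
        assert np.all(np.diff(aics) < 0)

    def test_noise_predictors_eliminated(self, rng):
        # one strong predictor plus five noise columns; noise should be
        # dropped at a high rate across repetitions
        dropped, total = 0, 0
        for rep in range(10):
            X = frame(rng.standard_normal((500, 6)))
            y = 1.0 * X["x0"] + rng.standard_normal(500)
            red = backward_aic(X, y)
            assert "x0" in red.predictors
            dropped += sum(f"x{j}" not in red.predictors for j in range(1, 6))
            total += 5
        assert dropped / total >= 0.8

    def test_strong_full_model_fully_retained(self, rng):
        X = frame(rng.standard_normal((500, 6)))
        y = X.to_numpy() @ np.full(6, 1.0) + 0.5 * rng.standard_normal(500)
        red = backward_aic(X, y)
        assert set(red.predictors) == set(X.columns)
        assert red.elimination_path == ()


class TestBestSubsets:
    def test_matches_brute_force_oracle(self, rng):
        X = frame(rng.standard_normal((50, 3)))
        y = X["x0"] - X["x2"] + rng.standard_normal(50)
        report = best_subsets(X, y)
        n = 50
        for k in (1, 2, 3):
            scored = []
            for combo in itertools.combinations(X.columns, k):
                fit = fit_mlr(X[list(combo)], y)
                scored.append((fit.r2_adj, combo))
            scored.sort(key=lambda t: -t[0])
            got = report.best_for_size(k)
            for rank, (r2_adj, combo) in enumerate(scored[: len(got)], start=1):
                row = got[got["rank"] == rank].iloc[0]
                assert row["r2_adj"] == pytest.approx(r2_adj, abs=1e-10)
                members = {c for c in X.columns if row[c]}
                assert members == set(combo)

    def test_full_size_equals_full_model(self, rng):
        X = frame(rng.standard_normal((50, 4)))
        y = rng.standard_normal(50)
        report = best_subsets(X, y)
        full_rows = report.best_for_size(4)
        assert len(full_rows) == 1
        assert full_rows.iloc[0]["r2_adj"] == pytest.approx(fit_mlr(X, y).r2_adj, abs=1e-10)

    def test_dominant_predictor_in_every_top_model(self, rng):
        X = frame(rng.standard_normal((200, 13)))
        y = 3.0 * X["x1"] + 0.1 * rng.standard_normal(200)
        report = best_subsets(X, y)
        # at k=1 only the single model {x1} can contain it; from k=2 on the
        # 12 x1-containing subsets dominate the whole top-10
        assert report.best_for_size(1).iloc[0]["x1"]
        multi = report.table[report.table["size"] >= 2]
        assert multi["x1"].all()

    def test_best_unadjusted_r2_nondecreasing_in_size(self, rng):
        X = frame(rng.standard_normal((80, 6)))
        y = X["x0"] + rng.standard_normal(80)
        report = best_subsets(X, y)
        best_r2 = report.table.groupby("size")["r2"].max()
        assert np.all(np.diff(best_r2.to_numpy()) >= -1e-12)

    def test_too_many_predictors_guarded(self, rng):
        X = frame(rng.standard_normal((50, 21)))
        with pytest.raises(ValueError, match="20"):
            best_subsets(X, rng.standard_normal(50))


class TestSpearman:
    def test_self_and_monotone(self):
        x = np.arange(40.0)
        rt = RatingTable(
            pd.DataFrame({"a": x, "b": -x}, index=[f"i{k}" for k in range(40)])
        )
        r, p = spearman_matrix(rt)
        assert r.loc["a", "a"] == 1.0
        assert r.loc["a", "b"] == pytest.approx(-1.0)
        assert p.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_rank_then_pearson_with_ties(self, rng):
        a = rng.integers(0, 5, size=60).astype(float)
        b = a + rng.integers(0, 3, size=60)
        rt = RatingTable(pd.DataFrame({"a": a, "b": b}, index=[f"i{k}" for k in range(60)]))
        r, _ = spearman_matrix(rt)
        ra = stats.rankdata(a)
        rb = stats.rankdata(b)
        assert r.loc["a", "b"] == pytest.approx(stats.pearsonr(ra, rb)[0], abs=1e-12)


def holm_oracle(pvals):
    """Textbook Holm step-down: sorted p * (m - rank + 1), monotonized."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = min(1.0, (m - rank) * pvals[idx])
        running = max(running, val)
        adj[idx] = running
    return adj


class TestCompareFeatureDistributions:
    def test_identical_groups_nonsignificant(self, rng):
        base = pd.DataFrame({"f": rng.standard_normal(50)})
        out = compare_feature_distributions([base, base.copy()], ["a", "b"])
        kw = out[out["test"] == "kruskal"].iloc[0]
        assert kw["statistic"] == pytest.approx(0.0, abs=1e-9)
        assert kw["p"] > 0.9

    def test_large_shift_significant_after_correction(self, rng):
        a = pd.DataFrame({"f": rng.standard_normal(100)})
        b = pd.DataFrame({"f": rng.standard_normal(100) + 5.0})
        out = compare_feature_distributions([a, b], ["a", "b"])
        pw = out[out["test"] == "pairwise"].iloc[0]
        assert pw["p_corrected"] < 1e-4

    def test_holm_correction_matches_oracle(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(10):
            pvals = rng.uniform(size=6)
            adj = multipletests(pvals, method="holm")[1]
            np.testing.assert_allclose(adj, holm_oracle(pvals), atol=1e-12)

    def test_three_groups_pairwise_family(self, rng):
        groups = [pd.DataFrame({"f": rng.standard_normal(30) + mu}) for mu in (0, 0, 4)]
        out = compare_feature_distributions(groups, ["a", "b", "c"])
        pw = out[out["test"] == "pairwise"]
        assert len(pw) == 3  # 3 pairs for one feature
        sig = pw[(pw["group_a"] == "a") & (pw["group_b"] == "c")]["p_corrected"].iloc[0]
        assert sig < 0.001
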