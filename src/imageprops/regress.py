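"""Multiple linear regression, backward AIC elimination, best subsets,
rating correlations and group comparisons of feature distributions.

The regression surface mirrors the standard analysis of rating tables:

* :func:`fit_mlr` -- ordinary least squares of one rating on the 13 image
  properties, reporting R^2, adjusted R^2 (1 - (1-R^2)(n-1)/(n-p-1)),
  standardized coefficients beta_i = b_i * sd(x_i)/sd(y), per-coefficient
  two-sided t p-values, and AIC in the n*ln(RSS/n) + 2(p+1) convention
  (only AIC differences matter for model comparison).
* :func:`backward_aic` -- backward stepwise elimination: repeatedly drop the
  predictor whose removal most decreases AIC, stop when no removal helps.
* :func:`best_subsets` -- exhaustive search over all predictor subsets of
  each size k, ranked by adjusted R^2 (for fixed k this equals ranking by
  R^2), reporting the top models per size and a membership matrix for
  plotting.
* :func:`spearman_matrix` -- pairwise Spearman rank correlations (average
  ranks for ties) with two-sided p-values among rating terms.
* :func:`compare_feature_distributions` -- per-feature Kruskal-Wallis test
  across image groups with pairwise Wilcoxon rank-sum post-hoc tests,
  Holm-corrected within each feature's family of pairs.

Coefficient p-values are reported unadjusted across the 13 predictors (a
multiplicity caveat applies when interpreting single coefficients).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import RatingTable

__all__ = [
    "MLRFit",
    "SubsetReport",
    "fit_mlr",
    "backward_aic",
    "best_subsets",
    "spearman_matrix",
    "compare_feature_distributions",
]


@dataclass(frozen=True)
class MLRFit:
    """An OLS fit of a rating on a set of image properties."""

    predictors: tuple[str, ...]
    coefficients: dict[str, float]  # raw slopes, keyed by predictor
    intercept: float
    std_betas: dict[str, float]
    std_beta_se: dict[str, float]  # standard errors on the std_betas scale
    p_values: dict[str, float]
    r2: float
    r2_adj: float
    aic: float
    n: int
    rss: float
    elimination_path: tuple[tuple[str, float], ...] = field(default_factory=tuple)

    @property
    def n_predictors(self) -> int:
        return len(self.predictors)


def _check_collinearity(X: pd.DataFrame) -> None:
    A = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # name a minimal set of columns involved in the exact dependency
        bad: list[str] = []
        cols = list(X.columns)
        base = np.ones((len(X), 1))
        cur = base
        for c in cols:
            cand = np.column_stack([cur, X[c].to_numpy(dtype=float)])
            if np.linalg.matrix_rank(cand) == cur.shape[1]:
                bad.append(c)
            else:
                cur = cand
        raise ValueError(f"exactly collinear predictor columns: {bad}")


def fit_mlr(X: pd.DataFrame, y: pd.Series | np.ndarray) -> MLRFit:
    """Ordinary least squares of ``y`` on the columns of ``X``."""
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 2:
        raise ValueError(f"need n > p + 2 observations (n={n}, p={p})")
    if np.isnan(y).any() or X.isna().any().any():
        raise ValueError("missing values in regression inputs")
    _check_collinearity(X)
    Xd = sm.add_constant(X.to_numpy(dtype=float))
    res = sm.OLS(y, Xd).fit()
    rss = float(res.ssr)
    aic = n * np.log(rss / n) + 2 * (p + 1)
    sy = y.std(ddof=1)
    cols = list(X.columns)
    coef = dict(zip(cols, res.params[1:]))
    std_betas = {
        c: float(coef[c] * X[c].std(ddof=1) / sy) if sy > 0 else np.nan for c in cols
    }
    se = dict(zip(cols, res.bse[1:]))
    std_beta_se = {
        c: float(se[c] * X[c].std(ddof=1) / sy) if sy > 0 else np.nan for c in cols
    }
    return MLRFit(
        predictors=tuple(cols),
        coefficients={c: float(v) for c, v in coef.items()},
        intercept=float(res.params[0]),
        std_betas=std_betas,
        std_beta_se=std_beta_se,
        p_values=dict(zip(cols, (float(v) for v in res.pvalues[1:]))),
        r2=float(res.rsquared),
        r2_adj=float(res.rsquared_adj),
        aic=float(aic),
        n=n,
        rss=rss,
    )


def backward_aic(X: pd.DataFrame, y: pd.Series | np.ndarray) -> MLRFit:
    """Backward stepwise elimination driven by AIC.

    Starting from the full model, the single predictor whose removal most
    decreases AIC is dropped; the loop stops when no removal decreases AIC.
    The refitted reduced model is returned with the elimination path
    (removed predictor, AIC after removal) attached.
    """
    current = fit_mlr(X, y)
    path: list[tuple[str, float]] = []
    cols = list(X.columns)
    while cols:
        candidates = []
        for c in cols:
            reduced_cols = [k for k in cols if k != c]
            if reduced_cols:
                fit = fit_mlr(X[reduced_cols], y)
            else:
                fit = _intercept_only(y)
            candidates.append((fit.aic, c, fit))
        best_aic, removed, best_fit = min(candidates, key=lambda t: (t[0], t[1]))
        if best_aic >= current.aic:
            break
        current = best_fit
        cols = [k for k in cols if k != removed]
        path.append((removed, best_aic))
    return MLRFit(**{**current.__dict__, "elimination_path": tuple(path)})


def _intercept_only(y: np.ndarray) -> MLRFit:
    y = np.asarray(y, dtype=float)
    n = len(y)
    rss = float(((y - y.mean()) ** 2).sum())
    return MLRFit(
        predictors=(),
        coefficients={},
        intercept=float(y.mean()),
        std_betas={},
        std_beta_se={},
        p_values={},
        r2=0.0,
        r2_adj=0.0,
        aic=float(n * np.log(rss / n) + 2),
        n=n,
        rss=rss,
    )


@dataclass(frozen=True)
class SubsetReport:
    """Top subsets per model size from exhaustive best-subset search.

    ``table`` has one row per (size, rank) with columns ``size``, ``rank``,
    ``r2_adj``, ``r2`` and one boolean membership column per predictor --
    directly plottable as a shaded membership matrix.
    """

    table: pd.DataFrame
    predictors: tuple[str, ...]

    def best_for_size(self, k: int) -> pd.DataFrame:
        return self.table[self.table["size"] == k]

    def membership_matrix(self) -> pd.DataFrame:
        return self.table.set_index(["size", "rank"])[list(self.predictors)]


def best_subsets(
    X: pd.DataFrame, y: pd.Series | np.ndarray, max_k: int | None = None, top: int = 10
) -> SubsetReport:
    """Exhaustive subset search ranked by adjusted R^2.

    Enumerates all C(p, k) predictor subsets for each size k = 1..max_k and
    keeps the ``top`` best by adjusted R^2 (ties broken by subset order).
    Guarded to p <= 20 predictors (2^p enumeration).
    """
    y = np.asarray(y, dtype=float)
    cols = list(X.columns)
    p = len(cols)
    if p > 20:
        raise ValueError(f"p={p} predictors: exhaustive enumeration is limited to 20; screen first")
    if max_k is None:
        max_k = p
    n = len(y)
    Xc = X.to_numpy(dtype=float) - X.to_numpy(dtype=float).mean(axis=0)
    yc = y - y.mean()
    tss = float(yc @ yc)
    rows = []
    for k in range(1, max_k + 1):
        scored = []
        for combo in itertools.combinations(range(p), k):
            sub = Xc[:, combo]
            beta, *_ = np.linalg.lstsq(sub, yc, rcond=None)
            rss = float(((yc - sub @ beta) ** 2).sum())
            r2 = 1.0 - rss / tss
            r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
            scored.append((r2_adj, r2, combo))
        scored.sort(key=lambda t: (-t[0], t[2]))
        for rank, (r2_adj, r2, combo) in enumerate(scored[:top], start=1):
            row = {"size": k, "rank": rank, "r2_adj": r2_adj, "r2": r2}
            for j, c in enumerate(cols):
                row[c] = j in combo
            rows.append(row)
    return SubsetReport(pd.DataFrame(rows), tuple(cols))


def spearman_matrix(ratings: RatingTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman correlations (r, two-sided p) among rating terms."""
    terms = ratings.terms
    if len(terms) < 2:
        raise ValueError("need >= 2 rating terms")
    r = pd.DataFrame(np.eye(len(terms)), index=terms, columns=terms)
    p = pd.DataFrame(np.zeros((len(terms), len(terms))), index=terms, columns=terms)
    for a, b in itertools.combinations(terms, 2):
        sub = ratings.data[[a, b]].dropna()
        rho, pv = stats.spearmanr(sub[a], sub[b])
        r.loc[a, b] = r.loc[b, a] = rho
        p.loc[a, b] = p.loc[b, a] = pv
    return r, p


def compare_feature_distributions(
    tables: list[pd.DataFrame], groups: list[str]
) -> pd.DataFrame:
    """Kruskal-Wallis across groups per feature, with Holm-corrected
    pairwise Wilcoxon rank-sum post-hoc tests.

    Returns a long-format frame: one ``kruskal`` row per feature (statistic,
    p) and one ``pairwise`` row per feature and group pair (corrected p).
    """
    if len(tables) != len(groups) or len(tables) < 2:
        raise ValueError("need >= 2 groups with matching names")
    for t, g in zip(tables, groups):
        if len(t) < 5:
            raise ValueError(f"group {g!r} has fewer than 5 rows")
    features = list(tables[0].columns)
    rows = []
    for feat in features:
        samples = [t[feat].dropna().to_numpy() for t in tables]
        try:
            h, p = stats.kruskal(*samples)
        except ValueError:  # all values identical across groups
            h, p = 0.0, 1.0
        rows.append(
            {"feature": feat, "test": "kruskal", "group_a": "", "group_b": "",
             "statistic": float(h), "p": float(p), "p_corrected": np.nan}
        )
        pairs = list(itertools.combinations(range(len(groups)), 2))
        raw = []
        for i, j in pairs:
            if np.ptp(np.concatenate([samples[i], samples[j]])) == 0:
                raw.append(1.0)
            else:
                _, pv = stats.mannwhitneyu(samples[i], samples[j], alternative="two-sided")
                raw.append(float(pv))
        corrected = multipletests(raw, method="holm")[1]
        for (i, j), pv, pc in zip(pairs, raw, corrected):
            rows.append(
                {"feature": feat, "test": "pairwise", "group_a": groups[i],
                 "group_b": groups[j], "statistic": np.nan, "p": pv,
                 "p_corrected": float(pc)}
            )
    return pd.DataFrame(rows)
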