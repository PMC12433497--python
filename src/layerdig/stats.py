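"""Statistical stages: fence-based outlier removal, between-line tests,
significance-masked correlations, PCA summaries and linear prediction models.

The stages operate on a per-bird trait table (one row per bird, columns
``bird_id``, ``line`` and numeric traits) and mirror a conventional
two-line phenotype comparison: records are screened once with Tukey
fences per line, line differences are tested with two-sample t-tests
(Welch by default), trait coherence is summarised with Pearson
correlations masked at alpha and a standardized PCA, and feed efficiency
is regressed on either performance traits (egg mass + body weight) or a
single digestibility coefficient at a time. No multiple-testing
correction is applied; alpha = 0.05 throughout by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "DEFAULT_SCREEN_TRAITS",
    "LineComparison",
    "CorrelationMatrix",
    "PCAResult",
    "ModelFit",
    "iqr_filter",
    "line_ttest",
    "correlation_matrix",
    "pca_summary",
    "fit_performance_model",
    "fit_dc_model",
    "p_value_band",
]

#: Traits screened by the fence filter when none are named explicitly.
DEFAULT_SCREEN_TRAITS = (
    "dfc", "em", "dmw", "dbw", "fcr", "dc_dm", "dc_fat", "dc_n", "dc_org",
)


@dataclass(frozen=True)
class LineComparison:
    """Between-line summary for one trait: per-line mean (SE) and the test p."""

    trait: str
    mean_a: float
    se_a: float
    n_a: int
    mean_b: float
    se_b: float
    n_b: int
    t_statistic: float
    p_value: float


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise Pearson correlations with p-values and a significance mask.

    ``significant`` is True where p < alpha; undefined pairs (constant
    trait, insufficient overlap) carry NaN r and are masked.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame
    alpha: float


@dataclass(frozen=True)
class PCAResult:
    """Principal components of the (optionally standardized) trait table.

    ``explained_pct`` sums to 100 over the retained dimensions;
    ``loadings`` has orthonormal columns (one per dimension);
    ``contributions`` gives each trait's percentage contribution to each
    dimension (squared loading x 100).
    """

    explained_pct: np.ndarray
    loadings: pd.DataFrame
    contributions: pd.DataFrame
    n_obs: int
    standardized: bool


@dataclass(frozen=True)
class ModelFit:
    """An OLS fit: coefficient table (estimate, se, t, p) plus R^2."""

    response: str
    coefficients: pd.DataFrame
    r_squared: float
    n_obs: int
    df_resid: int


def _screened(df: pd.DataFrame, traits) -> list[str]:
    if traits is None:
        return [t for t in DEFAULT_SCREEN_TRAITS if t in df.columns]
    missing = [t for t in traits if t not in df.columns]
    if missing:
        raise KeyError(f"screen trait(s) not in table: {missing}")
    return list(traits)


def iqr_filter(
    df: pd.DataFrame,
    k: float = 1.5,
    traits=None,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Remove whole records outside the Tukey fences, per line and per trait.

    For every line and screened trait, quartiles are taken by linear
    interpolation and a record is removed if any screened trait falls
    outside [Q1 - k*IQR, Q3 + k*IQR]. Fences are computed once on the
    incoming data (not re-iterated after removal). Missing trait values do
    not trigger removal. Returns the retained table and the removed bird
    ids per line.
    """
    if "line" not in df.columns or "bird_id" not in df.columns:
        raise KeyError("trait table must have 'line' and 'bird_id' columns")
    traits = _screened(df, traits)
    removed: dict[str, list[str]] = {}
    keep = pd.Series(True, index=df.index)
    for label, grp in df.groupby("line", sort=True):
        if len(grp) < 4:
            raise ValueError(f"line {label}: need >= 4 records for quartiles, got {len(grp)}")
        bad = pd.Series(False, index=grp.index)
        for t in traits:
            vals = grp[t].dropna()
            if vals.empty:
                continue
            q1, q3 = np.percentile(vals.to_numpy(dtype=float), [25, 75])
            iqr = q3 - q1
            lo, hi = q1 - k * iqr, q3 + k * iqr
            bad |= (grp[t] < lo) | (grp[t] > hi)
        removed[str(label)] = sorted(grp.loc[bad, "bird_id"].tolist())
        keep.loc[grp.index[bad]] = False
    out = df.loc[keep].reset_index(drop=True)
    if out.empty:
        raise ValueError("outlier filter removed every record; check the inputs")
    return out, removed


def line_ttest(
    values_a,
    values_b,
    trait: str = "",
    *,
    equal_var: bool = False,
) -> LineComparison:
    """Two-sample t-test between lines (Welch by default; pooled via flag).

    Degenerate input with zero variance in both groups and equal means is
    reported as t = 0, p = 1 by convention.
    """
    a = pd.Series(values_a).dropna().to_numpy(dtype=float)
    b = pd.Series(values_b).dropna().to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per line")
    if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return LineComparison(
        trait=trait,
        mean_a=float(a.mean()), se_a=float(a.std(ddof=1) / np.sqrt(len(a))), n_a=len(a),
        mean_b=float(b.mean()), se_b=float(b.std(ddof=1) / np.sqrt(len(b))), n_b=len(b),
        t_statistic=float(t_stat), p_value=float(p),
    )


def correlation_matrix(
    df: pd.DataFrame,
    traits=None,
    alpha: float = 0.05,
) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations with t-distribution p-values.

    Pairs whose p >= alpha are masked (``significant`` False), matching the
    grey-cross convention of correlation heatmaps. Constant traits yield
    NaN and are masked.
    """
    if traits is None:
        traits = [c for c in df.columns if c not in ("bird_id", "line")]
    sub = df[list(traits)]
    if len(sub.dropna()) < 3:
        raise ValueError("need at least 3 complete records")
    m = len(traits)
    r = np.eye(m)
    p = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            pair = sub.iloc[:, [i, j]].dropna()
            x, y = pair.iloc[:, 0], pair.iloc[:, 1]
            if len(pair) < 3 or x.nunique() < 2 or y.nunique() < 2:
                rij, pij = np.nan, np.nan
            else:
                rij, pij = sps.pearsonr(x, y)
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    r_df = pd.DataFrame(r, index=traits, columns=traits)
    p_df = pd.DataFrame(p, index=traits, columns=traits)
    sig = (p_df < alpha) & r_df.notna()
    np.fill_diagonal(sig.values, True)
    return CorrelationMatrix(r=r_df, p=p_df, significant=sig, alpha=alpha)


def pca_summary(
    df: pd.DataFrame,
    traits=None,
    standardize: bool = True,
) -> PCAResult:
    """PCA of the trait table via SVD of the centered (scaled) matrix.

    Standardization (the default) puts traits measured in grams, percent
    and ratios on a common footing. Explained-variance percentages are
    singular-value based and sum to 100 over the retained dimensions;
    rank-deficient input simply yields fewer dimensions. Rows with any
    missing trait are dropped.
    """
    if traits is None:
        traits = [c for c in df.columns if c not in ("bird_id", "line")]
    x = df[list(traits)].dropna().to_numpy(dtype=float)
    n, m = x.shape
    if n <= m:
        raise ValueError(f"need more observations ({n}) than traits ({m})")
    x = x - x.mean(axis=0)
    if standardize:
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            const = [t for t, s in zip(traits, sd) if s == 0]
            raise ValueError(f"constant trait(s) cannot be standardized: {const}")
        x = x / sd
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    tol = s.max() * max(x.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    var = s[:rank] ** 2
    explained = var / var.sum() * 100.0
    dims = [f"dim{i + 1}" for i in range(rank)]
    loadings = pd.DataFrame(vt[:rank].T, index=traits, columns=dims)
    contributions = loadings**2 * 100.0
    return PCAResult(
        explained_pct=explained,
        loadings=loadings,
        contributions=contributions,
        n_obs=n,
        standardized=standardize,
    )


def _ols(df: pd.DataFrame, response: str, predictors: list[str]) -> ModelFit:
    sub = df[[response, *predictors]].dropna()
    if len(sub) < len(predictors) + 2:
        raise ValueError(
            f"need at least {len(predictors) + 2} complete records, got {len(sub)}"
        )
    for pcol in predictors:
        if sub[pcol].nunique() < 2:
            raise ValueError(f"predictor {pcol!r} is constant")
    X = sm.add_constant(sub[predictors].to_numpy(dtype=float))
    fit = sm.OLS(sub[response].to_numpy(dtype=float), X).fit()
    names = ["intercept", *predictors]
    table = pd.DataFrame(
        {
            "coefficient": names,
            "estimate": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    ).reset_index(drop=True)
    return ModelFit(
        response=response,
        coefficients=table,
        r_squared=float(fit.rsquared),
        n_obs=int(fit.nobs),
        df_resid=int(fit.df_resid),
    )


def fit_performance_model(df: pd.DataFrame, response: str) -> ModelFit:
    """OLS of FCR or RFC on egg mass and daily body weight.

    Daily feed consumed and laying percentage are deliberately excluded:
    both are arithmetically confounded with the response.
    """
    return _ols(df, response, ["em", "dbw"])


def fit_dc_model(df: pd.DataFrame, response: str, dc: str) -> ModelFit:
    """OLS of FCR or RFC on a single digestibility coefficient.

    One DC at a time because the DCs are strongly mutually correlated;
    ``dc`` is one of ``dc_dm``, ``dc_n``, ``dc_org`` (``dc_fat`` accepted).
    """
    if dc not in ("dc_dm", "dc_n", "dc_org", "dc_fat"):
        raise ValueError(f"unsupported DC predictor {dc!r}")
    return _ols(df, response, [dc])


def p_value_band(p: float) -> str:
    """Render a p-value with conventional significance bands."""
    if np.isnan(p):
        return "NA"
    for threshold in (0.001, 0.01, 0.05, 0.1):
        if p < threshold:
            return f"<{threshold:g}"
    return f"{p:.2f}"
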