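"""Association statistics: robust outlier removal, hierarchical regression and
Benjamini-Hochberg correction across a family of models."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "ModelSpec",
    "StatResult",
    "mcd_outliers",
    "hierarchical_regression",
    "bh_correct",
    "run_models",
]

TRANSFORMS = {
    None: lambda x: x,
    "sqrt": lambda x: np.sqrt(x),
    "log": lambda x: np.log(x),
}


@dataclass
class ModelSpec:
    """One hierarchical (or simple) regression model.

    ``step1`` covariates enter first; ``step2`` is the focal predictor whose
    incremental contribution is tested. An empty ``step1`` yields a simple
    regression where the omnibus and change tests coincide.
    """

    dependent: str
    step2: str
    step1: Sequence[str] = field(default_factory=list)
    transform: dict[str, Optional[str]] = field(default_factory=dict)
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.step2 in self.step1:
            raise ValueError("focal predictor cannot also be a step-1 covariate")
        if self.name is None:
            self.name = f"{self.dependent}~{self.step2}"

    @property
    def variables(self) -> list[str]:
        return [self.dependent, *self.step1, self.step2]


@dataclass
class StatResult:
    model: str
    n: int
    outliers: list
    adj_r2_final: float
    delta_adj_r2: float
    f_change: float
    df_change: tuple[int, int]
    p_change: float
    beta_focal: float
    beta_ci: tuple[float, float]
    p_omnibus: float
    p_bh: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "n": self.n,
            "outliers_removed": list(self.outliers),
            "adj_r2_final": self.adj_r2_final,
            "delta_adj_r2": self.delta_adj_r2,
            "F_change": self.f_change,
            "df_change": list(self.df_change),
            "p_change": self.p_change,
            "beta_focal_std": self.beta_focal,
            "beta_ci95": list(self.beta_ci),
            "p_omnibus": self.p_omnibus,
            "p_bh": self.p_bh,
        }


def mcd_outliers(
    X: np.ndarray,
    support_fraction: float = 0.75,
    quantile: float = 0.975,
    seed: Optional[int] = 0,
) -> np.ndarray:
    """Flag multivariate outliers by robust Mahalanobis distance.

    Location/scatter come from the Minimum Covariance Determinant estimator;
    rows whose robust squared distance exceeds the chi-squared ``quantile`` for
    ``dim`` degrees of freedom are flagged. Returns a boolean mask (True =
    outlier).
    """
    from sklearn.covariance import MinCovDet

    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n < 2 * (p + 1):
        raise ValueError(f"need at least {2 * (p + 1)} rows for dim={p}")
    if np.any(~np.isfinite(X)):
        raise ValueError("missing or non-finite values among model variables")
    try:
        mcd = MinCovDet(support_fraction=support_fraction, random_state=seed).fit(X)
    except ValueError as exc:  # singular subsets raise inside sklearn
        raise ValueError(f"MCD failed: {exc}") from exc
    cov = mcd.covariance_
    if not np.all(np.isfinite(cov)) or np.linalg.matrix_rank(cov) < p or (
        np.linalg.det(cov) <= np.finfo(float).tiny
    ):
        raise ValueError("robust scatter matrix is singular")
    d2 = mcd.mahalanobis(X)
    # small-sample consistency rescaling: align the distance median with the
    # chi-squared median so the quantile rule holds its nominal level
    med = np.median(d2)
    if med > 0:
        d2 = d2 * sstats.chi2.ppf(0.5, df=p) / med
    return d2 > sstats.chi2.ppf(quantile, df=p)


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Coefficients, residual sum of squares and R^2 for a design with intercept."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return beta, rss, r2


def hierarchical_regression(
    table: pd.DataFrame,
    spec: ModelSpec,
    cond_threshold: float = 1e10,
) -> StatResult:
    """Two-step OLS with incremental-variance (F-change) test for the focal predictor.

    Reports the final adjusted R², the adjusted-R² increment from adding the
    focal predictor, the F-change test with its df and p value, the
    standardized focal coefficient with a 95% CI, and the final model's omnibus
    F p value.
    """
    cols = spec.variables
    data = table[cols].copy()
    for var, tag in spec.transform.items():
        if tag is not None:
            data[var] = TRANSFORMS[tag](data[var].to_numpy(dtype=float))
    arr = data.to_numpy(dtype=float)
    if np.any(~np.isfinite(arr)):
        raise ValueError("non-finite values after transforms")
    n = arr.shape[0]
    n_params_full = len(spec.step1) + 2  # intercept + covariates + focal
    if n <= n_params_full + 1:
        raise ValueError("too few rows for the requested model")
    y = arr[:, 0]
    covs = arr[:, 1 : 1 + len(spec.step1)]
    focal = arr[:, -1]

    X1 = np.column_stack([np.ones(n), covs]) if len(spec.step1) else np.ones((n, 1))
    X2 = np.column_stack([X1, focal])
    if np.linalg.cond(X2) > cond_threshold:
        raise ValueError("collinear predictors (design condition number too large)")

    _, rss1, r2_1 = _ols(y, X1)
    beta2, rss2, r2_2 = _ols(y, X2)
    p1, p2 = X1.shape[1], X2.shape[1]
    df2 = n - p2
    q = p2 - p1

    def adj(r2: float, n_pred: int) -> float:
        return 1.0 - (1.0 - r2) * (n - 1) / (n - n_pred - 1)

    adj1 = adj(r2_1, p1 - 1)
    adj2 = adj(r2_2, p2 - 1)
    if rss2 <= 0:
        f_change, p_change = np.inf, 0.0
    else:
        f_change = ((rss1 - rss2) / q) / (rss2 / df2)
        p_change = float(sstats.f.sf(f_change, q, df2))

    # omnibus F of the final model
    tss = float(np.sum((y - y.mean()) ** 2))
    if rss2 <= 0 or tss <= 0:
        p_omni = 0.0 if tss > 0 else 1.0
    else:
        f_omni = ((tss - rss2) / (p2 - 1)) / (rss2 / df2)
        p_omni = float(sstats.f.sf(f_omni, p2 - 1, df2))

    # standardized focal coefficient and its 95% CI
    sd_y = y.std(ddof=1)
    sd_x = focal.std(ddof=1)
    if sd_x == 0:
        raise ValueError("focal predictor has zero variance")
    coef = float(beta2[-1])
    sigma2 = rss2 / df2 if df2 > 0 else np.nan
    xtx_inv = np.linalg.inv(X2.T @ X2)
    se = float(np.sqrt(sigma2 * xtx_inv[-1, -1]))
    tcrit = sstats.t.ppf(0.975, df2)
    scale = sd_x / sd_y if sd_y > 0 else np.nan
    beta_std = coef * scale
    ci = ((coef - tcrit * se) * scale, (coef + tcrit * se) * scale)

    return StatResult(
        model=spec.name or "",
        n=n,
        outliers=[],
        adj_r2_final=float(adj2),
        delta_adj_r2=float(adj2 - adj1),
        f_change=float(f_change),
        df_change=(int(q), int(df2)),
        p_change=p_change,
        beta_focal=float(beta_std),
        beta_ci=(float(ci[0]), float(ci[1])),
        p_omnibus=p_omni,
    )


def bh_correct(p_values: Sequence[float], m: Optional[int] = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, in input order.

    ``m`` is the size of the comparison family and may exceed the number of
    p values passed (unrun planned models); defaults to ``len(p_values)``.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    k = len(p)
    if m is None:
        m = k
    if m < k:
        raise ValueError("m must be at least the number of p values")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, k + 1)
    # enforce monotonicity from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(k)
    out[order] = adj
    return out


def run_models(
    table: pd.DataFrame,
    specs: Sequence[ModelSpec],
    bh_m: Optional[int] = None,
    remove_outliers: bool = True,
    id_column: Optional[str] = "id",
    seed: int = 0,
) -> list[StatResult]:
    """Fit every model (with per-model MCD outlier removal) and BH-correct the
    omnibus p values across the family."""
    results = []
    for spec in specs:
        sub = table.dropna(subset=spec.variables)
        data = sub[spec.variables].copy()
        for var, tag in spec.transform.items():
            if tag is not None:
                data[var] = TRANSFORMS[tag](data[var].to_numpy(dtype=float))
        removed: list = []
        if remove_outliers:
            mask = mcd_outliers(data.to_numpy(dtype=float), seed=seed)
            if id_column and id_column in sub.columns:
                removed = sub.loc[mask, id_column].tolist()
            else:
                removed = sub.index[mask].tolist()
            sub = sub.loc[~mask]
        # transforms are re-applied inside hierarchical_regression
        res = hierarchical_regression(sub, spec)
        res.outliers = removed
        results.append(res)
    adj = bh_correct([r.p_omnibus for r in results], m=bh_m)
    for r, a in zip(results, adj):
        r.p_bh = float(a)
    return results
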