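"""Fit-accuracy evaluation: transformed linear models, GLS with exponential
variance, and nested variance components.

Surrogate fit accuracy is the R² of a linear model of a phylogeny-based
metric on its clade index (Faith's PD square-root transformed, VPD
log-transformed, MPD untransformed). Heteroscedastic regularity fits use
generalized least squares with an exponential variance function,
Var(e_i) = sigma^2 * exp(2 * delta * v_i), delta estimated by maximum
likelihood (profile over delta). Simulation-wide R² tables are decomposed
into nested variance components (scale / pool size / richness range /
residual) by balanced-design expected mean squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "FitResult",
    "VarianceComponents",
    "fit_linear",
    "fit_gls_varexp",
    "variance_components",
    "DegenerateFitError",
    "ConvergenceError",
]


class DegenerateFitError(ValueError):
    """Zero-variance predictor/response or too few usable observations."""


class ConvergenceError(RuntimeError):
    """Iterative estimation failed to converge."""


@dataclass
class FitResult:
    """One fitted model.

    coefficients are (intercept, slope[, quadratic]); r_squared is the
    ordinary coefficient of determination for OLS and, for GLS, the squared
    correlation of fitted vs observed (pseudo-R², the definition is
    reported, not interchangeable with OLS R²).
    """

    model: str  # "ols" | "ols+quadratic" | "gls-varexp"
    transform: str  # "none" | "sqrt" | "log"
    coefficients: tuple[float, ...]
    r_squared: float
    n_used: int
    n_dropped: int = 0
    quad_pvalue: float | None = None
    delta: float | None = None
    loglik: float | None = None

    def to_text(self) -> str:
        lines = [
            f"model\t{self.model}",
            f"transform\t{self.transform}",
            f"coefficients\t{', '.join(f'{c:.10g}' for c in self.coefficients)}",
            f"r_squared\t{self.r_squared:.10g}",
            f"n_used\t{self.n_used}",
            f"n_dropped\t{self.n_dropped}",
        ]
        if self.quad_pvalue is not None:
            lines.append(f"quad_pvalue\t{self.quad_pvalue:.6g}")
        if self.delta is not None:
            lines.append(f"delta\t{self.delta:.10g}")
        if self.loglik is not None:
            lines.append(f"loglik\t{self.loglik:.10g}")
        return "\n".join(lines) + "\n"


def _clean_xy(
    x, y, transform: str
) -> tuple[np.ndarray, np.ndarray, int]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    ok = np.isfinite(x) & np.isfinite(y)
    if transform == "log":
        ok &= y > 0
    elif transform == "sqrt":
        ok &= y >= 0
    elif transform != "none":
        raise ValueError(f"unknown transform: {transform!r}")
    n_dropped = int(x.size - ok.sum())
    x, y = x[ok], y[ok]
    if transform == "log":
        y = np.log(y)
    elif transform == "sqrt":
        y = np.sqrt(y)
    return x, y, n_dropped


def fit_linear(
    x: Sequence[float],
    y: Sequence[float],
    transform: str = "none",
    quadratic: bool = False,
) -> FitResult:
    """OLS of (transformed) y on x; optionally with a quadratic term.

    Rows with missing values (and, for the log transform, nonpositive
    responses) are dropped and counted. Raises
    :class:`DegenerateFitError` when fewer than 3 usable pairs remain or
    either variable has zero variance.
    """
    import statsmodels.api as sm

    xx, yy, n_dropped = _clean_xy(x, y, transform)
    if xx.size < 3:
        raise DegenerateFitError(
            f"need >= 3 complete pairs, have {xx.size} ({n_dropped} dropped)"
        )
    if np.ptp(xx) == 0:
        raise DegenerateFitError("zero predictor variance")
    if np.ptp(yy) == 0:
        raise DegenerateFitError("zero response variance")
    cols = [np.ones_like(xx), xx]
    if quadratic:
        cols.append(xx**2)
    X = np.column_stack(cols)
    res = sm.OLS(yy, X).fit()
    quad_p = float(res.pvalues[2]) if quadratic else None
    return FitResult(
        model="ols+quadratic" if quadratic else "ols",
        transform=transform,
        coefficients=tuple(float(b) for b in res.params),
        r_squared=float(res.rsquared),
        n_used=int(xx.size),
        n_dropped=n_dropped,
        quad_pvalue=quad_p,
        loglik=float(res.llf),
    )


def _varexp_profile_loglik(
    delta: float, X: np.ndarray, y: np.ndarray, v: np.ndarray
) -> tuple[float, np.ndarray, float]:
    """Profile ML log-likelihood at delta, with beta-hat and sigma^2-hat."""
    n = y.size
    # standard-deviation multiplier exp(delta * v); weighted least squares
    log_m = delta * v
    log_m = log_m - log_m.mean()  # absorb the constant into sigma^2
    w = np.exp(-log_m)
    Xw = X * w[:, None]
    yw = y * w
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    rss = float(((yw - Xw @ beta) ** 2).sum())
    sigma2 = rss / n
    if sigma2 <= 0:
        return math.inf, beta, sigma2
    ll = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0) - float(log_m.sum())
    return ll, beta, sigma2


def fit_gls_varexp(
    x: Sequence[float],
    y: Sequence[float],
    variance_covariate: Sequence[float] | None = None,
    transform: str = "none",
) -> FitResult:
    """GLS with exponential variance: Var(e_i) = sigma^2 * exp(2*delta*v_i).

    The mean model is linear in x; v defaults to x. (beta, delta, sigma^2)
    are estimated by maximum likelihood, profiling the likelihood over delta
    with a 1-D optimizer. The reported r_squared is the squared correlation
    of fitted and observed values (pseudo-R²).
    """
    xx, yy, n_dropped = _clean_xy(x, y, transform)
    if variance_covariate is None:
        vv = xx.copy()
    else:
        v_all = np.asarray(variance_covariate, dtype=float)
        if v_all.shape != np.asarray(x, dtype=float).shape:
            raise ValueError("variance covariate must align with x")
        ok = np.isfinite(np.asarray(x, dtype=float)) & np.isfinite(
            np.asarray(y, dtype=float)
        )
        if transform == "log":
            ok &= np.asarray(y, dtype=float) > 0
        vv = v_all[ok]
        if not np.isfinite(vv).all():
            raise ValueError("variance covariate contains missing values")
    if xx.size < 10:
        raise DegenerateFitError(
            f"need >= 10 complete pairs for GLS, have {xx.size}"
        )
    if np.ptp(xx) == 0 or np.ptp(yy) == 0:
        raise DegenerateFitError("zero predictor or response variance")

    X = np.column_stack([np.ones_like(xx), xx])
    v_scale = np.ptp(vv)
    if v_scale == 0:
        raise DegenerateFitError("variance covariate is constant")

    def neg_ll(delta: float) -> float:
        ll, _, _ = _varexp_profile_loglik(delta, X, yy, vv)
        return -ll

    bound = 50.0 / v_scale  # |delta * range(v)| <= 50: ample, keeps exp finite
    opt = minimize_scalar(neg_ll, bounds=(-bound, bound), method="bounded",
                          options={"xatol": 1e-8})
    if not opt.success or not np.isfinite(opt.fun):
        raise ConvergenceError(
            f"varExp profile optimization failed at delta={opt.x:.6g}, "
            f"objective={opt.fun:.6g}"
        )
    delta = float(opt.x)
    ll, beta, _ = _varexp_profile_loglik(delta, X, yy, vv)
    fitted = X @ beta
    r = np.corrcoef(fitted, yy)[0, 1]
    return FitResult(
        model="gls-varexp",
        transform=transform,
        coefficients=tuple(float(b) for b in beta),
        r_squared=float(r**2),
        n_used=int(xx.size),
        n_dropped=n_dropped,
        delta=delta,
        loglik=float(ll),
    )


@dataclass
class VarianceComponents:
    """Relative variance (%) of a response attributed to three nested design
    factors and the residual. Percentages are nonnegative and sum to 100."""

    percent: dict[str, float]
    variances: dict[str, float]
    factors: tuple[str, str, str]

    def to_text(self) -> str:
        lines = [f"{k}\t{v:.4f}" for k, v in self.percent.items()]
        return "\n".join(lines) + "\n"


def variance_components(
    results: pd.DataFrame,
    value: str = "r2",
    factors: tuple[str, str, str] = ("scale", "pool_size", "richness_range"),
) -> VarianceComponents:
    """Nested variance components of ``value`` across a balanced design.

    Factors are treated as hierarchically nested (outermost first), matching
    a random-effect nesting of scale / pool size / richness range, with
    replicates inside the innermost cell. Estimation is by balanced-design
    expected mean squares (method of moments); negative estimates are
    truncated to zero before normalizing to percentages.
    """
    fA, fB, fC = factors
    df = results[[fA, fB, fC, value]].dropna()
    if df.empty:
        raise DegenerateFitError("no usable rows")
    y = df[value].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise DegenerateFitError("response has zero variance")

    cell_counts = df.groupby([fA, fB, fC], observed=True)[value].count()
    n = int(cell_counts.iloc[0])
    a = df[fA].nunique()
    b_counts = df.groupby(fA, observed=True)[fB].nunique()
    c_counts = df.groupby([fA, fB], observed=True)[fC].nunique()
    b, c = int(b_counts.iloc[0]), int(c_counts.iloc[0])
    balanced = (
        cell_counts.eq(n).all()
        and b_counts.eq(b).all()
        and c_counts.eq(c).all()
        and len(cell_counts) == a * b * c
    )
    if not balanced:
        raise ValueError(
            "design is unbalanced; drop cells to a balanced subset before "
            "computing nested variance components"
        )
    if n < 2:
        raise ValueError("need >= 2 replicates per innermost cell")

    grand = y.mean()
    mean_A = df.groupby(fA, observed=True)[value].mean()
    mean_AB = df.groupby([fA, fB], observed=True)[value].mean()
    mean_ABC = df.groupby([fA, fB, fC], observed=True)[value].mean()

    ss_a = b * c * n * float(((mean_A - grand) ** 2).sum())
    ss_b = c * n * float(
        ((mean_AB - mean_A.reindex(mean_AB.index.get_level_values(0)).to_numpy()) ** 2).sum()
    )
    ss_c = n * float(
        (
            (
                mean_ABC
                - mean_AB.reindex(
                    mean_ABC.index.droplevel(2)
                ).to_numpy()
            )
            ** 2
        ).sum()
    )
    cell_of_row = df.set_index([fA, fB, fC]).index
    ss_e = float(((y - mean_ABC.reindex(cell_of_row).to_numpy()) ** 2).sum())

    ms_a = ss_a / (a - 1)
    ms_b = ss_b / (a * (b - 1)) if b > 1 else 0.0
    ms_c = ss_c / (a * b * (c - 1)) if c > 1 else 0.0
    ms_e = ss_e / (a * b * c * (n - 1))

    var_e = ms_e
    var_c = max((ms_c - ms_e) / n, 0.0) if c > 1 else 0.0
    var_b = max((ms_b - ms_c) / (c * n), 0.0) if b > 1 else 0.0
    var_a = max((ms_a - ms_b) / (b * c * n), 0.0) if a > 1 else 0.0

    variances = {fA: var_a, fB: var_b, fC: var_c, "residual": var_e}
    total = sum(variances.values())
    if total <= 0:
        raise DegenerateFitError("all variance estimates are zero")
    percent = {k: 100.0 * v / total for k, v in variances.items()}
    return VarianceComponents(percent=percent, variances=variances, factors=factors)
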