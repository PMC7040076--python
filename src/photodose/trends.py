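"""Trend and inference layer.

Three tools used to relate seasonal trait trends to irradiance:

* Local regression (loess) with tricube weights, local degree 2 by
  default, and pointwise 95% confidence intervals from the equivalent
  kernel: at each evaluation point the fit is a linear functional
  l(x₀)'y, so SE(x₀) = σ̂·‖l(x₀)‖ with σ̂² taken from the residuals using
  the trace-based degrees of freedom δ₁ = n − 2·tr(L) + tr(L'L).
  Two trends differ where their 95% bands fail to overlap.

* Pearson correlation with the t test on n − 2 degrees of freedom and
  the conventional significance brackets (* p < 0.05, ** p ≤ 0.01,
  *** p ≤ 0.001).

* Feasible GLS with a compound-symmetry (CS) correlation structure
  within groups and optionally heteroscedastic residual SDs across
  strata, estimated by iterated moment updates with a likelihood
  safeguard.  AIC-based selection across candidate structures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Loess
# ---------------------------------------------------------------------------

@dataclass
class LoessFit:
    grid: np.ndarray
    fitted: np.ndarray
    se: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    span: float
    degree: int
    df_resid: float
    sigma: float


def _loess_row(x: np.ndarray, x0: float, span: float, degree: int) -> np.ndarray:
    """Equivalent-kernel row l(x0): fit at x0 equals l(x0) @ y."""
    n = x.size
    d = np.abs(x - x0)
    if span <= 1.0:
        q = int(np.ceil(span * n))
        h = np.sort(d)[min(q, n) - 1]
    else:
        h = span * d.max()
    if h <= 0:
        # all retained points coincide with x0
        h = 1.0
    w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
    active = w > 0
    if active.sum() < degree + 2:
        raise ValueError(
            f"loess: only {int(active.sum())} points with positive weight at "
            f"x0={x0:g}; need at least degree + 2 = {degree + 2} "
            f"(increase the span)"
        )
    # local polynomial basis in (x - x0)
    B = (x[:, None] - x0) ** np.arange(degree + 1)[None, :]
    WB = w[:, None] * B
    # l = e1' (B'WB)^-1 B'W
    M = B.T @ WB
    try:
        first_row = np.linalg.solve(M, WB.T)[0]
    except np.linalg.LinAlgError:
        first_row = (np.linalg.pinv(M) @ WB.T)[0]
    return first_row


def loess_fit(x, y, span: float = 1.0, degree: int = 2, grid=None,
              level: float = 0.95) -> LoessFit:
    """Local polynomial regression with pointwise confidence intervals.

    ``span`` (α) ≤ 1 selects the ⌈α·n⌉ nearest points; α > 1 uses every
    point with the bandwidth inflated to α times the largest distance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if span <= 0:
        raise ValueError("span must be > 0")
    if n < degree + 2:
        raise ValueError(f"need at least degree + 2 = {degree + 2} points")
    if grid is None:
        grid = np.arange(np.floor(x.min()), np.floor(x.max()) + 1.0)
    grid = np.asarray(grid, dtype=float)

    # smoother matrix on the data points, for residual df
    L = np.vstack([_loess_row(x, xi, span, degree) for xi in x])
    fitted_data = L @ y
    resid = y - fitted_data
    df_resid = n - 2.0 * np.trace(L) + np.trace(L.T @ L)
    df_resid = max(df_resid, 1e-8)
    sigma2 = float(resid @ resid) / df_resid
    sigma = float(np.sqrt(max(sigma2, 0.0)))

    rows = np.vstack([_loess_row(x, g, span, degree) for g in grid])
    fitted = rows @ y
    se = sigma * np.sqrt((rows ** 2).sum(axis=1))
    tcrit = float(stats.t.ppf(0.5 + level / 2.0, df_resid))
    return LoessFit(
        grid=grid, fitted=fitted, se=se,
        ci_lower=fitted - tcrit * se, ci_upper=fitted + tcrit * se,
        span=span, degree=degree, df_resid=float(df_resid), sigma=sigma,
    )


def ci_overlap(fit_a: LoessFit, fit_b: LoessFit) -> dict:
    """Where do two trends' 95% bands fail to overlap?

    Non-overlap at x iff lowerA(x) > upperB(x) or lowerB(x) > upperA(x)
    (strict inequalities).  Returns per-grid-point flags and contiguous
    non-overlap runs as closed grid intervals.
    """
    if fit_a.grid.shape != fit_b.grid.shape or not np.array_equal(fit_a.grid, fit_b.grid):
        raise ValueError("ci_overlap requires both fits on the same grid")
    non = (fit_a.ci_lower > fit_b.ci_upper) | (fit_b.ci_lower > fit_a.ci_upper)
    intervals = []
    start = None
    for i, flag in enumerate(non):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            intervals.append((float(fit_a.grid[start]), float(fit_a.grid[i - 1])))
            start = None
    if start is not None:
        intervals.append((float(fit_a.grid[start]), float(fit_a.grid[-1])))
    return {"grid": fit_a.grid, "non_overlap": non, "intervals": intervals}


# ---------------------------------------------------------------------------
# Pearson correlation with significance brackets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    r: float | None
    n: int
    t: float | None
    p: float | None
    bracket: str
    reason: str = ""


def significance_bracket(p: float) -> str:
    """Bracket thresholds: *** ≤ 0.001, ** ≤ 0.01, * < 0.05 (strict), ns."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def pearson_r_with_test(x, y) -> CorrelationResult:
    """Sample correlation with t = r√(n−2)/√(1−r²) and a two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("need at least 3 paired observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx <= 0 or syy <= 0:
        return CorrelationResult(None, n, None, None, "", reason="zero variance")
    r = float(xc @ yc) / np.sqrt(sxx * syy)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return CorrelationResult(r, n, np.inf if r > 0 else -np.inf, 0.0, "***")
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return CorrelationResult(r, n, float(t), p, significance_bracket(p))


def bracket_for_r(r: float, n: int) -> str:
    """Significance bracket implied by a correlation coefficient at size n."""
    t = abs(r) * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * float(stats.t.sf(t, n - 2))
    return significance_bracket(p)


# ---------------------------------------------------------------------------
# Feasible GLS with compound symmetry
# ---------------------------------------------------------------------------

@dataclass
class GlsFit:
    params: np.ndarray
    rho: float
    sigmas: dict
    loglik: float
    aic: float
    pseudo_r2: float
    n_iter: int
    converged: bool
    correlation: str
    variance: str
    n_params: int
    fitted: np.ndarray = field(repr=False, default=None)
    loglik_path: list = field(repr=False, default_factory=list)


def _cs_loglik_and_beta(y, X, group_codes, stratum_of_obs, sigma2_k, rho):
    """One GLS pass: β given (ρ, σ²_k), plus the Gaussian log-likelihood."""
    p = X.shape[1]
    A = np.zeros((p, p))
    b = np.zeros(p)
    n = y.size
    # accumulate X' Σ⁻¹ X and X' Σ⁻¹ y per group using the CS inverse:
    # Σ_g = σ²[(1−ρ)I + ρJ];  Σ⁻¹ = 1/(σ²(1−ρ)) [I − ρ/(1+(m−1)ρ) J]
    logdet = 0.0
    for g in np.unique(group_codes):
        idx = np.where(group_codes == g)[0]
        m = idx.size
        s2 = sigma2_k[stratum_of_obs[idx[0]]]
        Xg, yg = X[idx], y[idx]
        c1 = 1.0 / (s2 * (1.0 - rho)) if m > 1 else 1.0 / s2
        c2 = rho / (1.0 + (m - 1) * rho) if m > 1 else 0.0
        sx = Xg.sum(axis=0)
        sy = yg.sum()
        A += c1 * (Xg.T @ Xg - c2 * np.outer(sx, sx))
        b += c1 * (Xg.T @ yg - c2 * sx * sy)
        logdet += m * np.log(s2)
        if m > 1:
            logdet += (m - 1) * np.log(1.0 - rho) + np.log(1.0 + (m - 1) * rho)
    beta = np.linalg.solve(A, b)
    # quadratic form with the same inverse
    quad = 0.0
    r = y - X @ beta
    for g in np.unique(group_codes):
        idx = np.where(group_codes == g)[0]
        m = idx.size
        s2 = sigma2_k[stratum_of_obs[idx[0]]]
        rg = r[idx]
        c1 = 1.0 / (s2 * (1.0 - rho)) if m > 1 else 1.0 / s2
        c2 = rho / (1.0 + (m - 1) * rho) if m > 1 else 0.0
        quad += c1 * (rg @ rg - c2 * rg.sum() ** 2)
    loglik = -0.5 * (n * np.log(2.0 * np.pi) + logdet + quad)
    return beta, float(loglik)


def fit_gls_cs(y, X, groups, strata=None, correlation: str = "cs",
               variance: str = "by_stratum", max_iter: int = 100,
               tol: float = 1e-8, param_eps: float = 1e-6) -> GlsFit:
    """Feasible GLS with within-group compound symmetry.

    ``groups`` labels the correlated blocks (e.g. measurement points);
    ``strata`` labels residual-variance strata (e.g. DOY or stand); every
    group must lie within a single stratum.  ``correlation`` in
    {"none", "cs"}; ``variance`` in {"homoscedastic", "by_stratum"}.

    Estimation alternates a GLS solve for β with moment updates for σ²_k
    (stratum residual mean squares) and ρ (mean within-group residual
    cross-product over the pooled variance).  An update that would lower
    the Gaussian log-likelihood is rejected and iteration stops, so the
    likelihood path is non-decreasing by construction.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be n × p")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    groups = np.asarray(groups)
    n = y.size
    if strata is None or variance == "homoscedastic":
        strata = np.zeros(n, dtype=int)
    strata = np.asarray(strata)

    _, group_codes = np.unique(groups, return_inverse=True)
    stratum_labels, stratum_codes = np.unique(strata, return_inverse=True)
    for g in np.unique(group_codes):
        if np.unique(stratum_codes[group_codes == g]).size > 1:
            raise ValueError("each group must lie within a single stratum")

    group_sizes = np.bincount(group_codes)
    m_max = int(group_sizes.max())
    rho_lo = (-1.0 / (m_max - 1) + param_eps) if m_max > 1 else 0.0
    rho_hi = 1.0 - param_eps

    # OLS start
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rho = 0.0
    sigma2 = np.array([
        max(float(np.mean((y - X @ beta)[stratum_codes == k] ** 2)), 1e-12)
        for k in range(stratum_labels.size)
    ])

    use_cs = correlation == "cs"
    if correlation not in ("cs", "none"):
        raise ValueError("correlation must be 'cs' or 'none'")

    loglik_path = []
    beta, ll = _cs_loglik_and_beta(y, X, group_codes, stratum_codes, sigma2, rho)
    loglik_path.append(ll)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        resid = y - X @ beta
        new_sigma2 = np.array([
            max(float(np.mean(resid[stratum_codes == k] ** 2)), 1e-12)
            for k in range(stratum_labels.size)
        ])
        if use_cs:
            e = resid / np.sqrt(new_sigma2[stratum_codes])
            num = 0.0
            den_pairs = 0
            for g in np.unique(group_codes):
                eg = e[group_codes == g]
                m = eg.size
                if m > 1:
                    num += eg.sum() ** 2 - eg @ eg
                    den_pairs += m * (m - 1)
            pooled = float(np.mean(e ** 2))
            new_rho = (num / den_pairs / pooled) if den_pairs and pooled > 0 else 0.0
            clipped = float(np.clip(new_rho, rho_lo, rho_hi))
            if clipped != new_rho:
                logger.info("GLS: rho estimate %.4f clipped into (%.4f, %.4f)",
                            new_rho, rho_lo, rho_hi)
            new_rho = clipped
        else:
            new_rho = 0.0
        new_beta, new_ll = _cs_loglik_and_beta(
            y, X, group_codes, stratum_codes, new_sigma2, new_rho
        )
        if new_ll < ll - 1e-10:
            logger.debug("GLS: update would lower the log-likelihood; stopping")
            converged = True
            break
        delta = max(
            float(np.max(np.abs(new_beta - beta))),
            abs(new_rho - rho),
            float(np.max(np.abs(np.sqrt(new_sigma2) - np.sqrt(sigma2)))),
        )
        beta, rho, sigma2, ll = new_beta, new_rho, new_sigma2, new_ll
        loglik_path.append(ll)
        if delta < tol:
            converged = True
            break

    fitted = X @ beta
    var_fit = np.var(fitted)
    pseudo_r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2) if var_fit > 0 else 0.0
    k_params = X.shape[1] + stratum_labels.size + (1 if use_cs else 0)
    aic = -2.0 * ll + 2.0 * k_params
    sigmas = {lab: float(np.sqrt(s2)) for lab, s2 in zip(stratum_labels, sigma2)}
    return GlsFit(
        params=beta, rho=float(rho), sigmas=sigmas, loglik=float(ll),
        aic=float(aic), pseudo_r2=pseudo_r2, n_iter=it, converged=converged,
        correlation=correlation, variance=variance, n_params=k_params,
        fitted=fitted, loglik_path=loglik_path,
    )


DEFAULT_STRUCTURES = (
    ("none", "homoscedastic"),
    ("cs", "homoscedastic"),
    ("cs", "by_stratum"),
)


def select_model(y, X, groups, strata=None, structures=DEFAULT_STRUCTURES):
    """Fit each candidate (correlation, variance) structure; lowest AIC wins.

    Ties (within 1e-9) break toward fewer parameters.  Candidates that
    fail to fit are excluded with a log entry.  Returns ``(best, fits)``
    where ``fits`` maps structure tuples to :class:`GlsFit`.
    """
    if len(structures) < 1:
        raise ValueError("need at least one candidate structure")
    fits = {}
    for corr, var in structures:
        try:
            fits[(corr, var)] = fit_gls_cs(y, X, groups, strata,
                                           correlation=corr, variance=var)
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("structure (%s, %s) excluded: %s", corr, var, exc)
    if not fits:
        raise ValueError("no candidate structure could be fitted")
    best = min(fits.values(), key=lambda f: (round(f.aic / 1e-9) * 1e-9, f.n_params))
    return best, fits
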