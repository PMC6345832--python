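"""Structure-function correlation statistics.

Partial correlations with covariates (residualization against an
intercept plus the covariates), Steiger's test for two dependent
correlations sharing one variable, Bonferroni thresholds, and the
minimum Pearson correlation detectable at a given sample size, alpha and
power. The power analysis solves for the smallest population correlation
rho such that the two-sided test of rho = 0 (critical r from the exact t
transform at df = n - 2) reaches the target power; the sampling model of
r is, by default, exact integration of its density under a bivariate
normal, with Fisher-z approximations (bias-corrected or raw) as faster
alternatives.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import integrate, optimize, special, stats

from .behavior import sd_outlier_mask
from .containers import AssociationResult

__all__ = [
    "partial_correlation",
    "compare_dependent_correlations",
    "min_detectable_r",
    "correlation_power",
    "critical_r",
    "bonferroni_threshold",
    "run_association_battery",
]

log = logging.getLogger(__name__)


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    alpha_corrected: float = 0.05,
    x_name: str = "x",
    y_name: str = "y",
    covariate_names: tuple = (),
    n_excluded: int = 0,
) -> AssociationResult:
    """Pearson correlation of x and y after removing the covariates.

    Both variables are residualized by least squares against an intercept
    plus the covariate columns; with no covariates this reduces to the
    plain Pearson correlation. The two-sided p comes from
    t = r * sqrt(df / (1 - r^2)) with df = n - 2 - #covariates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must have equal length")
    if covariates is None or (np.size(covariates) == 0):
        z = np.empty((n, 0))
    else:
        z = np.asarray(covariates, dtype=float)
        if z.ndim == 1:
            z = z[:, None]
        if z.shape[0] != n:
            raise ValueError("covariates must have one row per observation")
    k = z.shape[1]
    if n < k + 4:
        raise ValueError(f"need at least {k + 4} observations for {k} covariates")
    design = np.column_stack([np.ones(n), z])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError("collinear covariates: design matrix is rank-deficient")
    beta, *_ = np.linalg.lstsq(design, np.column_stack([x, y]), rcond=None)
    resid = np.column_stack([x, y]) - design @ beta
    sx, sy = resid.std(axis=0)
    if sx <= 1e-10 * max(x.std(), 1e-30) or sy <= 1e-10 * max(y.std(), 1e-30):
        raise ValueError("constant variable after residualization; correlation undefined")
    r = float((resid[:, 0] @ resid[:, 1]) / (n * sx * sy))
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 2 - k
    covariate_names = tuple(covariate_names)
    if len(covariate_names) != k:
        covariate_names = tuple(f"cov{i}" for i in range(k))
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1 - r**2))
        p = float(2 * stats.t.sf(abs(t), df))
    return AssociationResult(
        x_name=x_name,
        y_name=y_name,
        covariate_names=tuple(covariate_names),
        r_partial=r,
        df=df,
        p=p,
        n_used=n,
        alpha_corrected=alpha_corrected,
        significant=bool(p < alpha_corrected),
        n_excluded=n_excluded,
    )


def compare_dependent_correlations(
    r_jk: float, r_jh: float, r_kh: float, n: int, variant: str = "steiger"
) -> dict:
    """Compare two dependent correlations sharing variable j.

    ``r_jk`` and ``r_jh`` are the two correlations under comparison,
    ``r_kh`` the correlation between their non-shared variables. The
    default is Steiger's Z on Fisher-transformed correlations with the
    Dunn-Clark covariance correction (evaluated at the pooled
    correlation); ``variant="williams"`` gives the Williams-Hotelling t.
    Returns ``{"z": ..., "p": ...}`` (for the Williams variant the
    statistic is still reported under "z", with "df" added).
    """
    for name, r in (("r_jk", r_jk), ("r_jh", r_jh), ("r_kh", r_kh)):
        if not np.isfinite(r) or abs(r) >= 1:
            raise ValueError(f"{name} must lie strictly inside (-1, 1)")
    if n < 10:
        raise ValueError("need n >= 10")
    rmat = np.array([[1, r_jk, r_jh], [r_jk, 1, r_kh], [r_jh, r_kh, 1]])
    if np.linalg.det(rmat) <= 0:
        raise ValueError("impossible correlation triple (non-PSD 3x3 matrix)")
    if variant == "steiger":
        rbar = (r_jk + r_jh) / 2
        cov = (r_kh * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r_kh**2)) / (
            1 - rbar**2
        ) ** 2
        z = (np.arctanh(r_jk) - np.arctanh(r_jh)) * np.sqrt((n - 3) / (2 * (1 - cov)))
        return {"z": float(z), "p": float(2 * stats.norm.sf(abs(z)))}
    if variant == "williams":
        det = float(np.linalg.det(rmat))
        rbar = (r_jk + r_jh) / 2
        t = (r_jk - r_jh) * np.sqrt(
            (n - 1) * (1 + r_kh)
            / (2 * det * (n - 1) / (n - 3) + rbar**2 * (1 - r_kh) ** 3)
        )
        return {"z": float(t), "df": n - 3, "p": float(2 * stats.t.sf(abs(t), n - 3))}
    raise ValueError(f"unknown variant {variant!r}")


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Two-sided critical sample correlation via the exact t transform."""
    t = stats.t.ppf(1 - alpha / 2, n - 2)
    return float(t / np.sqrt(t**2 + n - 2))


def _r_log_density(r, rho, n):
    nu = n - 1
    return (
        np.log(nu - 1)
        + special.gammaln(nu)
        - 0.5 * np.log(2 * np.pi)
        - special.gammaln(nu + 0.5)
        + (nu / 2) * np.log1p(-(rho**2))
        + ((nu - 3) / 2) * np.log1p(-(r**2))
        - (nu - 0.5) * np.log1p(-rho * r)
    )


def _r_density(r, rho, n):
    """Density of the sample correlation under a bivariate normal."""
    return np.exp(_r_log_density(r, rho, n)) * special.hyp2f1(
        0.5, 0.5, n - 0.5, (rho * r + 1) / 2
    )


def correlation_power(
    rho: float, n: int, alpha: float = 0.05, method: str = "exact"
) -> float:
    """Power of the two-sided test of rho = 0 at true correlation rho.

    ``method``: "exact" integrates the sample-correlation density over
    the rejection region; "fisher-bias" uses the Fisher-z normal
    approximation with mean atanh(rho) + rho / (2 (n - 1)) and SD
    1 / sqrt(n - 3); "fisher" omits the bias term.
    """
    rc = critical_r(n, alpha)
    if method == "exact":
        lo, _ = integrate.quad(_r_density, -1, -rc, args=(rho, n))
        hi, _ = integrate.quad(_r_density, rc, 1, args=(rho, n))
        return float(lo + hi)
    if method in ("fisher", "fisher-bias"):
        zc = np.arctanh(rc)
        mu = np.arctanh(rho) + (rho / (2 * (n - 1)) if method == "fisher-bias" else 0.0)
        sd = 1 / np.sqrt(n - 3)
        return float(stats.norm.sf((zc - mu) / sd) + stats.norm.cdf((-zc - mu) / sd))
    raise ValueError(f"unknown method {method!r}")


def min_detectable_r(
    n: int,
    alpha: float = 0.05,
    power: float = 0.80,
    tails: int = 2,
    method: str = "exact",
) -> float:
    """Smallest population correlation detectable with the given power.

    Solves power(rho) = target by bisection to 1e-6 for the two-sided
    test of H0: rho = 0 at level ``alpha`` with ``n`` bivariate-normal
    observations. The default "exact" sampling model reproduces the
    classical G*Power result (0.478 for n = 31, alpha = 0.05, power
    0.80); "fisher-bias" gives 0.479 and "fisher" 0.486 there.
    """
    if n < 5:
        raise ValueError("need n >= 5")
    if tails != 2:
        raise ValueError("only the two-sided test is implemented")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0, 1)")
    if alpha >= power:
        raise ValueError("requested power must exceed the test size")
    f = lambda rho, m: correlation_power(rho, n, alpha, m) - power
    # the Fisher-z power curve is well-behaved over the whole (0, 1) range;
    # its root brackets the exact solution, whose density integral is only
    # evaluated where it is numerically benign
    r_fisher = optimize.brentq(lambda r: f(r, "fisher-bias"), 1e-9, 1 - 1e-9, xtol=1e-8)
    if method == "fisher-bias":
        return float(r_fisher)
    lo = max(1e-9, r_fisher - 0.2)
    hi = min(1 - 1e-6, r_fisher + 0.2)
    return float(optimize.brentq(lambda r: f(r, method), lo, hi, xtol=1e-6))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """alpha / m at full precision (display rounding is the caller's job)."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    return alpha / m


def run_association_battery(
    measures: pd.DataFrame,
    plan: list,
    alpha: float = 0.05,
    outlier_k: float = 3.0,
) -> list:
    """Run a list of partial-correlation tests with per-family Bonferroni
    thresholds and a single-pass 3-SD exclusion per column.

    Each plan entry is ``{"x": col, "y": col, "covariates": [cols],
    "family_size": m}``. Exclusion flags are computed per column over all
    subjects; a test uses the rows where every involved column is both
    included and non-missing (pairwise-complete deletion). Duplicated
    plan entries are computed again and flagged in the log.
    """
    results = []
    seen = set()
    include_by_col = {}

    def included(col):
        if col not in measures.columns:
            raise KeyError(col)
        if col not in include_by_col:
            vals = measures[col].to_numpy(dtype=float)
            ok = np.isfinite(vals)
            flags = np.zeros(len(vals), dtype=bool)
            if ok.sum() >= 3:
                flags[ok] = sd_outlier_mask(vals[ok], k=outlier_k)
            else:
                flags[ok] = True
            include_by_col[col] = flags
        return include_by_col[col]

    for entry in plan:
        try:
            xcol, ycol = entry["x"], entry["y"]
            covs = list(entry.get("covariates", []))
            m = int(entry.get("family_size", 1))
            key = (xcol, ycol, tuple(covs), m)
            if key in seen:
                log.warning("duplicated test in plan: %s ~ %s | %s", xcol, ycol, covs)
            seen.add(key)
            rows = np.ones(len(measures), dtype=bool)
            for col in [xcol, ycol] + covs:
                rows &= included(col)
            n_excl = int(len(measures) - rows.sum())
            if n_excl:
                log.info("%s ~ %s: %d subjects excluded", xcol, ycol, n_excl)
            sub = measures.loc[rows]
            results.append(
                partial_correlation(
                    sub[xcol].to_numpy(dtype=float),
                    sub[ycol].to_numpy(dtype=float),
                    sub[covs].to_numpy(dtype=float) if covs else None,
                    alpha_corrected=bonferroni_threshold(alpha, m),
                    x_name=xcol,
                    y_name=ycol,
                    covariate_names=tuple(covs),
                    n_excluded=n_excl,
                )
            )
        except KeyError as e:
            from .errors import ConfigurationError

            raise ConfigurationError(f"association plan names unknown column {e}") from e
    return results
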