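"""Phenotypic, twin-pair and polyserial correlations with 95% CIs.

Twin-pair correlations are estimated by maximum likelihood under a
saturated bivariate-normal pair model with means and variances equal across
twin order (the double-entry / intraclass convention: which twin is "1" is
arbitrary), with likelihood-based confidence intervals — the same framework
the structural models use, and the reason printed intervals can be
asymmetric.  The polyserial estimator recovers the latent bivariate-normal
correlation between a continuous variable and an ordinal variable whose
thresholds are estimated from its margins.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import io as tio

__all__ = [
    "CorrelationEstimate",
    "CorrelationMatrix",
    "cross_interval_correlations",
    "twin_pair_correlation",
    "polyserial_correlation",
]

_CHI2_95 = float(stats.chi2.ppf(0.95, 1))


@dataclass(frozen=True)
class CorrelationEstimate:
    estimate: float
    lower95: float
    upper95: float
    n_effective: int
    method: str

    def __post_init__(self):
        if not (self.lower95 - 1e-9 <= self.estimate <= self.upper95 + 1e-9):
            raise ValueError("confidence bounds must bracket the estimate")

    def as_tuple(self):
        return (self.estimate, self.lower95, self.upper95)


def _pearson_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    if n <= 3 or abs(r) >= 1.0:
        return (-1.0, 1.0) if abs(r) < 1.0 else (r, r)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zc = stats.norm.ppf(0.5 + level / 2)
    return float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se))


@dataclass
class CorrelationMatrix:
    """T x T matrix of correlation estimates with per-cell CIs."""

    estimates: pd.DataFrame
    cells: dict[tuple[str, str], CorrelationEstimate]

    def cell(self, v1: str, v2: str) -> CorrelationEstimate:
        key = (v1, v2) if (v1, v2) in self.cells else (v2, v1)
        return self.cells[key]


def cross_interval_correlations(
    wide: pd.DataFrame, method: str = "pearson-pairwise", n_bins: int = 5
) -> CorrelationMatrix:
    """Correlations between interval variables, both twins as individuals.

    Pairwise-complete observations; ``method`` is ``"pearson-pairwise"`` or
    ``"polyserial"`` (the column variable discretized into ``n_bins``
    equal-count categories).  All-missing variable pairs yield NaN cells.
    """
    var_names = tio.wide_variable_names(wide)
    persons = pd.concat(
        [
            wide[[f"{v}_a" for v in var_names]].set_axis(var_names, axis=1),
            wide[[f"{v}_b" for v in var_names]].set_axis(var_names, axis=1),
        ],
        ignore_index=True,
    )
    est = pd.DataFrame(np.eye(len(var_names)), index=var_names, columns=var_names)
    cells: dict[tuple[str, str], CorrelationEstimate] = {}
    for i, v1 in enumerate(var_names):
        cells[(v1, v1)] = CorrelationEstimate(1.0, 1.0, 1.0, int(persons[v1].notna().sum()), method)
        for v2 in var_names[i + 1 :]:
            sub = persons[[v1, v2]].dropna()
            if len(sub) < 3:
                est.loc[v1, v2] = est.loc[v2, v1] = np.nan
                cells[(v1, v2)] = CorrelationEstimate(np.nan, np.nan, np.nan, len(sub), method)
                warnings.warn(f"fewer than 3 complete observations for ({v1}, {v2})")
                continue
            x, y = sub[v1].to_numpy(), sub[v2].to_numpy()
            if method == "pearson-pairwise":
                r = float(np.corrcoef(x, y)[0, 1])
                lo, hi = _pearson_ci(r, len(sub))
                cell = CorrelationEstimate(r, lo, hi, len(sub), method)
            elif method == "polyserial":
                codes = pd.qcut(y, q=min(n_bins, len(sub)), labels=False, duplicates="drop")
                cell = polyserial_correlation(x, codes)
            else:
                raise ValueError(f"unknown method {method!r}")
            est.loc[v1, v2] = est.loc[v2, v1] = cell.estimate
            cells[(v1, v2)] = cell
    return CorrelationMatrix(estimates=est, cells=cells)


# ---------------------------------------------------------------------------
# Twin-pair (intraclass) correlation by ML with profile-likelihood CI
# ---------------------------------------------------------------------------


def twin_pair_correlation(
    wide: pd.DataFrame, variable: str, zygosity: str, level: float = 0.95
) -> CorrelationEstimate:
    """ML twin-pair correlation for one variable within one zygosity group.

    Equal means/variances across twin order make the estimate invariant to
    within-pair relabeling.  The CI is the profile-likelihood interval: for
    fixed r, the mean and variance maximizers have closed forms, giving a
    one-dimensional profile in r.
    """
    sub = wide[wide["zygosity"] == zygosity][[f"{variable}_a", f"{variable}_b"]].dropna()
    n = len(sub)
    if n < 3:
        raise ValueError(
            f"need at least 3 complete {zygosity} pairs for {variable!r}, got {n}"
        )
    x1 = sub.iloc[:, 0].to_numpy(float)
    x2 = sub.iloc[:, 1].to_numpy(float)
    mu = float(np.mean(np.concatenate([x1, x2])))  # ML mean for any r
    d1, d2 = x1 - mu, x2 - mu
    q = float(d1 @ d1 + d2 @ d2)
    p = float(d1 @ d2)
    if q <= 0:
        return CorrelationEstimate(1.0, 1.0, 1.0, n, "ml-bivariate")

    # Profiling sigma^2 out for fixed r has the closed form
    # sigma2_hat(r) = (q - 2 r p) / (2 n (1 - r^2)), leaving a 1-D profile.
    def m2ll(r: float) -> float:
        s2 = (q - 2.0 * r * p) / (2.0 * n * (1.0 - r * r))
        if s2 <= 0:
            return np.inf
        quad = (q - 2.0 * r * p) / (s2 * (1.0 - r * r))
        return n * (2.0 * np.log(2 * np.pi) + np.log(s2 * s2 * (1.0 - r * r))) + quad

    res = optimize.minimize_scalar(m2ll, bounds=(-0.999, 0.999), method="bounded")
    r_hat = float(res.x)
    m2_min = float(res.fun)
    # perfectly (anti)correlated pairs push the likelihood to the boundary
    if abs(r_hat) > 0.998 and m2ll(np.sign(r_hat) * 0.99999) < m2_min:
        sign = np.sign(r_hat)
        m2_min = m2ll(sign * 0.99999)
        bound = float(sign)
        crit = float(stats.chi2.ppf(level, 1))

        def crossing(r):
            return m2ll(r) - (m2_min + crit)

        inner = float(optimize.brentq(crossing, -0.999999 * sign if sign > 0 else sign * 0.999999, sign * 0.99999)) if crossing(-sign * 0.999999) > 0 else -bound
        lo, hi = (inner, 1.0) if sign > 0 else (-1.0, inner)
        return CorrelationEstimate(bound, lo, hi, n, "ml-bivariate")
    crit = float(stats.chi2.ppf(level, 1))

    def crossing(r):
        return m2ll(r) - (m2_min + crit)

    lo = -1.0 + 1e-6
    hi = 1.0 - 1e-6
    lower = float(optimize.brentq(crossing, lo, r_hat)) if crossing(lo) > 0 else -1.0
    upper = float(optimize.brentq(crossing, r_hat, hi)) if crossing(hi) > 0 else 1.0
    return CorrelationEstimate(r_hat, lower, upper, n, "ml-bivariate")


# ---------------------------------------------------------------------------
# Polyserial correlation
# ---------------------------------------------------------------------------


def polyserial_minus2ll(
    rho: float, z: np.ndarray, codes: np.ndarray, thresholds: np.ndarray
) -> float:
    """-2 log-likelihood of the latent-correlation part of the polyserial model.

    ``z`` is the standardized continuous variable, ``codes`` the 0-based
    ordinal category per observation and ``thresholds`` the K-1 interior
    thresholds.  (The marginal normal density of the continuous variable
    does not depend on rho and is omitted.)
    """
    if abs(rho) >= 1.0:
        return np.inf
    w = np.sqrt(1.0 - rho * rho)
    tau = np.concatenate([[-np.inf], thresholds, [np.inf]])
    upper = (tau[codes + 1] - rho * z) / w
    lower = (tau[codes] - rho * z) / w
    prob = stats.norm.cdf(upper) - stats.norm.cdf(lower)
    if np.any(prob <= 0):
        return np.inf
    return -2.0 * float(np.sum(np.log(prob)))


def polyserial_correlation(
    continuous, ordinal, level: float = 0.95
) -> CorrelationEstimate:
    """ML polyserial correlation with thresholds from the ordinal margins.

    Returns the latent bivariate-normal correlation, not the attenuated
    product-moment correlation of the observed variables.  Empty ordinal
    categories are dropped with a warning.  The CI is profile-likelihood,
    clipped at +/-1.
    """
    x = np.asarray(continuous, dtype=float)
    y = np.asarray(ordinal)
    ok = np.isfinite(x) & ~pd.isna(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 5:
        raise ValueError(f"need at least 5 complete observations, got {n}")
    if np.std(x) == 0:
        raise ValueError("continuous variable is degenerate (zero variance)")
    levels, codes = np.unique(y, return_inverse=True)
    k = len(levels)
    if k < 2:
        raise ValueError("ordinal variable needs at least 2 observed categories")
    if np.issubdtype(levels.dtype, np.integer) and levels.max() - levels.min() + 1 > k:
        warnings.warn(
            "ordinal coding has gaps; empty categories were dropped and "
            "thresholds re-estimated from the observed margins"
        )
    counts = np.bincount(codes, minlength=k)
    cum = np.cumsum(counts)[:-1] / n
    thresholds = stats.norm.ppf(cum)
    z = (x - x.mean()) / x.std()

    res = optimize.minimize_scalar(
        polyserial_minus2ll,
        bounds=(-0.999, 0.999),
        method="bounded",
        args=(z, codes, thresholds),
    )
    rho_hat = float(res.x)
    m2_min = float(res.fun)
    crit = float(stats.chi2.ppf(level, 1))

    def crossing(r):
        return polyserial_minus2ll(r, z, codes, thresholds) - (m2_min + crit)

    lo, hi = -0.9999, 0.9999
    lower = float(optimize.brentq(crossing, lo, rho_hat)) if crossing(lo) > 0 else -1.0
    upper = float(optimize.brentq(crossing, rho_hat, hi)) if crossing(hi) > 0 else 1.0
    return CorrelationEstimate(rho_hat, lower, upper, n, "polyserial")
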