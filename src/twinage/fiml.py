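"""Twin-pair full-information maximum-likelihood (FIML) engine.

The unit of analysis is the twin pair.  With ``T`` phenotype variables per
person (here: predicted brain age at each chronological-age interval), a pair
contributes a ``2T``-vector.  A structural model maps a parameter vector to
within-person variance components ``Sigma_A`` (additive genetic), ``Sigma_C``
(shared environment) and ``Sigma_E`` (non-shared environment), each ``T x T``
and positive semi-definite by construction (path parameterization).  The
implied pair covariance for a zygosity group is the block matrix

    [[ Sigma_W,            r_A*Sigma_A + Sigma_C ],
     [ r_A*Sigma_A+Sigma_C, Sigma_W              ]]

with ``Sigma_W = Sigma_A + Sigma_C + Sigma_E`` and the additive-genetic
cross-twin correlation ``r_A = 1.0`` for monozygotic and ``0.5`` for dizygotic
pairs; shared environment is fully correlated within pairs in both groups and
non-shared environment is uncorrelated.

The raw-data likelihood sums, over pairs, the log multivariate-normal density
of each pair's *observed* sub-vector: rows/columns of missing entries are
deleted per pair, never the pair itself.  Pairs are grouped by missingness
pattern and summarized by sufficient statistics so that one likelihood
evaluation costs O(patterns * T^3) regardless of sample size.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "GENETIC_CORRELATION",
    "Parameter",
    "TwinModel",
    "PairData",
    "FitResult",
    "FimlError",
    "NonPositiveDefiniteError",
    "FitFailedError",
    "pair_covariance",
    "fiml_loglik",
    "fit",
]

log = logging.getLogger(__name__)

LOG_2PI = float(np.log(2.0 * np.pi))

#: Cross-twin additive-genetic correlation by zygosity: MZ pairs are
#: genetically identical, DZ pairs share on average half their segregating
#: genes.
GENETIC_CORRELATION: dict[str, float] = {"MZ": 1.0, "DZ": 0.5}


class FimlError(Exception):
    """Base class for likelihood-engine errors."""


class NonPositiveDefiniteError(FimlError):
    """An implied covariance matrix is not positive (semi-)definite."""

    def __init__(self, message: str, zygosity: str | None = None):
        super().__init__(message)
        self.zygosity = zygosity


class FitFailedError(FimlError):
    """Every optimizer start failed; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics: list[str]):
        super().__init__(message + "\n" + "\n".join(diagnostics))
        self.diagnostics = diagnostics


@dataclass(frozen=True)
class Parameter:
    """One scalar model parameter (a path coefficient, beta or mean)."""

    name: str
    start: float
    lower: float = -np.inf
    upper: float = np.inf
    free: bool = True


@dataclass
class TwinModel:
    """Declarative twin model: parameters -> implied moments.

    ``components(theta)`` returns the tuple ``(Sigma_A, Sigma_C, Sigma_E)``
    of within-person T x T component matrices for a *full* parameter vector
    ``theta`` (fixed parameters included at their fixed values).  Means are
    ``theta[mean_idx]``, one per variable, shared across twins and zygosity
    groups.  ``quantities`` maps names of derived scalar quantities (e.g. a
    standardized variance component) to functions of the full vector; they
    are the handles used for profile-likelihood confidence intervals.
    ``meta`` carries builder-specific structure (factor-loading indices etc.)
    used for standardization reports.
    """

    name: str
    n_vars: int
    params: tuple[Parameter, ...]
    components: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray, np.ndarray]]
    mean_idx: np.ndarray
    var_names: tuple[str, ...] = ()
    quantities: dict[str, Callable[[np.ndarray], float]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)
    #: optional hook mapping sample component moments (see ``sample_moments``)
    #: to parameter start values; used by ``fit`` for its first start point
    initializer: Callable[[dict], Mapping[str, float]] | None = None

    def __post_init__(self) -> None:
        if not self.var_names:
            self.var_names = tuple(f"t{i + 1}" for i in range(self.n_vars))
        if len(self.var_names) != self.n_vars:
            raise ValueError("var_names length must equal n_vars")

    # -- parameter bookkeeping -------------------------------------------
    @property
    def param_names(self) -> list[str]:
        return [p.name for p in self.params]

    @property
    def free_mask(self) -> np.ndarray:
        return np.array([p.free for p in self.params], dtype=bool)

    @property
    def free_names(self) -> list[str]:
        return [p.name for p in self.params if p.free]

    @property
    def n_free(self) -> int:
        return int(self.free_mask.sum())

    @property
    def start_full(self) -> np.ndarray:
        return np.array([p.start for p in self.params], dtype=float)

    @property
    def bounds_free(self) -> list[tuple[float, float]]:
        return [(p.lower, p.upper) for p in self.params if p.free]

    def full_vector(self, free_values: np.ndarray) -> np.ndarray:
        """Expand a free-parameter vector to the full vector."""
        theta = self.start_full
        theta[self.free_mask] = np.asarray(free_values, dtype=float)
        return theta

    def param_dict(self, theta: np.ndarray) -> dict[str, float]:
        return dict(zip(self.param_names, np.asarray(theta, dtype=float)))

    def vector_from(self, mapping: Mapping[str, float]) -> np.ndarray:
        """Full parameter vector from a name->value mapping.

        Unmentioned parameters keep their start (or fixed) values.
        """
        theta = self.start_full
        names = self.param_names
        for key, value in mapping.items():
            if key not in names:
                raise KeyError(f"unknown parameter {key!r} for model {self.name!r}")
            theta[names.index(key)] = float(value)
        return theta

    def means(self, theta: np.ndarray) -> np.ndarray:
        return np.asarray(theta, dtype=float)[self.mean_idx]

    def fix(self, assignments: Mapping[str, float]) -> "TwinModel":
        """Return a copy with the named parameters fixed at given values."""
        new_params = []
        names = set(assignments)
        for p in self.params:
            if p.name in assignments:
                new_params.append(
                    Parameter(p.name, float(assignments[p.name]), p.lower, p.upper, free=False)
                )
                names.discard(p.name)
            else:
                new_params.append(p)
        if names:
            raise KeyError(f"unknown parameters {sorted(names)} for model {self.name!r}")
        fixed_tags = ",".join(f"{k}={assignments[k]:g}" for k in sorted(assignments))
        return dataclasses.replace(
            self, name=f"{self.name}[{fixed_tags}]", params=tuple(new_params)
        )


def pair_covariance(model: TwinModel, theta: np.ndarray, zygosity: str) -> np.ndarray:
    """Implied 2T x 2T covariance of a twin pair's phenotype vector."""
    try:
        r_a = GENETIC_CORRELATION[zygosity]
    except KeyError:
        raise KeyError(f"unknown zygosity code {zygosity!r}; expected MZ or DZ") from None
    sigma_a, sigma_c, sigma_e = model.components(np.asarray(theta, dtype=float))
    within = sigma_a + sigma_c + sigma_e
    cross = r_a * sigma_a + sigma_c
    return np.block([[within, cross], [cross.T, within]])


# ---------------------------------------------------------------------------
# Data container: missingness-pattern groups with sufficient statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _PatternGroup:
    zygosity: str
    obs_idx: np.ndarray  # observed positions within the 2T vector
    n: int
    s: np.ndarray  # sum of observed sub-vectors
    scatter: np.ndarray  # sum of outer products x x^T


@dataclass(frozen=True)
class _PatternBatch:
    """Pattern groups of equal dimension stacked for batched linalg."""

    zygosity: str
    obs_idx: np.ndarray  # (k, d) observed positions per group
    n: np.ndarray  # (k,)
    s: np.ndarray  # (k, d)
    scatter: np.ndarray  # (k, d, d)


def _batch_groups(groups: Sequence[_PatternGroup]) -> tuple[_PatternBatch, ...]:
    batches = []
    keyed: dict[tuple[str, int], list[_PatternGroup]] = {}
    for g in groups:
        keyed.setdefault((g.zygosity, len(g.obs_idx)), []).append(g)
    for (zyg, _), gs in keyed.items():
        batches.append(
            _PatternBatch(
                zygosity=zyg,
                obs_idx=np.stack([g.obs_idx for g in gs]),
                n=np.array([g.n for g in gs], dtype=float),
                s=np.stack([g.s for g in gs]),
                scatter=np.stack([g.scatter for g in gs]),
            )
        )
    return tuple(batches)


@dataclass(frozen=True)
class PairData:
    """Wide twin data compiled for fast repeated likelihood evaluation."""

    n_vars: int
    var_names: tuple[str, ...]
    groups: tuple[_PatternGroup, ...]
    batches: tuple[_PatternBatch, ...]
    n_pairs: int
    n_obs: int

    @staticmethod
    def from_wide(wide: pd.DataFrame) -> "PairData":
        from .io import wide_variable_names  # local import to avoid cycle

        var_names = wide_variable_names(wide)
        t = len(var_names)
        cols = [f"{v}_a" for v in var_names] + [f"{v}_b" for v in var_names]
        groups: list[_PatternGroup] = []
        n_pairs = 0
        n_obs = 0
        for zyg in ("MZ", "DZ"):
            sub = wide.loc[wide["zygosity"] == zyg, cols]
            if sub.empty:
                continue
            x = sub.to_numpy(dtype=float)
            observed = ~np.isnan(x)
            if not observed.any(axis=1).all():
                bad = sub.index[~observed.any(axis=1)].tolist()
                raise ValueError(
                    f"{zyg} pairs with no observed phenotype at rows {bad}; "
                    "every pair must contribute at least one observation"
                )
            patterns, inverse = np.unique(observed, axis=0, return_inverse=True)
            for k, pat in enumerate(patterns):
                rows = x[inverse == k][:, pat]
                idx = np.flatnonzero(pat)
                groups.append(
                    _PatternGroup(
                        zygosity=zyg,
                        obs_idx=idx,
                        n=rows.shape[0],
                        s=rows.sum(axis=0),
                        scatter=rows.T @ rows,
                    )
                )
                n_obs += rows.size
            n_pairs += x.shape[0]
        if n_pairs == 0:
            raise ValueError("no MZ or DZ pairs in data")
        return PairData(
            n_vars=t,
            var_names=tuple(var_names),
            groups=tuple(groups),
            batches=_batch_groups(groups),
            n_pairs=n_pairs,
            n_obs=n_obs,
        )

    def observed_means(self) -> np.ndarray:
        """Per-variable mean over all observed entries (both twins pooled)."""
        t = self.n_vars
        tot = np.zeros(t)
        cnt = np.zeros(t)
        for g in self.groups:
            for pos, val in zip(g.obs_idx, g.s):
                tot[pos % t] += val
                cnt[pos % t] += g.n
        with np.errstate(invalid="ignore"):
            return np.where(cnt > 0, tot / np.maximum(cnt, 1), 0.0)

    def pooled_sd(self) -> float:
        """Rough pooled standard deviation of all observed entries."""
        n = 0
        s = 0.0
        ss = 0.0
        for g in self.groups:
            n += g.n * len(g.obs_idx)
            s += g.s.sum()
            ss += np.trace(g.scatter)
        if n < 2:
            return 1.0
        var = ss / n - (s / n) ** 2
        return float(np.sqrt(max(var, 1e-12)))


def _as_pairdata(data: pd.DataFrame | PairData) -> PairData:
    if isinstance(data, PairData):
        return data
    return PairData.from_wide(data)


def fiml_loglik(model: TwinModel, theta: np.ndarray, data: pd.DataFrame | PairData) -> float:
    """-2 log-likelihood of the raw twin-pair data under the model.

    Returns ``+inf`` (optimizer-safe) when an implied observed-pattern
    submatrix is not positive definite.
    """
    pdat = _as_pairdata(data)
    if pdat.n_vars != model.n_vars:
        raise ValueError(
            f"model has {model.n_vars} variables but data has {pdat.n_vars}"
        )
    theta = np.asarray(theta, dtype=float)
    mu_t = model.means(theta)
    mu_full = np.concatenate([mu_t, mu_t])
    sigma: dict[str, np.ndarray] = {}
    for zyg in ("MZ", "DZ"):
        sigma[zyg] = pair_covariance(model, theta, zyg)
    total = 0.0
    for b in pdat.batches:
        d = b.obs_idx.shape[1]
        sub = sigma[b.zygosity][b.obs_idx[:, :, None], b.obs_idx[:, None, :]]
        mu = mu_full[b.obs_idx]  # (k, d)
        try:
            chol = np.linalg.cholesky(sub)
            diag = np.diagonal(chol, axis1=1, axis2=2)
            if np.any(diag <= 0):
                return np.inf
            logdet = 2.0 * np.log(diag).sum(axis=1)
            rhs = np.concatenate([b.scatter, b.s[:, :, None], mu[:, :, None]], axis=2)
            z = np.linalg.solve(sub, rhs)
        except np.linalg.LinAlgError:
            log.debug("non-PD implied submatrix for %s (d=%d)", b.zygosity, d)
            return np.inf
        trace = np.einsum("kii->k", z[:, :, :d])
        mu_inv_s = np.einsum("kd,kd->k", mu, z[:, :, d])
        mu_inv_mu = np.einsum("kd,kd->k", mu, z[:, :, d + 1])
        total += float(
            np.sum(b.n * (d * LOG_2PI + logdet) + trace - 2.0 * mu_inv_s + b.n * mu_inv_mu)
        )
    return total


# ---------------------------------------------------------------------------
# Moment estimates used for informed optimizer starts
# ---------------------------------------------------------------------------


def sample_moments(pdat: PairData) -> dict | None:
    """Pairwise-complete moment estimates of the twin variance components.

    Returns per-variable means plus rough component matrices obtained from
    the classic identities ``X_MZ = A + C``, ``X_DZ = A/2 + C`` and
    ``W = A + C + E`` applied to pooled within- and cross-twin sample
    covariance blocks.  Returns ``None`` when a zygosity group is absent or
    too small for the contrast.  These are *start values only*; estimation
    is always by FIML.
    """
    t = pdat.n_vars
    blocks: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for zyg in ("MZ", "DZ"):
        groups = [g for g in pdat.groups if g.zygosity == zyg]
        if not groups or sum(g.n for g in groups) < 5:
            return None
        s2 = np.zeros((2 * t, 2 * t))
        n2 = np.zeros((2 * t, 2 * t))
        s1 = np.zeros(2 * t)
        n1 = np.zeros(2 * t)
        for g in groups:
            ix = np.ix_(g.obs_idx, g.obs_idx)
            s2[ix] += g.scatter
            n2[ix] += g.n
            s1[g.obs_idx] += g.s
            n1[g.obs_idx] += g.n
        mu = np.where(n1 > 0, s1 / np.maximum(n1, 1), 0.0)
        with np.errstate(invalid="ignore"):
            cov = np.where(n2 > 0, s2 / np.maximum(n2, 1), 0.0) - np.outer(mu, mu)
        within = 0.5 * (cov[:t, :t] + cov[t:, t:])
        cross = cov[:t, t:]
        cross = 0.5 * (cross + cross.T)
        blocks[zyg] = (within, cross)
    w = 0.5 * (blocks["MZ"][0] + blocks["DZ"][0])
    x_mz, x_dz = blocks["MZ"][1], blocks["DZ"][1]
    sigma_a = 2.0 * (x_mz - x_dz)
    sigma_c = 2.0 * x_dz - x_mz
    sigma_e = w - x_mz
    return {
        "mean": (
            pdat.observed_means()
        ),
        "W": w,
        "A": sigma_a,
        "C": sigma_c,
        "E": sigma_e,
    }


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Outcome of a FIML fit."""

    model: TwinModel
    params: np.ndarray  # full parameter vector at the optimum
    minus2lnL: float
    n_free_params: int
    converged: bool
    n_pairs_used: int
    n_observations_used: int
    start_minus2lnL: tuple[float, ...] = ()
    message: str = ""

    @property
    def estimates(self) -> dict[str, float]:
        return self.model.param_dict(self.params)

    @property
    def free_values(self) -> np.ndarray:
        return self.params[self.model.free_mask]

    def quantity(self, name: str) -> float:
        return float(self.model.quantities[name](self.params))

    def to_dict(self) -> dict:
        return {
            "model": self.model.name,
            "estimates": {k: float(v) for k, v in self.estimates.items()},
            "minus2lnL": float(self.minus2lnL),
            "n_free_params": int(self.n_free_params),
            "aic": float(self.minus2lnL + 2 * self.n_free_params),
            "converged": bool(self.converged),
            "n_pairs_used": int(self.n_pairs_used),
            "n_observations_used": int(self.n_observations_used),
        }


def _data_informed_start(model: TwinModel, pdat: PairData) -> np.ndarray:
    """Seed mean parameters at observed means and scale path starts.

    Parameters bounded below at exactly 0 are treated as scale-like (path
    coefficients, innovation SDs, loadings) and their starts are multiplied
    by the pooled observed SD so that starting implied variances are on the
    data's scale.
    """
    theta = model.start_full
    scale = pdat.pooled_sd()
    for i, p in enumerate(model.params):
        if not p.free:
            continue
        if p.lower == 0.0 and not np.isfinite(p.upper):
            theta[i] = p.start * scale
    theta[model.mean_idx] = pdat.observed_means()
    return theta


def fit(
    model: TwinModel,
    data: pd.DataFrame | PairData,
    *,
    n_starts: int = 10,
    seed: int = 0,
    tol: float = 1e-9,
    jitter: float = 0.3,
    max_iter: int = 1000,
    extra_starts: Sequence[np.ndarray] = (),
) -> FitResult:
    """Maximize the FIML likelihood by multi-start quasi-Newton (L-BFGS-B).

    The first start is data-informed (observed means, scale-matched paths,
    and the model's moment initializer when it has one); the remaining
    ``n_starts - 1`` are seeded multiplicative/additive jitters of it.
    ``extra_starts`` are additional full parameter vectors to optimize from
    (e.g. a solution projected from a related model).  The best converged
    solution is returned; if no start converges, the best point found is
    returned with ``converged=False`` and a warning.
    """
    pdat = _as_pairdata(data)
    if model.n_free == 0:
        raise ValueError("model has no free parameters")
    rng = np.random.default_rng(seed)
    free_mask = model.free_mask
    theta0 = _data_informed_start(model, pdat)
    if model.initializer is not None:
        moments = sample_moments(pdat)
        if moments is not None:
            try:
                mapping = model.initializer(moments)
                names = model.param_names
                for key, value in mapping.items():
                    i = names.index(key)
                    p = model.params[i]
                    if p.free and np.isfinite(value):
                        theta0[i] = float(np.clip(value, p.lower, p.upper))
            except Exception as exc:  # informed start is best-effort only
                log.debug("initializer for %s failed: %s", model.name, exc)
    x0 = theta0[free_mask]
    bounds = model.bounds_free

    def objective(x: np.ndarray) -> float:
        return fiml_loglik(model, model.full_vector(x), pdat)

    lo_arr = np.array([lo if np.isfinite(lo) else -1e6 for lo, _ in bounds])
    hi_arr = np.array([hi if np.isfinite(hi) else 1e6 for _, hi in bounds])
    start_points = [x0.copy()]
    for theta in extra_starts:
        start_points.append(np.clip(np.asarray(theta, float)[free_mask], lo_arr, hi_arr))
    for _ in range(max(1, n_starts) - 1):
        xk = x0 * (1.0 + jitter * rng.uniform(-1, 1, size=x0.shape))
        xk = xk + 0.1 * jitter * rng.standard_normal(size=x0.shape)
        start_points.append(np.clip(xk, lo_arr, hi_arr))

    best: optimize.OptimizeResult | None = None
    best_ok = False
    per_start: list[float] = []
    diagnostics: list[str] = []
    for k, xk in enumerate(start_points):
        if not np.isfinite(objective(xk)):
            diagnostics.append(f"start {k}: non-finite objective at start point")
            continue
        with np.errstate(invalid="ignore", over="ignore"):
            res = optimize.minimize(
                objective,
                xk,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8},
            )
        per_start.append(float(res.fun))
        diagnostics.append(f"start {k}: fun={res.fun:.6g} success={res.success}")
        if best is None or res.fun < best.fun - 1e-10 or (
            res.success and not best_ok and res.fun <= best.fun + 1e-6
        ):
            best = res
            best_ok = bool(res.success)
    if best is None:
        raise FitFailedError(f"all optimizer starts failed for model {model.name!r}", diagnostics)
    if not best_ok:
        log.warning("fit of %s did not converge: %s", model.name, best.message)
    theta_hat = model.full_vector(best.x)
    return FitResult(
        model=model,
        params=theta_hat,
        minus2lnL=float(best.fun),
        n_free_params=model.n_free,
        converged=best_ok,
        n_pairs_used=pdat.n_pairs,
        n_observations_used=pdat.n_obs,
        start_minus2lnL=tuple(per_start),
        message=str(best.message),
    )
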