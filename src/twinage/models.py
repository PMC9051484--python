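"""Candidate biometrical twin models and derived summaries.

All models use a path parameterization: variance components are squares (or
Gram matrices) of free path coefficients, so every implied component matrix
is positive semi-definite without inequality constraints.  Path signs are
unidentified; scale-like paths are bounded at zero and reported quantities
are variances, i.e. squares.

Model families
--------------
``univariate_model``
    Classic single-variable ACE/AE/CE/E decomposition.
``correlated_factors_model``
    Per component, a lower-triangular (Cholesky) path matrix giving free
    variances and covariances; the atheoretical multivariate reference.
``autoregression_model``
    Genetic and environmental simplex chains: the latent true score at
    occasion ``t`` is ``beta_t`` times the score at ``t-1`` plus an
    occasion-specific innovation; observations add occasion-specific
    (non-shared environmental) residuals.
``common_pathway_model``
    One or two latent phenotype factors, each with unit total variance split
    into A and E (and optionally C) parts, loading on every occasion, plus
    per-occasion A/E residuals.
``independent_pathway_model``
    Separate common A and E factors loading directly on occasions, plus
    per-occasion residuals.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fiml import FitResult, Parameter, TwinModel

__all__ = [
    "univariate_model",
    "correlated_factors_model",
    "autoregression_model",
    "common_pathway_model",
    "independent_pathway_model",
    "model_by_name",
    "standardize",
    "component_correlations",
    "std_component_quantity",
    "VarianceDecomposition",
    "ComponentCorrelations",
]

_COMPONENT_LETTERS = ("A", "C", "E")


def _norm_components(components) -> tuple[str, ...]:
    if isinstance(components, str):
        comps = tuple(components.upper())
    else:
        comps = tuple(c.upper() for c in components)
    bad = [c for c in comps if c not in _COMPONENT_LETTERS]
    if bad:
        raise ValueError(f"unknown variance components {bad}; use subsets of A, C, E")
    if "E" not in comps:
        raise ValueError(
            "E must be included: a model without non-shared environmental "
            "(residual) variance is unidentified"
        )
    return tuple(c for c in _COMPONENT_LETTERS if c in comps)


class _Spec:
    """Incremental parameter registry used by the model builders."""

    def __init__(self) -> None:
        self.params: list[Parameter] = []

    def add(self, name, start, lower=-np.inf, upper=np.inf, free=True) -> int:
        self.params.append(Parameter(name, float(start), lower, upper, free))
        return len(self.params) - 1

    def vec(self, names, start, lower=-np.inf, upper=np.inf) -> np.ndarray:
        return np.array([self.add(n, start, lower, upper) for n in names], dtype=int)

    def means(self, t: int) -> np.ndarray:
        return self.vec([f"mu_{i + 1}" for i in range(t)], 0.0)


def _zero(t: int) -> np.ndarray:
    return np.zeros((t, t))


# -- moment-informed starts --------------------------------------------------
#
# The builders attach an ``initializer`` translating rough sample component
# moments (from ``fiml.sample_moments``) into start values for their own
# parameterization.  Starts only need to be in the right basin, so all
# estimates below are floored/clipped rather than exact.


def _psd_project(mat: np.ndarray, floor_frac: float = 1e-3) -> np.ndarray:
    mat = 0.5 * (mat + mat.T)
    w, v = np.linalg.eigh(mat)
    floor = floor_frac * max(float(w.max()), 1e-8)
    return (v * np.maximum(w, floor)) @ v.T


def _safe_chol(mat: np.ndarray) -> np.ndarray:
    return np.linalg.cholesky(_psd_project(mat))


def _lead_factor(mat: np.ndarray) -> np.ndarray:
    """Loading vector of the leading principal component, sign-positive."""
    w, v = np.linalg.eigh(_psd_project(mat))
    lam = np.sqrt(max(w[-1], 1e-8)) * v[:, -1]
    return lam if lam.sum() >= 0 else -lam


def _offdiag_mean(mat: np.ndarray) -> float:
    t = mat.shape[0]
    return float((mat.sum() - np.trace(mat)) / max(t * (t - 1), 1))


def _mean_starts(mom: dict, t: int) -> dict[str, float]:
    return {f"mu_{i + 1}": float(mom["mean"][i]) for i in range(t)}


# ---------------------------------------------------------------------------
# Univariate
# ---------------------------------------------------------------------------


def univariate_model(components="AE", var_names=("y",)) -> TwinModel:
    """Univariate decomposition into the requested subset of {A, C, E}."""
    comps = _norm_components(components)
    sp = _Spec()
    idx = {c: sp.add(c.lower(), 0.5, lower=0.0) for c in comps}
    mean_idx = sp.means(1)

    def component_fn(theta):
        out = []
        for c in _COMPONENT_LETTERS:
            v = theta[idx[c]] ** 2 if c in idx else 0.0
            out.append(np.array([[v]]))
        return tuple(out)

    def initializer(mom: dict) -> dict[str, float]:
        w = max(float(mom["W"][0, 0]), 1e-6)
        mapping = {}
        for c in comps:
            frac = 0.1 if c == "E" else 0.05
            mapping[c.lower()] = float(np.sqrt(np.clip(mom[c][0, 0], frac * w, w)))
        mapping.update(_mean_starts(mom, 1))
        return mapping

    model = TwinModel(
        name=f"uni-{''.join(comps).lower()}",
        n_vars=1,
        params=tuple(sp.params),
        components=component_fn,
        mean_idx=mean_idx,
        var_names=tuple(var_names),
        meta={"kind": "univariate", "components": comps},
        initializer=initializer,
    )
    for c in comps:
        model.quantities[f"std_{c}"] = std_component_quantity(model, c, 0)
    return model


# ---------------------------------------------------------------------------
# Correlated factors (Cholesky reference)
# ---------------------------------------------------------------------------


def correlated_factors_model(t: int, components="AE", var_names=None) -> TwinModel:
    """Cholesky-parameterized free variances/covariances per component."""
    if t < 2:
        raise ValueError("correlated factors model needs at least 2 variables")
    comps = _norm_components(components)
    sp = _Spec()
    tril = np.tril_indices(t)
    idx: dict[str, np.ndarray] = {}
    for c in comps:
        ids = []
        for i, j in zip(*tril):
            diag = i == j
            ids.append(
                sp.add(
                    f"{c.lower()}_{i + 1}{j + 1}",
                    0.6 if diag else 0.05,
                    lower=0.0 if diag else -np.inf,
                )
            )
        idx[c] = np.array(ids, dtype=int)
    mean_idx = sp.means(t)

    def component_fn(theta):
        out = []
        for c in _COMPONENT_LETTERS:
            if c in idx:
                chol = np.zeros((t, t))
                chol[tril] = theta[idx[c]]
                out.append(chol @ chol.T)
            else:
                out.append(_zero(t))
        return tuple(out)

    def initializer(mom: dict) -> dict[str, float]:
        mapping = _mean_starts(mom, t)
        share = 1.0 / len(comps)
        for c in comps:
            target = mom[c] if _offdiag_mean(np.abs(mom[c])) + np.trace(mom[c]) > 0 else share * mom["W"]
            chol = _safe_chol(target + 0.02 * np.trace(mom["W"]) / t * np.eye(t))
            for i, j in zip(*tril):
                mapping[f"{c.lower()}_{i + 1}{j + 1}"] = float(chol[i, j])
        return mapping

    return TwinModel(
        name=f"cf-{''.join(comps).lower()}",
        n_vars=t,
        params=tuple(sp.params),
        components=component_fn,
        mean_idx=mean_idx,
        var_names=tuple(var_names) if var_names else (),
        meta={"kind": "cf", "components": comps},
        initializer=initializer,
    )


# ---------------------------------------------------------------------------
# Autoregression (simplex)
# ---------------------------------------------------------------------------


def autoregression_model(
    t: int,
    components="AE",
    *,
    genetic_residuals: bool = False,
    residual_structure: str = "equal",
    var_names=None,
) -> TwinModel:
    """Latent simplex chains with occasion-specific innovations.

    Each included component (A always; C optional; E always) has its own
    chain: true score ``g_t = beta_t * g_{t-1} + innovation_t``.  Observed
    scores are the sum of the chain true scores plus non-shared
    environmental residuals (``genetic_residuals=True`` adds A residuals as
    a sensitivity variant).

    ``residual_structure="equal"`` (default) shares one residual variance
    across occasions.  This is an identification constraint, not a
    convenience: with fully free residuals the quasi-simplex confounds the
    first occasion's E innovation with its residual and the last occasion's
    E innovation with its residual, leaving two unidentified directions and
    a misleading free-parameter count.  ``"free"`` keeps per-occasion
    residuals for users who want the diagram's literal parameterization.
    """
    if t < 2:
        raise ValueError("autoregression model needs at least 2 occasions")
    if residual_structure not in ("equal", "free"):
        raise ValueError("residual_structure must be 'equal' or 'free'")
    comps = _norm_components(components)
    sp = _Spec()
    inn_idx: dict[str, np.ndarray] = {}
    beta_idx: dict[str, np.ndarray] = {}
    for c in comps:
        lc = c.lower()
        inn_idx[c] = sp.vec([f"{lc}_inn_{i + 1}" for i in range(t)], 0.5, lower=0.0)
        beta_idx[c] = sp.vec(
            [f"beta_{lc}_{i + 2}" for i in range(t - 1)], 0.5, lower=-2.0, upper=2.0
        )

    def _res_vec(prefix: str) -> np.ndarray:
        if residual_structure == "equal":
            shared = sp.add(prefix, 0.3, lower=0.0)
            return np.full(t, shared, dtype=int)
        return sp.vec([f"{prefix}_{i + 1}" for i in range(t)], 0.3, lower=0.0)

    e_res_idx = _res_vec("e_res")
    a_res_idx = _res_vec("a_res") if genetic_residuals else None
    mean_idx = sp.means(t)
    eye = np.eye(t)

    def chain_cov(theta, c):
        bmat = np.zeros((t, t))
        betas = theta[beta_idx[c]]
        for i in range(t - 1):
            bmat[i + 1, i] = betas[i]
        inv = np.linalg.solve(eye - bmat, eye)
        psi = np.diag(theta[inn_idx[c]] ** 2)
        return inv @ psi @ inv.T

    def component_fn(theta):
        out = []
        for c in _COMPONENT_LETTERS:
            mat = chain_cov(theta, c) if c in inn_idx else _zero(t)
            if c == "E":
                mat = mat + np.diag(theta[e_res_idx] ** 2)
            if c == "A" and a_res_idx is not None:
                mat = mat + np.diag(theta[a_res_idx] ** 2)
            out.append(mat)
        return tuple(out)

    def initializer(mom: dict) -> dict[str, float]:
        mapping = _mean_starts(mom, t)
        wdiag = np.clip(np.diag(mom["W"]), 1e-6, None)
        for c in comps:
            mat = _psd_project(mom[c], 1e-2)
            if c == "E":
                # reserve part of the E diagonal for occasion residuals
                res = 0.4 * np.clip(np.diag(mom["E"]), 0.05 * wdiag, None)
                if residual_structure == "equal":
                    mapping["e_res"] = float(np.sqrt(res.mean()))
                else:
                    for i in range(t):
                        mapping[f"e_res_{i + 1}"] = float(np.sqrt(res[i]))
                mat = _psd_project(mat - np.diag(res), 1e-2)
            lc = c.lower()
            mapping[f"{lc}_inn_1"] = float(np.sqrt(max(mat[0, 0], 0.02 * wdiag[0])))
            for i in range(1, t):
                beta = float(np.clip(mat[i, i - 1] / max(mat[i - 1, i - 1], 1e-8), -1.5, 1.5))
                mapping[f"beta_{lc}_{i + 1}"] = beta
                inn2 = mat[i, i] - beta**2 * mat[i - 1, i - 1]
                mapping[f"{lc}_inn_{i + 1}"] = float(np.sqrt(max(inn2, 0.02 * wdiag[i])))
        return mapping

    return TwinModel(
        name=f"ar-{''.join(comps).lower()}",
        n_vars=t,
        params=tuple(sp.params),
        components=component_fn,
        mean_idx=mean_idx,
        var_names=tuple(var_names) if var_names else (),
        meta={
            "kind": "ar",
            "components": comps,
            "genetic_residuals": genetic_residuals,
            "residual_structure": residual_structure,
        },
        initializer=initializer,
    )


# ---------------------------------------------------------------------------
# Common pathway
# ---------------------------------------------------------------------------


def common_pathway_model(
    t: int, n_factors: int = 1, components="AE", var_names=None
) -> TwinModel:
    """Latent phenotype factor(s) with unit variance split across components.

    Each factor's total variance is constrained to 1 by construction: with
    components AE the genetic path ``facK_a`` lies in [0, 1] and the
    environmental part is ``sqrt(1 - facK_a^2)``, so the squared genetic path
    is directly the factor's heritability.  Occasion residuals exist for
    every included component.  The second factor's first loading is fixed to
    zero for rotational identification.
    """
    if n_factors not in (1, 2):
        raise ValueError("n_factors must be 1 or 2")
    if t < 3:
        raise ValueError("a 1-factor common pathway model needs at least 3 variables")
    if n_factors == 2 and t < 4:
        raise ValueError("a 2-factor common pathway model needs at least 4 variables")
    comps = _norm_components(components)
    sp = _Spec()
    split_idx: dict[tuple[int, str], int] = {}
    load_idx: list[np.ndarray] = []
    for k in range(n_factors):
        for c in comps:
            if c == "E":
                continue  # E share of the factor is derived from the unit constraint
            split_idx[(k, c)] = sp.add(f"fac{k + 1}_{c.lower()}", 0.7, lower=0.0, upper=1.0)
        ids = []
        for i in range(t):
            if k == 1 and i == 0:
                ids.append(sp.add(f"lam{k + 1}_{i + 1}", 0.0, free=False))
            else:
                lower = 0.0 if i == k else -np.inf
                ids.append(sp.add(f"lam{k + 1}_{i + 1}", 0.7, lower=lower))
        load_idx.append(np.array(ids, dtype=int))
    res_idx = {
        c: sp.vec([f"{c.lower()}_res_{i + 1}" for i in range(t)], 0.3, lower=0.0)
        for c in comps
    }
    mean_idx = sp.means(t)

    def factor_shares(theta, k):
        """Squared component paths of factor k; sums to 1 (E takes the rest)."""
        shares = {}
        used = 0.0
        for c in ("A", "C"):
            if (k, c) in split_idx:
                shares[c] = theta[split_idx[(k, c)]] ** 2
                used += shares[c]
        shares["E"] = max(0.0, 1.0 - used)
        return shares

    def component_fn(theta):
        common = {c: _zero(t) for c in _COMPONENT_LETTERS}
        for k in range(n_factors):
            lam = theta[load_idx[k]]
            outer = np.outer(lam, lam)
            for c, share in factor_shares(theta, k).items():
                common[c] = common[c] + share * outer
        out = []
        for c in _COMPONENT_LETTERS:
            mat = common[c]
            if c in res_idx:
                mat = mat + np.diag(theta[res_idx[c]] ** 2)
            out.append(mat)
        return tuple(out)

    def initializer(mom: dict) -> dict[str, float]:
        mapping = _mean_starts(mom, t)
        w = mom["W"]
        wdiag = np.clip(np.diag(w), 1e-6, None)
        lam = _lead_factor(w)
        denom = _offdiag_mean(w)
        shares = {}
        rest = 1.0
        for c in comps:
            if c == "E":
                continue
            s = _offdiag_mean(mom[c]) / denom if abs(denom) > 1e-10 else 0.4
            shares[c] = float(np.clip(s, 0.05, rest - 0.05))
            rest -= shares[c]
        for c, s in shares.items():
            mapping[f"fac1_{c.lower()}"] = float(np.sqrt(s))
        for i in range(t):
            mapping[f"lam1_{i + 1}"] = float(lam[i])
            for c in comps:
                s = shares.get(c, rest)  # E takes the remainder
                res2 = mom[c][i, i] - s * lam[i] ** 2
                mapping[f"{c.lower()}_res_{i + 1}"] = float(
                    np.sqrt(np.clip(res2, 0.03 * wdiag[i], wdiag[i]))
                )
        if n_factors == 2:
            for i in range(1, t):
                mapping[f"lam2_{i + 1}"] = 0.1
            for c in shares:
                mapping[f"fac2_{c.lower()}"] = mapping[f"fac1_{c.lower()}"]
        return mapping

    model = TwinModel(
        name=f"cp{n_factors}-{''.join(comps).lower()}",
        n_vars=t,
        params=tuple(sp.params),
        components=component_fn,
        mean_idx=mean_idx,
        var_names=tuple(var_names) if var_names else (),
        initializer=initializer,
        meta={
            "kind": "cp",
            "components": comps,
            "n_factors": n_factors,
            "factor_shares": factor_shares,
            "load_idx": load_idx,
            "res_idx": res_idx,
        },
    )
    for c in comps:
        model.quantities[f"factor_{c}_share"] = (
            lambda theta, c=c: factor_shares(theta, 0)[c]
        )
    return model


# ---------------------------------------------------------------------------
# Independent pathway
# ---------------------------------------------------------------------------


def independent_pathway_model(t: int, components="AE", var_names=None) -> TwinModel:
    """Separate common factors per component, loading directly on occasions."""
    if t < 3:
        raise ValueError("independent pathway model needs at least 3 variables")
    comps = _norm_components(components)
    sp = _Spec()
    load_idx = {}
    for c in comps:
        ids = []
        for i in range(t):
            ids.append(sp.add(f"lam_{c.lower()}{i + 1}", 0.5, lower=0.0 if i == 0 else -np.inf))
        load_idx[c] = np.array(ids, dtype=int)
    res_idx = {
        c: sp.vec([f"{c.lower()}_res_{i + 1}" for i in range(t)], 0.3, lower=0.0)
        for c in comps
    }
    mean_idx = sp.means(t)

    def component_fn(theta):
        out = []
        for c in _COMPONENT_LETTERS:
            if c in load_idx:
                lam = theta[load_idx[c]]
                mat = np.outer(lam, lam) + np.diag(theta[res_idx[c]] ** 2)
            else:
                mat = _zero(t)
            out.append(mat)
        return tuple(out)

    def initializer(mom: dict) -> dict[str, float]:
        mapping = _mean_starts(mom, t)
        wdiag = np.clip(np.diag(mom["W"]), 1e-6, None)
        for c in comps:
            lam = _lead_factor(mom[c])
            for i in range(t):
                mapping[f"lam_{c.lower()}{i + 1}"] = float(lam[i])
                res2 = mom[c][i, i] - lam[i] ** 2
                mapping[f"{c.lower()}_res_{i + 1}"] = float(
                    np.sqrt(np.clip(res2, 0.03 * wdiag[i], wdiag[i]))
                )
        return mapping

    return TwinModel(
        name=f"ip-{''.join(comps).lower()}",
        n_vars=t,
        params=tuple(sp.params),
        components=component_fn,
        mean_idx=mean_idx,
        var_names=tuple(var_names) if var_names else (),
        meta={"kind": "ip", "components": comps, "load_idx": load_idx, "res_idx": res_idx},
        initializer=initializer,
    )


def model_by_name(name: str, t: int = 4, components: str | None = None) -> TwinModel:
    """Construct a model from its short CLI name (``uni-ace``, ``cf``, ...)."""
    name = name.lower()
    if name.startswith("uni"):
        comps = components or (name.split("-", 1)[1] if "-" in name else "ace")
        return univariate_model(comps)
    comps = components or (name.split("-", 1)[1] if "-" in name else "ae")
    base = name.split("-", 1)[0]
    if base == "cf":
        return correlated_factors_model(t, comps)
    if base == "ar":
        return autoregression_model(t, comps)
    if base == "cp1":
        return common_pathway_model(t, 1, comps)
    if base == "cp2":
        return common_pathway_model(t, 2, comps)
    if base == "ip":
        return independent_pathway_model(t, comps)
    raise ValueError(f"unknown model name {name!r}")


# ---------------------------------------------------------------------------
# Derived summaries
# ---------------------------------------------------------------------------


def std_component_quantity(model: TwinModel, component: str, var_index: int):
    """Callable(theta) -> standardized variance share of one component."""
    ci = _COMPONENT_LETTERS.index(component)

    def quantity(theta: np.ndarray) -> float:
        mats = model.components(np.asarray(theta, dtype=float))
        total = sum(m[var_index, var_index] for m in mats)
        if total <= 0:
            raise ZeroDivisionError(f"total variance of variable {var_index} is zero")
        return float(mats[ci][var_index, var_index] / total)

    return quantity


@dataclass
class VarianceDecomposition:
    """Standardized variance components per variable (rows sum to 1)."""

    standardized: pd.DataFrame  # index: variable, columns: A, C, E
    common: pd.DataFrame | None = None  # common-factor part of each share
    factor_shares: dict[str, float] | None = None  # e.g. {"A": 0.74, "E": 0.26}

    def to_dict(self) -> dict:
        out = {"standardized": self.standardized.to_dict(orient="index")}
        if self.common is not None:
            out["common"] = self.common.to_dict(orient="index")
        if self.factor_shares is not None:
            out["factor_shares"] = self.factor_shares
        return out


def standardize(fit: FitResult) -> VarianceDecomposition:
    """Standardized A/C/E per variable; factor split for factor models."""
    if not fit.converged:
        raise ValueError(f"refusing to standardize non-converged fit of {fit.model.name!r}")
    model = fit.model
    theta = fit.params
    sigma_a, sigma_c, sigma_e = model.components(theta)
    total = np.diag(sigma_a + sigma_c + sigma_e).copy()
    if np.any(total <= 0):
        raise ZeroDivisionError("zero total variance for at least one variable")
    std = pd.DataFrame(
        {
            "A": np.diag(sigma_a) / total,
            "C": np.diag(sigma_c) / total,
            "E": np.diag(sigma_e) / total,
        },
        index=list(model.var_names),
    )
    common = None
    factor_shares = None
    meta = model.meta
    if meta.get("kind") == "cp":
        shares0 = meta["factor_shares"](theta, 0)
        factor_shares = {c: float(shares0.get(c, 0.0)) for c in _COMPONENT_LETTERS}
        common_var = {c: np.zeros(model.n_vars) for c in _COMPONENT_LETTERS}
        for k in range(meta["n_factors"]):
            lam = theta[meta["load_idx"][k]]
            shares = meta["factor_shares"](theta, k)
            for c, s in shares.items():
                common_var[c] += s * lam**2
        common = pd.DataFrame(
            {c: common_var[c] / total for c in _COMPONENT_LETTERS},
            index=list(model.var_names),
        )
    elif meta.get("kind") == "ip":
        common_var = {c: np.zeros(model.n_vars) for c in _COMPONENT_LETTERS}
        for c, idx in meta["load_idx"].items():
            common_var[c] = theta[idx] ** 2
        common = pd.DataFrame(
            {c: common_var[c] / total for c in _COMPONENT_LETTERS},
            index=list(model.var_names),
        )
    return VarianceDecomposition(standardized=std, common=common, factor_shares=factor_shares)


@dataclass
class ComponentCorrelations:
    """Genetic and environmental correlation matrices between variables."""

    rG: pd.DataFrame
    rC: pd.DataFrame | None
    rE: pd.DataFrame

    def to_dict(self) -> dict:
        out = {"rG": self.rG.to_dict(orient="index"), "rE": self.rE.to_dict(orient="index")}
        if self.rC is not None:
            out["rC"] = self.rC.to_dict(orient="index")
        return out


def _cov_to_corr(mat: np.ndarray, names) -> pd.DataFrame:
    d = np.diag(mat).copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt(np.outer(d, d))
        corr = np.where(denom > 0, mat / np.where(denom > 0, denom, 1.0), np.nan)
    np.fill_diagonal(corr, np.where(d > 0, 1.0, np.nan))
    return pd.DataFrame(corr, index=list(names), columns=list(names))


def component_correlations(fit: FitResult) -> ComponentCorrelations:
    """rG_ij = SigmaA_ij / sqrt(SigmaA_ii * SigmaA_jj); rE analogous.

    Cells whose component variance vanishes on either variable are NaN.
    """
    if fit.model.n_vars < 2:
        raise ValueError("component correlations need a multivariate fit")
    if not fit.converged:
        raise ValueError(f"refusing to summarize non-converged fit of {fit.model.name!r}")
    sigma_a, sigma_c, sigma_e = fit.model.components(fit.params)
    names = fit.model.var_names
    has_c = "C" in fit.model.meta.get("components", ())
    return ComponentCorrelations(
        rG=_cov_to_corr(sigma_a, names),
        rC=_cov_to_corr(sigma_c, names) if has_c else None,
        rE=_cov_to_corr(sigma_e, names),
    )
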