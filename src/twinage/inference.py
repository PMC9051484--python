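"""Model comparison and likelihood-based inference.

Likelihood-ratio tests use the naive central chi-square reference, which is
what applied twin analyses conventionally report even when a variance
component sits on the boundary of its parameter space; the boundary
(chi-bar-square) mixture reference is available via ``boundary=True`` but is
off by default so that conventional decision sequences are reproduced.

Profile-likelihood confidence intervals re-optimize all other parameters at
each candidate value of the target quantity and bound the interval where
-2 lnL rises by the chi-square(1) critical value (3.841 at 95%).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .fiml import FitResult, TwinModel, _as_pairdata, fiml_loglik, fit
from .models import (
    ComponentCorrelations,
    VarianceDecomposition,
    autoregression_model,
    common_pathway_model,
    component_correlations,
    correlated_factors_model,
    independent_pathway_model,
    standardize,
)

__all__ = [
    "lrt",
    "aic",
    "profile_ci",
    "ProfileCI",
    "model_selection_pipeline",
    "SelectionResult",
    "NestingError",
]

log = logging.getLogger(__name__)

_CHI2_TOL = 1e-4


class NestingError(ValueError):
    """The 'nested' fit beat its parent by more than numerical tolerance."""


def lrt(parent: FitResult, nested: FitResult, *, boundary: bool = False):
    """Likelihood-ratio chi-square test of a nested model against its parent.

    Returns ``(chi2, df, p)``.  ``boundary=True`` uses the 50:50 mixture of
    chi-square(df-1) and chi-square(df) appropriate when a single variance
    component is tested on its boundary.
    """
    df = parent.n_free_params - nested.n_free_params
    if df < 0:
        raise NestingError(
            f"{nested.model.name} has more free parameters than {parent.model.name}"
        )
    chi2 = nested.minus2lnL - parent.minus2lnL
    if chi2 < -_CHI2_TOL:
        raise NestingError(
            f"nested model {nested.model.name} fits better than parent "
            f"{parent.model.name} (delta -2lnL = {chi2:.4g}); refit needed"
        )
    chi2 = max(chi2, 0.0)
    if df == 0:
        return chi2, 0, 1.0 if chi2 <= _CHI2_TOL else 0.0
    if boundary:
        p_hi = stats.chi2.sf(chi2, df)
        p_lo = stats.chi2.sf(chi2, df - 1) if df > 1 else (1.0 if chi2 <= 0 else 0.0)
        p = 0.5 * (p_hi + p_lo)
    else:
        p = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), float(p)


def aic(fit_result: FitResult) -> float:
    """Akaike information criterion, -2 lnL + 2 * (free parameters)."""
    return float(fit_result.minus2lnL + 2 * fit_result.n_free_params)


# ---------------------------------------------------------------------------
# Profile-likelihood confidence intervals
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProfileCI:
    lower: float
    upper: float
    lower_at_bound: bool = False
    upper_at_bound: bool = False

    def __iter__(self):
        return iter((self.lower, self.upper))

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def _resolve_quantity(model: TwinModel, quantity) -> Callable[[np.ndarray], float]:
    if callable(quantity):
        return quantity
    if quantity in model.quantities:
        return model.quantities[quantity]
    if quantity in model.param_names:
        i = model.param_names.index(quantity)
        return lambda theta: float(theta[i])
    raise KeyError(f"unknown quantity {quantity!r} for model {model.name!r}")


def profile_ci(
    model: TwinModel,
    data,
    fit_result: FitResult,
    quantity,
    level: float = 0.95,
    *,
    clip: tuple[float, float] | None = None,
    rtol: float = 1e-3,
) -> ProfileCI:
    """Profile-likelihood interval for a parameter or derived quantity.

    ``quantity`` is a parameter name, a key of ``model.quantities`` or a
    callable of the full parameter vector.  ``clip`` bounds the search range
    (e.g. ``(0, 1)`` for standardized components); a bound reached while the
    profiled -2 lnL is still below the critical rise is reported as the CI
    endpoint with the corresponding ``*_at_bound`` flag.
    """
    pdat = _as_pairdata(data)
    f = _resolve_quantity(model, quantity)
    crit = float(stats.chi2.ppf(level, 1))
    target = fit_result.minus2lnL + crit
    theta_hat = fit_result.params
    f_hat = float(f(theta_hat))
    free_mask = model.free_mask
    bounds = model.bounds_free

    def profiled(q: float, x0: np.ndarray) -> tuple[float, np.ndarray]:
        cons = [{"type": "eq", "fun": lambda x: f(model.full_vector(x)) - q}]
        with np.errstate(invalid="ignore", over="ignore"):
            res = optimize.minimize(
                lambda x: fiml_loglik(model, model.full_vector(x), pdat),
                x0,
                method="SLSQP",
                bounds=bounds,
                constraints=cons,
                options={"maxiter": 300, "ftol": 1e-10},
            )
        val = float(res.fun) if np.isfinite(res.fun) else np.inf
        # Constraint violation means the value q is not attainable.
        if abs(f(model.full_vector(res.x)) - q) > 1e-4:
            return np.inf, res.x
        return val, res.x

    def search(direction: int) -> tuple[float, bool]:
        limit = None
        if clip is not None:
            limit = clip[1] if direction > 0 else clip[0]
        step = max(0.02, 0.05 * abs(f_hat))
        q_in, x_in = f_hat, theta_hat[free_mask].copy()
        val_in = fit_result.minus2lnL
        q_out = None
        # march outward with doubling steps until the profile crosses target
        for _ in range(40):
            q = q_in + direction * step
            hit_limit = False
            if limit is not None and (q - limit) * direction >= 0:
                q = limit
                hit_limit = True
            val, x = profiled(q, x_in)
            if val > target:
                q_out = q
                break
            q_in, x_in, val_in = q, x, val
            if hit_limit:
                return float(limit), True
            step *= 2.0
        if q_out is None:
            log.warning("profile CI bound not bracketed in direction %+d", direction)
            return q_in, True
        # bisection between q_in (below target) and q_out (above target)
        tol = rtol * max(1.0, abs(f_hat))
        while abs(q_out - q_in) > tol:
            q_mid = 0.5 * (q_in + q_out)
            val, x = profiled(q_mid, x_in)
            if val > target:
                q_out = q_mid
            else:
                q_in, x_in = q_mid, x
        return 0.5 * (q_in + q_out), False

    lower, lower_bound = search(-1)
    upper, upper_bound = search(+1)
    lower, upper = min(lower, f_hat), max(upper, f_hat)
    return ProfileCI(float(lower), float(upper), lower_bound, upper_bound)


# ---------------------------------------------------------------------------
# End-to-end model selection
# ---------------------------------------------------------------------------


@dataclass
class SelectionResult:
    """Model-comparison table plus the selected model's summaries."""

    table: pd.DataFrame
    selected: str
    fits: dict[str, FitResult]
    decomposition: VarianceDecomposition | None
    correlations: ComponentCorrelations | None
    notes: list[str] = field(default_factory=list)

    @property
    def selected_fit(self) -> FitResult:
        return self.fits[self.selected]


def _embed_cp1(target: TwinModel, cp1_fit: FitResult) -> np.ndarray | None:
    """Exact embedding of a 1-factor common-pathway solution into a model
    that nests it (2-factor common pathway or independent pathway)."""
    est = cp1_fit.estimates
    t = cp1_fit.model.n_vars
    try:
        s_a = est["fac1_a"] ** 2
        mapping: dict[str, float] = {}
        for i in range(t):
            lam = est[f"lam1_{i + 1}"]
            mapping[f"mu_{i + 1}"] = est[f"mu_{i + 1}"]
            for pname in (f"a_res_{i + 1}", f"e_res_{i + 1}", f"c_res_{i + 1}"):
                if pname in est and pname in target.param_names:
                    mapping[pname] = est[pname]
            if target.meta.get("kind") == "ip":
                mapping[f"lam_a{i + 1}"] = np.sqrt(s_a) * lam
                mapping[f"lam_e{i + 1}"] = np.sqrt(max(1.0 - s_a, 0.0)) * lam
            else:  # cp2: second factor switched off
                mapping[f"lam1_{i + 1}"] = lam
                if f"lam2_{i + 1}" in target.free_names:
                    mapping[f"lam2_{i + 1}"] = 0.0
        if target.meta.get("kind") == "cp":
            mapping["fac1_a"] = est["fac1_a"]
            if "fac2_a" in target.param_names:
                mapping["fac2_a"] = est["fac1_a"]
        return target.vector_from(mapping)
    except KeyError:
        return None


def _row(name, fit_result, parent=None, selected=False, note=""):
    row = {
        "model": name,
        "minus2lnL": fit_result.minus2lnL,
        "n_free_params": fit_result.n_free_params,
        "AIC": aic(fit_result),
        "delta_minus2lnL": np.nan,
        "delta_df": np.nan,
        "p": np.nan,
        "selected": selected,
        "note": note,
    }
    if parent is not None:
        chi2, df, p = lrt(parent, fit_result)
        row.update(delta_minus2lnL=chi2, delta_df=df, p=p)
    return row


def model_selection_pipeline(
    data,
    *,
    components: str = "AE",
    alpha: float = 0.05,
    n_starts: int = 3,
    seed: int = 0,
    drop_order: Sequence[str] | None = None,
    residual_a_tests: bool = True,
) -> SelectionResult:
    """Fit the candidate multivariate models and select among them.

    Stage 1 fits the correlated-factors reference and the structured
    candidates (autoregression, 1- and 2-factor common pathway, independent
    pathway), comparing each candidate to the reference by LRT and AIC.
    Starts are cross-seeded: candidates start from the reference fit's
    implied components, and the reference is refit from each candidate's
    solution, so the nested likelihood ordering holds at the optima.
    Candidates whose LRT against the reference is non-significant are
    adequate; an adequate candidate that nests another adequate candidate
    is discarded when the LRT between them is non-significant (parameters
    that can be fixed to zero without significant deterioration are), and
    the lowest AIC among the survivors wins.  Stage 2 refits
    the winner with successively reduced component sets (for ACE:
    AE -> CE -> E; for AE: E) and keeps a reduction when its LRT against the
    current best is non-significant and its AIC is lower.  Per-variable
    residual genetic variances of a common/independent-pathway winner are
    additionally tested by fixing each to zero (diagnostic rows only).
    """
    pdat = _as_pairdata(data)
    t = pdat.n_vars
    var_names = pdat.var_names
    notes: list[str] = []

    def _fit(model, extra=()):
        return fit(model, pdat, n_starts=n_starts, seed=seed, extra_starts=extra)

    def _projected_start(model, source_fit):
        """Start vector for ``model`` seeded from another fit's implied moments."""
        if model.initializer is None:
            return None
        sigma_a, sigma_c, sigma_e = source_fit.model.components(source_fit.params)
        moments = {
            "mean": source_fit.model.means(source_fit.params),
            "W": sigma_a + sigma_c + sigma_e,
            "A": sigma_a,
            "C": sigma_c,
            "E": sigma_e,
        }
        try:
            return model.vector_from(model.initializer(moments))
        except Exception:
            return None

    reference = correlated_factors_model(t, components, var_names=var_names)
    ref_fit = _fit(reference)
    fits: dict[str, FitResult] = {reference.name: ref_fit}

    candidates = {
        m.name: m
        for m in (
            autoregression_model(t, components, var_names=var_names),
            common_pathway_model(t, 1, components, var_names=var_names),
            *(
                [common_pathway_model(t, 2, components, var_names=var_names)]
                if t >= 4
                else []
            ),
            independent_pathway_model(t, components, var_names=var_names),
        )
    }
    comps_tag = "".join(c for c in "ACE" if c in components.upper()).lower()
    cp1_name = f"cp1-{comps_tag}"
    for name, model in candidates.items():
        extra = [s for s in [_projected_start(model, ref_fit)] if s is not None]
        # the 2-factor and independent-pathway models nest the 1-factor
        # common pathway: seed them from its solution as well
        if name != cp1_name and cp1_name in fits and name in (f"cp2-{comps_tag}", f"ip-{comps_tag}"):
            proj = _projected_start(model, fits[cp1_name])
            if proj is not None:
                extra.append(proj)
            extra.append(_embed_cp1(model, fits[cp1_name]))
        try:
            fits[name] = _fit(model, extra=[e for e in extra if e is not None])
        except Exception as exc:  # pragma: no cover - defensive
            notes.append(f"{name}: fit failed ({exc}); excluded")

    # Refit the reference from each candidate's solution so that it attains
    # at least every nested optimum.
    ref_extra = [
        s
        for name in candidates
        if name in fits
        for s in [_projected_start(reference, fits[name])]
        if s is not None
    ]
    if ref_extra:
        refit = _fit(reference, extra=ref_extra)
        if refit.minus2lnL < ref_fit.minus2lnL:
            ref_fit = refit
            fits[reference.name] = ref_fit

    rows = [_row(reference.name, ref_fit)]
    adequate: dict[str, FitResult] = {}
    for name in candidates:
        if name not in fits:
            continue
        fr = fits[name]
        if not fr.converged:
            notes.append(f"{name}: did not converge; excluded from selection")
            rows.append(_row(name, fr, ref_fit, note="non-converged"))
            continue
        row = _row(name, fr, ref_fit)
        rows.append(row)
        if row["p"] > alpha:
            adequate[name] = fr

    # Parsimony among adequate candidates: a fuller model whose extra
    # parameters do not significantly improve on a nested adequate candidate
    # is discarded (they can be fixed to zero).
    survivors = dict(adequate)
    for small, big in ((cp1_name, f"cp2-{comps_tag}"), (cp1_name, f"ip-{comps_tag}")):
        if small in survivors and big in survivors:
            chi2 = max(survivors[small].minus2lnL - survivors[big].minus2lnL, 0.0)
            df = survivors[big].n_free_params - survivors[small].n_free_params
            if df > 0 and stats.chi2.sf(chi2, df) > alpha:
                survivors.pop(big)
    if survivors:
        winner = min(
            survivors, key=lambda nm: (aic(survivors[nm]), survivors[nm].n_free_params)
        )
    else:
        winner = reference.name
        notes.append(
            "no structured candidate fit adequately against the reference; "
            "selection falls back to the correlated-factors model"
        )
    winner_fit = fits[winner]

    # Stage 2: component drops within the winner family.
    def rebuild(name: str, comps: str) -> TwinModel:
        kind = candidates[name].meta["kind"] if name in candidates else "cf"
        if kind == "ar":
            return autoregression_model(t, comps, var_names=var_names)
        if kind == "cp":
            return common_pathway_model(
                t, candidates[name].meta["n_factors"], comps, var_names=var_names
            )
        if kind == "ip":
            return independent_pathway_model(t, comps, var_names=var_names)
        return correlated_factors_model(t, comps, var_names=var_names)

    if drop_order is None:
        drop_order = ("AE", "CE", "E") if "C" in components.upper() else ("E",)
    best_name, best_fit = winner, winner_fit
    for comps in drop_order:
        try:
            sub_model = rebuild(winner, comps)
        except ValueError:
            continue
        sub_fit = _fit(sub_model)
        fits[sub_model.name] = sub_fit
        nested = sub_fit.n_free_params < best_fit.n_free_params
        note = ""
        if not sub_fit.converged:
            rows.append(_row(sub_model.name, sub_fit, note="non-converged"))
            notes.append(f"{sub_model.name}: did not converge; excluded")
            continue
        if nested:
            row = _row(sub_model.name, sub_fit, best_fit)
            accept = row["p"] > alpha and row["AIC"] < aic(best_fit)
        else:
            row = _row(sub_model.name, sub_fit, note="non-nested; AIC comparison only")
            accept = row["AIC"] < aic(best_fit)
        rows.append(row)
        if accept:
            best_name, best_fit = sub_model.name, sub_fit

    # Diagnostic: per-variable residual genetic variance of a CP/IP winner.
    kind = best_fit.model.meta.get("kind")
    if residual_a_tests and kind in ("cp", "ip") and "A" in best_fit.model.meta["components"]:
        for i in range(t):
            pname = f"a_res_{i + 1}"
            if pname not in best_fit.model.param_names:
                continue
            sub = best_fit.model.fix({pname: 0.0})
            sub_fit = _fit(sub)
            fits[sub.name] = sub_fit
            if sub_fit.converged:
                rows.append(_row(sub.name, sub_fit, best_fit, note="residual-A test"))

    # Degenerate-structure flag: all common-factor loadings near zero.
    meta = best_fit.model.meta
    if kind in ("cp", "ip"):
        load_idx = meta["load_idx"]
        loads = (
            np.concatenate([best_fit.params[ix] for ix in load_idx])
            if isinstance(load_idx, list)
            else np.concatenate([best_fit.params[ix] for ix in load_idx.values()])
        )
        if np.all(np.abs(loads) < 1e-3):
            notes.append(
                f"{best_name}: all common-factor loadings are ~0; variables appear "
                "independent and the factor structure is degenerate"
            )

    table = pd.DataFrame(rows)
    table["selected"] = table["model"] == best_name
    decomposition = correlations = None
    try:
        decomposition = standardize(best_fit)
        if best_fit.model.n_vars >= 2:
            correlations = component_correlations(best_fit)
    except (ValueError, ZeroDivisionError) as exc:
        notes.append(f"summaries unavailable for {best_name}: {exc}")
    return SelectionResult(
        table=table,
        selected=best_name,
        fits=fits,
        decomposition=decomposition,
        correlations=correlations,
        notes=notes,
    )
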