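"""Simulation studies validating estimator behavior under known truth.

These routines generate twin data under a known model, run the package's
estimators and summarize recovery, confidence-interval coverage and
model-selection behavior.  They back both the test suite and the
reproducibility script, and are useful for power/robustness exploration at
other settings.
"""
from __future__ import annotations

import numpy as np

from .fiml import fit
from .inference import model_selection_pipeline, profile_ci
from .models import common_pathway_model, univariate_model
from .synthetic import TrueModel, simulate_wide, true_autoregression, true_common_pathway, true_univariate

__all__ = [
    "ae_recovery_study",
    "ci_coverage_study",
    "cp_factor_recovery_study",
    "selection_consistency_study",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    # independent per-replicate seeds, kept below 2**31
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def ae_recovery_study(
    n_reps: int = 50,
    n_mz: int = 2000,
    n_dz: int = 2000,
    a: float = 0.8,
    e: float = 0.6,
    seed: int = 0,
) -> dict:
    """Mean standardized A from univariate AE fits to AE-generated data."""
    true = true_univariate("AE", a=a, e=e)
    model = univariate_model("AE")
    seeds = _child_seeds(seed, n_reps)
    estimates = []
    for k in range(n_reps):
        wide = simulate_wide(true, n_mz, n_dz, seed=seeds[k])
        fr = fit(model, wide, n_starts=2, seed=seeds[k])
        estimates.append(fr.quantity("std_A"))
    est = np.asarray(estimates)
    truth = a**2 / (a**2 + e**2)
    return {
        "mean_std_a": float(est.mean()),
        "mc_se": float(est.std(ddof=1) / np.sqrt(n_reps)),
        "true_std_a": float(truth),
        "n_reps": n_reps,
        "n_pairs": n_mz + n_dz,
    }


def ci_coverage_study(
    n_reps: int = 500,
    n_mz: int = 300,
    n_dz: int = 300,
    a: float = 0.8,
    e: float = 0.6,
    level: float = 0.95,
    seed: int = 0,
) -> dict:
    """Empirical coverage of the profile-likelihood CI for standardized A."""
    true = true_univariate("AE", a=a, e=e)
    model = univariate_model("AE")
    truth = a**2 / (a**2 + e**2)
    seeds = _child_seeds(seed, n_reps)
    covered = 0
    for k in range(n_reps):
        wide = simulate_wide(true, n_mz, n_dz, seed=seeds[k])
        fr = fit(model, wide, n_starts=2, seed=seeds[k])
        ci = profile_ci(model, wide, fr, "std_A", level=level, clip=(0.0, 1.0))
        covered += ci.contains(truth)
    pct = 100.0 * covered / n_reps
    return {
        "coverage_pct": pct,
        "nominal_pct": 100.0 * level,
        "mc_se_pct": float(100.0 * np.sqrt(level * (1 - level) / n_reps)),
        "n_reps": n_reps,
        "n_pairs": n_mz + n_dz,
    }


def cp_factor_recovery_study(
    n_reps: int = 25,
    n_mz: int = 1500,
    n_dz: int = 1500,
    factor_a: float = 0.86,
    loadings: float = 0.8,
    residual_a: float = 0.3,
    residual_e: float = 0.45,
    seed: int = 0,
) -> dict:
    """Mean genetic share of the latent factor from refitted CP1-AE models."""
    true = true_common_pathway(
        t=4,
        factor_a=factor_a,
        loadings=loadings,
        residual_a=residual_a,
        residual_e=residual_e,
    )
    model = common_pathway_model(4, 1, "AE")
    seeds = _child_seeds(seed, n_reps)
    shares = []
    for k in range(n_reps):
        wide = simulate_wide(true, n_mz, n_dz, seed=seeds[k])
        fr = fit(model, wide, n_starts=3, seed=seeds[k])
        shares.append(fr.quantity("factor_A_share"))
    shares = np.asarray(shares)
    return {
        "mean_factor_a_pct": float(100.0 * shares.mean()),
        "mc_se_pct": float(100.0 * shares.std(ddof=1) / np.sqrt(n_reps)),
        "true_factor_a_pct": float(100.0 * factor_a**2),
        "n_reps": n_reps,
        "n_pairs": n_mz + n_dz,
    }


def selection_consistency_study(
    generator: str = "cp1",
    n_reps: int = 100,
    n_mz: int = 200,
    n_dz: int = 200,
    seed: int = 0,
    n_starts: int = 3,
) -> dict:
    """Fraction of replicates in which the pipeline selects the generator.

    ``generator`` is ``"cp1"`` (one-factor common pathway AE truth) or
    ``"ar"`` (genetic + environmental simplex AE truth).
    """
    truths: dict[str, TrueModel] = {
        "cp1": true_common_pathway(),
        "ar": true_autoregression(),
    }
    if generator not in truths:
        raise ValueError(f"unknown generator {generator!r}")
    true = truths[generator]
    target = {"cp1": "cp1-ae", "ar": "ar-ae"}[generator]
    seeds = _child_seeds(seed, n_reps)
    selected = []
    for k in range(n_reps):
        wide = simulate_wide(true, n_mz, n_dz, seed=seeds[k])
        sel = model_selection_pipeline(
            wide, components="AE", n_starts=n_starts, seed=seeds[k], residual_a_tests=False
        )
        selected.append(sel.selected)
    hits = sum(s == target for s in selected)
    return {
        "target": target,
        "selection_rate_pct": 100.0 * hits / n_reps,
        "n_reps": n_reps,
        "n_pairs": n_mz + n_dz,
        "selected_counts": {s: selected.count(s) for s in sorted(set(selected))},
    }
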