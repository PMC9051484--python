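"""Synthetic longitudinal twin cohorts with known generating parameters.

Emulates the structure of a longitudinal twin study of predicted brain age
(PBA) in middle-aged men: three assessment waves roughly 5.5 years apart
with overlapping age ranges (means 56.1, 61.8, 67.5, SD 2.6), monozygotic
and dizygotic pairs plus pairs with one member entirely absent, a scanner
change after wave 1 (1.5T vs 3T), ethnicity-group mean shifts, and birth
cohort (birth years 1943-1955) trends.  Phenotypes are drawn from the
multivariate normal distribution implied by any supported genetic model over
the four chronological-age intervals 51-55, 56-60, 61-65 and 66-72, so the
preprocessing stage (age-anchoring + residualization) has exactly the
structure it must undo.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as tio
from .fiml import NonPositiveDefiniteError, TwinModel, pair_covariance
from .models import (
    autoregression_model,
    common_pathway_model,
    correlated_factors_model,
    univariate_model,
)
from .preprocess import DEFAULT_SCHEME, AgeIntervalScheme, assign_interval

__all__ = [
    "Wave",
    "CohortConfig",
    "TrueModel",
    "true_univariate",
    "true_common_pathway",
    "true_autoregression",
    "true_correlated_factors",
    "simulate_wide",
    "simulate_cohort",
    "DEFAULT_WAVES",
]

#: Assessment waves: mean age, SD and observed range, per the emulated study.
DEFAULT_WAVES = (
    (56.1, 2.6, 51.1, 60.2),
    (61.8, 2.6, 56.0, 65.9),
    (67.5, 2.6, 61.4, 71.7),
)

_ETHNICITY_PROBS = {
    "non_hispanic_white": 0.883,
    "african_american": 0.053,
    "hispanic": 0.034,
    "other": 0.030,
}


@dataclass(frozen=True)
class Wave:
    """One assessment wave's age-at-assessment distribution (years)."""

    mean: float
    sd: float
    min: float
    max: float

    def __post_init__(self):
        if not (self.min <= self.mean <= self.max) or self.sd <= 0:
            raise ValueError(f"invalid wave age distribution {self}")


@dataclass(frozen=True)
class CohortConfig:
    """Design of a simulated twin cohort.

    Defaults emulate the reference cohort: 734 men (170 MZ + 130 DZ complete
    pairs plus 134 singleton pairs), three waves at the published age
    distributions, birth years 1943-1955, a scanner upgrade after wave 1 and
    small ethnicity/cohort mean effects on the phenotype (units: years of
    predicted brain age).
    """

    n_mz_pairs: int = 170
    n_dz_pairs: int = 130
    n_incomplete_pairs: int = 134
    waves: tuple[Wave, ...] = tuple(Wave(*w) for w in DEFAULT_WAVES)
    participation: tuple[float, ...] | float = 0.8
    scanner_shift: float = 1.0
    cohort_slope: float = 0.1
    ethnicity_shifts: dict = field(
        default_factory=lambda: {
            "non_hispanic_white": 0.0,
            "african_american": 0.4,
            "hispanic": 0.3,
            "other": 0.2,
        }
    )
    birth_year_range: tuple[int, int] = (1943, 1955)
    pair_attrition: bool = False
    seed: int = 0

    def participation_by_wave(self) -> tuple[float, ...]:
        p = self.participation
        if np.isscalar(p):
            return tuple(float(p) for _ in self.waves)
        if len(p) != len(self.waves):
            raise ValueError("per-wave participation length must match number of waves")
        return tuple(float(x) for x in p)

    def __post_init__(self):
        if min(self.n_mz_pairs, self.n_dz_pairs, self.n_incomplete_pairs) < 0:
            raise ValueError("pair counts must be non-negative")
        if not self.waves:
            raise ValueError("at least one assessment wave is required")
        for p in self.participation_by_wave():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"participation probability {p} outside [0, 1]")
        if self.birth_year_range[0] > self.birth_year_range[1]:
            raise ValueError("birth_year_range must be (lo, hi) with lo <= hi")


@dataclass(frozen=True)
class TrueModel:
    """A generating model: a structural model plus its parameter values."""

    model: TwinModel
    params: np.ndarray

    @property
    def name(self) -> str:
        return self.model.name

    @property
    def n_vars(self) -> int:
        return self.model.n_vars


def true_univariate(components="AE", mean: float = 0.0, **paths) -> TrueModel:
    """E.g. ``true_univariate("AE", a=0.8, e=0.6)``."""
    model = univariate_model(components)
    mapping = dict(paths)
    mapping["mu_1"] = mean
    return TrueModel(model, model.vector_from(mapping))


def true_common_pathway(
    t: int = 4,
    factor_a: float = 0.86,
    loadings: float | tuple = 0.8,
    residual_a: float | tuple = 0.3,
    residual_e: float | tuple = 0.45,
    means: float | tuple = 0.0,
) -> TrueModel:
    """One-factor common pathway AE generator.

    The factor's environmental path is derived from the unit-variance
    constraint, so ``factor_a=0.86`` implies an environmental path of
    ``sqrt(1 - 0.86^2) ~= 0.51`` and a factor heritability of ~74%.
    """
    model = common_pathway_model(t, 1, "AE")
    mapping: dict[str, float] = {"fac1_a": factor_a}
    for i in range(t):
        mapping[f"lam1_{i + 1}"] = np.broadcast_to(loadings, (t,))[i]
        mapping[f"a_res_{i + 1}"] = np.broadcast_to(residual_a, (t,))[i]
        mapping[f"e_res_{i + 1}"] = np.broadcast_to(residual_e, (t,))[i]
        mapping[f"mu_{i + 1}"] = np.broadcast_to(means, (t,))[i]
    return TrueModel(model, model.vector_from(mapping))


def true_autoregression(
    t: int = 4,
    a_innovations: float | tuple = (0.8, 0.4, 0.4, 0.4),
    e_innovations: float | tuple = (0.5, 0.35, 0.35, 0.35),
    beta_a: float | tuple = 0.9,
    beta_e: float | tuple = 0.7,
    residual_e: float = 0.3,
    means: float | tuple = 0.0,
) -> TrueModel:
    """Genetic + environmental simplex AE generator with shared E residual."""
    model = autoregression_model(t, "AE")
    mapping: dict[str, float] = {"e_res": float(residual_e)}
    a_inn = np.broadcast_to(np.asarray(a_innovations, dtype=float)[: t] if np.ndim(a_innovations) else a_innovations, (t,))
    e_inn = np.broadcast_to(np.asarray(e_innovations, dtype=float)[: t] if np.ndim(e_innovations) else e_innovations, (t,))
    for i in range(t):
        mapping[f"a_inn_{i + 1}"] = a_inn[i]
        mapping[f"e_inn_{i + 1}"] = e_inn[i]
        mapping[f"mu_{i + 1}"] = np.broadcast_to(means, (t,))[i]
    for i in range(t - 1):
        mapping[f"beta_a_{i + 2}"] = np.broadcast_to(beta_a, (t - 1,))[i]
        mapping[f"beta_e_{i + 2}"] = np.broadcast_to(beta_e, (t - 1,))[i]
    return TrueModel(model, model.vector_from(mapping))


def true_correlated_factors(t: int = 4, components="AE", **paths) -> TrueModel:
    """Cholesky-path generator, e.g. ``a_11=0.8, a_21=0.5, ...``; means 0."""
    model = correlated_factors_model(t, components)
    return TrueModel(model, model.vector_from(paths))


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def _check_psd(true: TrueModel) -> dict[str, np.ndarray]:
    sigma = {}
    for zyg in ("MZ", "DZ"):
        s = pair_covariance(true.model, true.params, zyg)
        eigmin = float(np.linalg.eigvalsh(s).min())
        if eigmin < -1e-8:
            raise NonPositiveDefiniteError(
                f"implied pair covariance for {zyg} group is not PSD "
                f"(min eigenvalue {eigmin:.3g})",
                zygosity=zyg,
            )
        sigma[zyg] = s
    return sigma


def simulate_wide(
    true: TrueModel,
    n_mz: int,
    n_dz: int,
    seed: int | np.random.Generator = 0,
    *,
    family_offset: int = 0,
) -> pd.DataFrame:
    """Draw complete twin pairs from the model-implied pair distribution."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = _check_psd(true)
    mu_t = true.model.means(true.params)
    mu = np.concatenate([mu_t, mu_t])
    frames = []
    fam = family_offset
    for zyg, n in (("MZ", n_mz), ("DZ", n_dz)):
        draws = rng.multivariate_normal(mu, sigma[zyg], size=n, method="eigh")
        cols = tio.wide_columns(list(true.model.var_names))
        df = pd.DataFrame(draws, columns=cols[2:])
        df.insert(0, "family_id", [f"F{fam + i + 1:05d}" for i in range(n)])
        df.insert(1, "zygosity", zyg)
        fam += n
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _truncnorm(rng: np.random.Generator, wave: Wave, size: int) -> np.ndarray:
    """Truncated-normal ages by rejection (bounds are ~2 SD, so this is cheap)."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(wave.mean, wave.sd, size=2 * (size - filled) + 8)
        keep = draw[(draw >= wave.min) & (draw <= wave.max)][: size - filled]
        out[filled : filled + len(keep)] = keep
        filled += len(keep)
    return out


def simulate_cohort(
    config: CohortConfig,
    true: TrueModel | None = None,
    scheme: AgeIntervalScheme = DEFAULT_SCHEME,
    *,
    return_latent: bool = False,
):
    """Simulate a long-format assessment table under the configured design.

    Each subject carries a latent phenotype trajectory over the scheme's age
    intervals drawn by :func:`simulate_wide`; the phenotype recorded at a
    wave is the latent value of the interval containing that wave's age plus
    scanner, cohort and ethnicity effects.  Twins share birth year and age
    at assessment; within-subject wave ages are redrawn until increasing.
    Attrition is independent per subject and wave unless
    ``config.pair_attrition`` shares it within pairs.  With
    ``return_latent=True`` the noiseless latent wide table is returned
    alongside the long table (useful for pipeline round-trip checks).
    """
    if true is None:
        true = true_common_pathway(t=len(scheme.intervals))
    if true.n_vars != len(scheme.intervals):
        raise ValueError(
            f"generating model has {true.n_vars} variables but the interval "
            f"scheme has {len(scheme.intervals)}"
        )
    rng = np.random.default_rng(config.seed)
    n_inc_mz = config.n_incomplete_pairs // 2
    n_inc_dz = config.n_incomplete_pairs - n_inc_mz
    n_mz = config.n_mz_pairs + n_inc_mz
    n_dz = config.n_dz_pairs + n_inc_dz
    latent = simulate_wide(true, n_mz, n_dz, rng)
    # Mark which pairs are singletons (twin 2 entirely absent).
    incomplete = np.zeros(len(latent), dtype=bool)
    incomplete[config.n_mz_pairs : n_mz] = True
    incomplete[n_mz + config.n_dz_pairs :] = True

    participation = config.participation_by_wave()
    lo_by, hi_by = config.birth_year_range
    eth_names = list(_ETHNICITY_PROBS)
    eth_probs = np.array(list(_ETHNICITY_PROBS.values()))
    eth_probs = eth_probs / eth_probs.sum()
    by_mid = 0.5 * (lo_by + hi_by)
    var_names = list(true.model.var_names)

    records = []
    for row_i, row in latent.iterrows():
        fam = row["family_id"]
        zyg = row["zygosity"]
        birth_year = int(rng.integers(lo_by, hi_by + 1))
        ethnicity = eth_names[int(rng.choice(len(eth_names), p=eth_probs))]
        # wave ages shared within the pair; redraw until strictly increasing
        for _ in range(1000):
            ages = np.array([_truncnorm(rng, w, 1)[0] for w in config.waves])
            if np.all(np.diff(ages) > 0) or len(ages) == 1:
                break
        shared_attend = (
            rng.uniform(size=len(config.waves)) < np.array(participation)
            if config.pair_attrition
            else None
        )
        twins = (1,) if incomplete[row_i] else (1, 2)
        for twin in twins:
            suffix = "a" if twin == 1 else "b"
            attend = (
                shared_attend
                if shared_attend is not None
                else rng.uniform(size=len(config.waves)) < np.array(participation)
            )
            for w, wave in enumerate(config.waves):
                if not attend[w]:
                    continue
                age = ages[w]
                label = assign_interval(age, scheme)
                latent_value = row[f"{var_names[scheme.labels.index(label)]}_{suffix}"]
                scanner = "1.5T" if w == 0 else "3T"
                value = (
                    latent_value
                    + config.scanner_shift * (scanner == "3T")
                    + config.cohort_slope * (birth_year - by_mid)
                    + config.ethnicity_shifts.get(ethnicity, 0.0)
                )
                records.append(
                    (fam, twin, zyg, w + 1, age, birth_year, scanner, ethnicity, value)
                )
    long = pd.DataFrame(records, columns=tio.LONG_COLUMNS)
    return (long, latent) if return_latent else long
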