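"""Age-anchoring and covariate residualization of longitudinal twin data.

Assessment waves with overlapping age ranges are recoded into fixed
chronological-age intervals: each subject's score is assigned to the
interval containing their age at assessment (completed years, i.e. floor),
so two subjects aged 60 at different waves contribute to the same interval
variable.  A subject assessed twice within one interval keeps only the
first (earliest-wave) observation.  The result is a wide twin table with
structured missingness, the unit of full-information likelihood analysis.

Predicted brain age difference (PBAD) is chronological age minus predicted
brain age; negative values mean the brain is predicted older than its
chronological age.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from . import io as tio

__all__ = [
    "AgeInterval",
    "AgeIntervalScheme",
    "DEFAULT_SCHEME",
    "AnchorReport",
    "AnchoredData",
    "AgeOutOfRangeError",
    "derive_pbad",
    "assign_interval",
    "age_anchor",
    "residualize",
]


class AgeOutOfRangeError(ValueError):
    """An age at assessment falls outside every interval of the scheme."""

    def __init__(self, age: float, scheme: "AgeIntervalScheme"):
        super().__init__(
            f"age {age} (completed years {int(np.floor(age))}) is outside the "
            f"interval scheme {scheme.labels}"
        )
        self.age = age


@dataclass(frozen=True)
class AgeInterval:
    label: str
    lo: int  # inclusive, completed years
    hi: int  # inclusive

    def contains(self, completed_years: int) -> bool:
        return self.lo <= completed_years <= self.hi


@dataclass(frozen=True)
class AgeIntervalScheme:
    """Ordered, non-overlapping, contiguous chronological-age intervals."""

    intervals: tuple[AgeInterval, ...]

    def __post_init__(self):
        if not self.intervals:
            raise ValueError("interval scheme must contain at least one interval")
        for iv in self.intervals:
            if iv.lo > iv.hi:
                raise ValueError(f"interval {iv.label} has lo > hi")
        for prev, nxt in zip(self.intervals, self.intervals[1:]):
            if nxt.lo != prev.hi + 1:
                raise ValueError(
                    f"intervals {prev.label} and {nxt.label} are not contiguous "
                    "and ordered"
                )

    @property
    def labels(self) -> list[str]:
        return [iv.label for iv in self.intervals]

    @staticmethod
    def from_bounds(bounds: list[tuple[int, int]]) -> "AgeIntervalScheme":
        return AgeIntervalScheme(
            tuple(AgeInterval(f"{lo}-{hi}", int(lo), int(hi)) for lo, hi in bounds)
        )


#: 51-55, 56-60, 61-65, 66-72: the four intervals spanning ages 51-72.
DEFAULT_SCHEME = AgeIntervalScheme.from_bounds([(51, 55), (56, 60), (61, 65), (66, 72)])


def derive_pbad(pba, chronological_age):
    """Predicted brain age difference: chronological age - predicted age.

    Negative values indicate a brain predicted *older* than its chronological
    age.  Accepts scalars or arrays.
    """
    pba = np.asarray(pba, dtype=float)
    age = np.asarray(chronological_age, dtype=float)
    if not (np.all(np.isfinite(pba)) and np.all(np.isfinite(age))):
        raise ValueError("PBA and chronological age must be finite")
    out = age - pba
    return float(out) if out.ndim == 0 else out


def assign_interval(age: float, scheme: AgeIntervalScheme = DEFAULT_SCHEME) -> str:
    """Label of the interval containing ``floor(age)`` (completed years)."""
    completed = int(np.floor(age))
    for iv in scheme.intervals:
        if iv.contains(completed):
            return iv.label
    raise AgeOutOfRangeError(age, scheme)


@dataclass
class AnchorReport:
    """Tallies from age-anchoring a long table."""

    subjects_by_n_intervals: dict[int, int] = field(default_factory=dict)
    n_duplicates_dropped: int = 0
    n_out_of_range_dropped: int = 0
    n_subjects: int = 0
    n_pairs: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "subjects_by_n_intervals": {
                    str(k): v for k, v in sorted(self.subjects_by_n_intervals.items())
                },
                "n_duplicates_dropped": self.n_duplicates_dropped,
                "n_out_of_range_dropped": self.n_out_of_range_dropped,
                "n_subjects": self.n_subjects,
                "n_pairs": self.n_pairs,
            },
            indent=2,
        )


@dataclass
class AnchoredData:
    """Wide phenotype table plus the per-observation covariate table."""

    wide: pd.DataFrame
    covariates: pd.DataFrame  # one row per retained observation
    report: AnchorReport


def age_anchor(
    long: pd.DataFrame, scheme: AgeIntervalScheme = DEFAULT_SCHEME
) -> AnchoredData:
    """Recode wave-based records into interval-anchored wide twin rows.

    Records outside the scheme are reported and dropped.  A subject with
    two records in the same interval keeps the earliest wave only; two
    records for the same subject and wave are a data-integrity error.
    """
    report = AnchorReport()
    labels = scheme.labels
    if long.empty:
        wide = pd.DataFrame(columns=tio.wide_columns(labels))
        cov = pd.DataFrame(columns=list(long.columns) + ["interval"])
        return AnchoredData(wide, cov, report)

    dup = long.duplicated(subset=["family_id", "twin", "wave"])
    if dup.any():
        bad = long.loc[dup, ["family_id", "twin", "wave"]].to_dict("records")
        raise ValueError(f"duplicate subject/wave records: {bad}")

    kept_rows = []
    per_subject_intervals: dict[tuple, set] = {}
    zygosity: dict[str, str] = {}
    for (fam, twin), grp in long.groupby(["family_id", "twin"], sort=False):
        zygosity[fam] = grp["zygosity"].iloc[0]
        seen: dict[str, int] = {}
        for _, rec in grp.sort_values("wave").iterrows():
            try:
                label = assign_interval(rec["age"], scheme)
            except AgeOutOfRangeError:
                report.n_out_of_range_dropped += 1
                continue
            if label in seen:
                report.n_duplicates_dropped += 1
                continue
            seen[label] = 1
            row = rec.to_dict()
            row["interval"] = label
            kept_rows.append(row)
        if seen:
            per_subject_intervals[(fam, twin)] = set(seen)

    for ivset in per_subject_intervals.values():
        k = len(ivset)
        report.subjects_by_n_intervals[k] = report.subjects_by_n_intervals.get(k, 0) + 1
    report.n_subjects = len(per_subject_intervals)

    cov = pd.DataFrame(kept_rows)
    families = list(dict.fromkeys(fam for fam, _ in per_subject_intervals))
    report.n_pairs = len(families)
    wide = pd.DataFrame(
        {
            "family_id": families,
            "zygosity": [zygosity[f] for f in families],
        }
    )
    for label in labels:
        for twin, suffix in ((1, "a"), (2, "b")):
            wide[f"{label}_{suffix}"] = np.nan
    windex = {f: i for i, f in enumerate(families)}
    for row in kept_rows:
        suffix = "a" if int(row["twin"]) == 1 else "b"
        wide.loc[windex[row["family_id"]], f"{row['interval']}_{suffix}"] = row["phenotype"]
    return AnchoredData(wide, cov, report)


# ---------------------------------------------------------------------------
# Residualization
# ---------------------------------------------------------------------------

_KNOWN_TERMS = ("scanner", "age", "ethnicity", "cohort")


def _design(cov: pd.DataFrame, terms) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(cov))]
    names = ["intercept"]
    for term in terms:
        if term == "age":
            cols.append(cov["age"].to_numpy(float) - cov["age"].mean())
            names.append("age")
        elif term == "cohort":
            cols.append(cov["birth_year"].to_numpy(float) - cov["birth_year"].mean())
            names.append("cohort")
        elif term in ("scanner", "ethnicity"):
            levels = sorted(cov[term].astype(str).unique())
            for lev in levels[1:]:  # first level is the reference
                cols.append((cov[term].astype(str) == lev).to_numpy(float))
                names.append(f"{term}[{lev}]")
        else:
            raise ValueError(f"unknown covariate term {term!r}; known: {_KNOWN_TERMS}")
    return np.column_stack(cols), names


def _collinear_columns(x: np.ndarray, names: list[str]) -> list[str]:
    _, r, piv = linalg.qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return [names[piv[i]] for i in range(rank, x.shape[1])]


def residualize(
    wide: pd.DataFrame,
    covariates: pd.DataFrame,
    terms=("scanner", "age", "ethnicity", "cohort"),
) -> pd.DataFrame:
    """Replace each interval variable by its OLS residual on the covariates.

    Each interval variable is regressed independently (intercept included,
    both twins pooled as individuals) on the requested terms; age and birth
    year enter centered within interval, scanner and ethnicity as dummy
    codes.  Missing phenotypes stay missing.  A rank-deficient design raises
    an error naming the collinear columns.
    """
    labels = tio.wide_variable_names(wide)
    out = wide.copy()
    windex = {f: i for i, f in enumerate(wide["family_id"])}
    for label in labels:
        cov = covariates[covariates["interval"] == label]
        n_wide = int(wide[[f"{label}_a", f"{label}_b"]].notna().to_numpy().sum())
        if len(cov) != n_wide:
            raise ValueError(
                f"interval {label!r}: {n_wide} non-missing phenotypes but "
                f"{len(cov)} covariate rows; every observation needs covariates"
            )
        if cov.empty:
            continue
        x, names = _design(cov, terms)
        if np.linalg.matrix_rank(x) < x.shape[1]:
            bad = _collinear_columns(x, names)
            raise ValueError(
                f"rank-deficient design for interval {label!r}: collinear "
                f"columns {bad}"
            )
        y = cov["phenotype"].to_numpy(float)
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        for value, (_, rec) in zip(resid, cov.iterrows()):
            suffix = "a" if int(rec["twin"]) == 1 else "b"
            out.loc[windex[rec["family_id"]], f"{label}_{suffix}"] = value
    return out
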