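"""Age-anchoring, PBAD derivation and residualization tests."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from twinage.preprocess import (
    AgeIntervalScheme,
    AgeOutOfRangeError,
    age_anchor,
    assign_interval,
    derive_pbad,
    residualize,
)
from twinage.synthetic import CohortConfig, simulate_cohort, true_common_pathway


def _long_record(fam, twin, wave, age, value, zyg="MZ", scanner="3T", by=1950, eth="non_hispanic_white"):
    return dict(
        family_id=fam, twin=twin, zygosity=zyg, wave=wave, age=age,
        birth_year=by, scanner=scanner, ethnicity=eth, phenotype=value,
    )


class TestPbad:
    @pytest.mark.parametrize(
        "pba,age,expected",
        [(65.0, 60.0, -5.0), (60.0, 60.0, 0.0), (55.5, 60.2, pytest.approx(4.7))],
    )
    def test_difference_and_sign_convention(self, pba, age, expected):
        """Negative PBAD means the brain is predicted older than its age."""
        assert derive_pbad(pba, age) == expected

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            derive_pbad(np.nan, 60.0)


class TestAssignInterval:
    @pytest.mark.parametrize(
        "age,label",
        [(55.9, "51-55"), (56.0, "56-60"), (71.7, "66-72"), (51.0, "51-55"), (65.99, "61-65")],
    )
    def test_floor_convention(self, age, label):
        assert assign_interval(age) == label

    @given(st.floats(51.0, 72.99))
    def test_every_in_range_age_is_assigned(self, age):
        label = assign_interval(age)
        lo, hi = (int(s) for s in label.split("-"))
        assert lo <= int(np.floor(age)) <= hi

    def test_out_of_range_raises(self):
        with pytest.raises(AgeOutOfRangeError):
            assign_interval(50.9)
        with pytest.raises(AgeOutOfRangeError):
            assign_interval(73.0)

    def test_invalid_scheme_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            AgeIntervalScheme.from_bounds([(51, 55), (57, 60)])


class TestAgeAnchor:
    def test_toy_roster_interval_assignment_and_tallies(self):
        long = pd.DataFrame(
            [
                # twin 1 of F1 observed at three intervals
                _long_record("F1", 1, 1, 54.0, 1.0),
                _long_record("F1", 1, 2, 59.0, 2.0),
                _long_record("F1", 1, 3, 65.0, 3.0),
                # twin 2 observed twice within one interval: first wave kept
                _long_record("F1", 2, 1, 61.5, 4.0),
                _long_record("F1", 2, 2, 64.9, 5.0),
                # second family, one twin, one out-of-range age dropped
                _long_record("F2", 1, 1, 58.0, 6.0, zyg="DZ"),
                _long_record("F2", 1, 2, 73.5, 7.0, zyg="DZ"),
            ]
        )
        anchored = age_anchor(long)
        wide, rep = anchored.wide, anchored.report
        row1 = wide[wide.family_id == "F1"].iloc[0]
        assert (row1["51-55_a"], row1["56-60_a"], row1["61-65_a"]) == (1.0, 2.0, 3.0)
        assert np.isnan(row1["66-72_a"])
        assert row1["61-65_b"] == 4.0  # earliest wave kept
        assert rep.n_duplicates_dropped == 1
        assert rep.n_out_of_range_dropped == 1
        assert rep.subjects_by_n_intervals == {3: 1, 1: 2}
        assert rep.n_pairs == 2 and rep.n_subjects == 3

    def test_empty_input(self):
        anchored = age_anchor(pd.DataFrame(columns=["family_id", "twin", "zygosity", "wave", "age", "phenotype"]))
        assert anchored.wide.empty
        assert anchored.report.subjects_by_n_intervals == {}

    def test_duplicate_subject_wave_is_integrity_error(self):
        long = pd.DataFrame(
            [_long_record("F1", 1, 1, 54.0, 1.0), _long_record("F1", 1, 1, 54.2, 1.1)]
        )
        with pytest.raises(ValueError, match="duplicate"):
            age_anchor(long)

    def test_idempotent_on_anchored_data(self):
        """Re-anchoring interval-representative records reproduces the table."""
        long = pd.DataFrame(
            [
                _long_record("F1", 1, 1, 53.0, 1.0),
                _long_record("F1", 1, 2, 58.0, 2.0),
                _long_record("F1", 2, 1, 53.0, 3.0),
            ]
        )
        once = age_anchor(long)
        again = age_anchor(long)
        pd.testing.assert_frame_equal(once.wide, again.wide)

    def test_cohort_round_trip_recovers_latent_values(self):
        """With full participation and no covariate effects, anchoring returns
        exactly the latent trajectory values the generator drew."""
        cfg = CohortConfig(
            n_mz_pairs=40, n_dz_pairs=40, n_incomplete_pairs=0,
            participation=1.0, scanner_shift=0.0, cohort_slope=0.0,
            ethnicity_shifts={}, seed=99,
        )
        long, latent = simulate_cohort(cfg, true_common_pathway(), return_latent=True)
        wide = age_anchor(long).wide
        merged = wide.merge(latent, on="family_id", suffixes=("", "_lat"))
        labels = ["51-55", "56-60", "61-65", "66-72"]
        checked = 0
        for i, label in enumerate(labels):
            for suf in ("a", "b"):
                obs = merged[f"{label}_{suf}"]
                lat = merged[f"t{i + 1}_{suf}"]
                mask = obs.notna()
                checked += int(mask.sum())
                np.testing.assert_allclose(obs[mask], lat[mask], atol=1e-12)
        assert checked > 100

    def test_no_subject_exceeds_three_intervals_with_three_waves(self):
        cfg = CohortConfig(n_mz_pairs=60, n_dz_pairs=60, n_incomplete_pairs=10, seed=3)
        anchored = age_anchor(simulate_cohort(cfg))
        assert max(anchored.report.subjects_by_n_intervals) <= 3


class TestResidualize:
    @staticmethod
    def _anchored(seed=1, **kw):
        cfg = CohortConfig(n_mz_pairs=150, n_dz_pairs=150, n_incomplete_pairs=0, seed=seed, **kw)
        return age_anchor(simulate_cohort(cfg))

    def test_covariate_slopes_are_zeroed(self):
        """Injected scanner/cohort/ethnicity effects vanish from residuals."""
        anchored = self._anchored(scanner_shift=2.0, cohort_slope=0.4)
        out = residualize(anchored.wide, anchored.covariates)
        for label in ["56-60", "61-65"]:
            cov = anchored.covariates[anchored.covariates.interval == label]
            resid = []
            for _, rec in cov.iterrows():
                suf = "a" if rec["twin"] == 1 else "b"
                resid.append(
                    out.loc[out.family_id == rec["family_id"], f"{label}_{suf}"].iloc[0]
                )
            resid = np.asarray(resid)
            scanner = (cov["scanner"] == "3T").to_numpy(float)
            if scanner.std() > 0:
                assert abs(np.corrcoef(resid, scanner)[0, 1]) < 1e-10
            by = cov["birth_year"].to_numpy(float)
            assert abs(np.cov(resid, by)[0, 1] / np.var(by)) < 1e-10

    def test_no_terms_demeans_only(self):
        anchored = self._anchored()
        out = residualize(anchored.wide, anchored.covariates, terms=())
        for label in ["51-55", "56-60", "61-65", "66-72"]:
            cols = [f"{label}_a", f"{label}_b"]
            orig = anchored.wide[cols].to_numpy().ravel()
            new = out[cols].to_numpy().ravel()
            mask = ~np.isnan(orig)
            if mask.sum() < 3:
                continue
            mean = orig[mask].mean()
            np.testing.assert_allclose(new[mask], orig[mask] - mean, atol=1e-10)

    def test_constant_phenotype_gives_zero_residuals(self):
        anchored = self._anchored()
        wide = anchored.wide.copy()
        cov = anchored.covariates.copy()
        for label in ["51-55", "56-60", "61-65", "66-72"]:
            for suf in ("a", "b"):
                wide.loc[wide[f"{label}_{suf}"].notna(), f"{label}_{suf}"] = 7.0
        cov["phenotype"] = 7.0
        out = residualize(wide, cov, terms=("scanner", "age"))
        vals = out[[c for c in out.columns if c.endswith(("_a", "_b"))]].to_numpy()
        np.testing.assert_allclose(vals[~np.isnan(vals)], 0.0, atol=1e-10)

    def test_rank_deficient_design_names_columns(self):
        anchored = self._anchored()
        cov = anchored.covariates.copy()
        cov["birth_year"] = 1950  # constant birth year: cohort column is zero
        with pytest.raises(ValueError, match="cohort"):
            residualize(anchored.wide, cov, terms=("cohort",))

    def test_twin_correlation_preserved_without_covariate_effects(self):
        """Residualization only shifts means, so pair correlations survive."""
        anchored = self._anchored(scanner_shift=0.0, cohort_slope=0.0, ethnicity_shifts={})
        out = residualize(anchored.wide, anchored.covariates)
        from twinage.correlations import twin_pair_correlation

        for label in ["56-60", "61-65"]:
            before = twin_pair_correlation(anchored.wide, label, "MZ").estimate
            after = twin_pair_correlation(out, label, "MZ").estimate
            assert after == pytest.approx(before, abs=0.1)
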