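"""Model-zoo tests: structure, implied moments vs path-tracing, summaries."""
import numpy as np
import pytest

import twinage as tw
from twinage.fiml import fit, pair_covariance
from twinage.models import (
    autoregression_model,
    common_pathway_model,
    component_correlations,
    correlated_factors_model,
    independent_pathway_model,
    model_by_name,
    standardize,
    univariate_model,
)

from _oracles import ram_pair_covariance


def _random_point(model, rng):
    """Random admissible full parameter vector for a model."""
    theta = model.start_full
    for i, p in enumerate(model.params):
        if not p.free:
            continue
        lo = p.lower if np.isfinite(p.lower) else -1.2
        hi = p.upper if np.isfinite(p.upper) else 1.2
        theta[i] = rng.uniform(lo + 0.05, hi)
    return theta


MODELS = [
    univariate_model("ACE"),
    univariate_model("AE"),
    correlated_factors_model(4, "AE"),
    correlated_factors_model(3, "ACE"),
    autoregression_model(4, "AE"),
    autoregression_model(4, "AE", residual_structure="free"),
    autoregression_model(3, "AE", genetic_residuals=True),
    common_pathway_model(4, 1, "AE"),
    common_pathway_model(4, 2, "AE"),
    common_pathway_model(4, 1, "CE"),
    common_pathway_model(3, 1, "E"),
    independent_pathway_model(4, "AE"),
]


@pytest.mark.parametrize("model", MODELS, ids=lambda m: m.name)
@pytest.mark.parametrize("zygosity", ["MZ", "DZ"])
def test_implied_covariance_matches_ram_oracle(model, zygosity):
    """Structural build equals full RAM path-tracing enumeration to 1e-10."""
    rng = np.random.default_rng(abs(hash(model.name)) % 2**31)
    for _ in range(3):
        theta = _random_point(model, rng)
        ours = pair_covariance(model, theta, zygosity)
        oracle = ram_pair_covariance(model, theta, zygosity)
        np.testing.assert_allclose(ours, oracle, atol=1e-10)


class TestStructure:
    def test_univariate_parameter_counts(self):
        assert univariate_model("ACE").n_free == 4  # a, c, e + mean
        assert univariate_model("AE").n_free == 3
        with pytest.raises(ValueError, match="E must be included"):
            univariate_model("AC")

    def test_correlated_factors_counts(self):
        m = correlated_factors_model(4, "AE")
        assert m.n_free == 2 * 10 + 4  # two triangles + means

    def test_independent_pathway_counts(self):
        m = independent_pathway_model(4, "AE")
        assert m.n_free == 8 + 8 + 4  # loadings + residuals + means

    def test_cp_identification_guards(self):
        with pytest.raises(ValueError):
            common_pathway_model(2, 1)
        with pytest.raises(ValueError):
            common_pathway_model(3, 2)
        with pytest.raises(ValueError):
            common_pathway_model(4, 3)

    def test_model_by_name(self):
        assert model_by_name("uni-ae").name == "uni-ae"
        assert model_by_name("cp1", t=4).meta["n_factors"] == 1
        assert model_by_name("cf", t=3, components="ACE").name == "cf-ace"
        with pytest.raises(ValueError):
            model_by_name("growth")


class TestAutoregression:
    def test_zero_transmission_severs_cross_covariances(self):
        m = autoregression_model(3, "AE")
        mapping = {f"a_inn_{i}": 0.7 for i in (1, 2, 3)}
        mapping.update({f"e_inn_{i}": 0.5 for i in (1, 2, 3)})
        mapping.update({"beta_a_2": 0, "beta_a_3": 0, "beta_e_2": 0, "beta_e_3": 0, "e_res": 0.3})
        a, _, e = m.components(m.vector_from(mapping))
        assert np.allclose(a - np.diag(np.diag(a)), 0)
        assert np.allclose(e - np.diag(np.diag(e)), 0)

    def test_perfect_transmission_gives_unit_correlations(self):
        m = autoregression_model(3, "AE")
        mapping = {"a_inn_1": 0.8, "a_inn_2": 0.0, "a_inn_3": 0.0,
                   "beta_a_2": 1.0, "beta_a_3": 1.0,
                   "e_inn_1": 0.0, "e_inn_2": 0.0, "e_inn_3": 0.0,
                   "beta_e_2": 0.0, "beta_e_3": 0.0, "e_res": 0.0}
        a, _, _ = m.components(m.vector_from(mapping))
        corr = a / np.sqrt(np.outer(np.diag(a), np.diag(a)))
        np.testing.assert_allclose(corr, 1.0)


class TestCommonPathway:
    def test_no_genetic_residuals_implies_unit_genetic_correlations(self):
        m = common_pathway_model(4, 1, "AE")
        mapping = {"fac1_a": 0.86, **{f"lam1_{i}": 0.8 for i in range(1, 5)},
                   **{f"a_res_{i}": 0.0 for i in range(1, 5)},
                   **{f"e_res_{i}": 0.45 for i in range(1, 5)}}
        a, _, _ = m.components(m.vector_from(mapping))
        rg = a / np.sqrt(np.outer(np.diag(a), np.diag(a)))
        np.testing.assert_allclose(rg, 1.0, atol=1e-12)

    def test_equal_loadings_no_residuals_is_compound_symmetric(self):
        m = common_pathway_model(4, 1, "AE")
        mapping = {"fac1_a": 0.7, **{f"lam1_{i}": 0.9 for i in range(1, 5)},
                   **{f"a_res_{i}": 0.0 for i in range(1, 5)},
                   **{f"e_res_{i}": 0.0 for i in range(1, 5)}}
        a, c, e = m.components(m.vector_from(mapping))
        total = a + c + e
        off = total[~np.eye(4, dtype=bool)]
        assert np.ptp(off) < 1e-12 and np.ptp(np.diag(total)) < 1e-12

    def test_two_factor_nests_one_factor(self):
        cp1, cp2 = common_pathway_model(4, 1), common_pathway_model(4, 2)
        assert cp2.n_free - cp1.n_free == 4  # 3 free loadings + 1 factor split
        mapping1 = {"fac1_a": 0.8, **{f"lam1_{i}": 0.6 for i in range(1, 5)},
                    **{f"a_res_{i}": 0.2 for i in range(1, 5)},
                    **{f"e_res_{i}": 0.4 for i in range(1, 5)}}
        mapping2 = dict(mapping1, fac2_a=0.5, **{f"lam2_{i}": 0.0 for i in range(2, 5)})
        np.testing.assert_allclose(
            pair_covariance(cp1, cp1.vector_from(mapping1), "DZ"),
            pair_covariance(cp2, cp2.vector_from(mapping2), "DZ"),
            atol=1e-12,
        )


class TestIndependentPathway:
    def test_proportional_loadings_reduce_to_common_pathway(self):
        """lam_a = sqrt(s) lam, lam_e = sqrt(1-s) lam reproduces CP covariance."""
        s, lam = 0.74, np.array([0.8, 0.7, 0.9, 0.6])
        ip = independent_pathway_model(4, "AE")
        cp = common_pathway_model(4, 1, "AE")
        res_a = [0.3, 0.25, 0.2, 0.35]
        res_e = [0.45, 0.4, 0.5, 0.3]
        ip_map = {}
        cp_map = {"fac1_a": np.sqrt(s)}
        for i in range(4):
            ip_map[f"lam_a{i + 1}"] = np.sqrt(s) * lam[i]
            ip_map[f"lam_e{i + 1}"] = np.sqrt(1 - s) * lam[i]
            ip_map[f"a_res_{i + 1}"] = res_a[i]
            ip_map[f"e_res_{i + 1}"] = res_e[i]
            cp_map[f"lam1_{i + 1}"] = lam[i]
            cp_map[f"a_res_{i + 1}"] = res_a[i]
            cp_map[f"e_res_{i + 1}"] = res_e[i]
        for zyg in ("MZ", "DZ"):
            np.testing.assert_allclose(
                pair_covariance(ip, ip.vector_from(ip_map), zyg),
                pair_covariance(cp, cp.vector_from(cp_map), zyg),
                atol=1e-12,
            )

    def test_zero_environmental_loadings_make_e_diagonal(self):
        ip = independent_pathway_model(3, "AE")
        mapping = {f"lam_e{i}": 0.0 for i in (1, 2, 3)}
        _, _, e = ip.components(ip.vector_from(mapping))
        assert np.allclose(e, np.diag(np.diag(e)))


class TestSummaries:
    def test_standardized_components_sum_to_one(self, cp_wide):
        fr = fit(common_pathway_model(4, 1, "AE"), cp_wide, n_starts=2, seed=3)
        dec = standardize(fr)
        np.testing.assert_allclose(dec.standardized.sum(axis=1), 1.0, atol=1e-6)
        assert ((dec.standardized >= 0) & (dec.standardized <= 1)).all().all()

    def test_cp_total_a_equals_common_plus_residual(self, cp_wide):
        """Per-variable total A from components equals factor + residual split."""
        m = common_pathway_model(4, 1, "AE")
        fr = fit(m, cp_wide, n_starts=2, seed=3)
        dec = standardize(fr)
        sigma_a, _, _ = m.components(fr.params)
        total = np.diag(sum(m.components(fr.params)))
        lam = fr.params[m.meta["load_idx"][0]]
        s_a = fr.estimates["fac1_a"] ** 2
        res_a = np.array([fr.estimates[f"a_res_{i}"] ** 2 for i in range(1, 5)])
        np.testing.assert_allclose(np.diag(sigma_a), s_a * lam**2 + res_a, atol=1e-12)
        np.testing.assert_allclose(
            dec.standardized["A"].to_numpy(), np.diag(sigma_a) / total, atol=1e-12
        )

    def test_diagonal_genetic_cholesky_gives_identity_rg(self):
        m = correlated_factors_model(3, "AE")
        mapping = {}
        for i, j in zip(*np.tril_indices(3)):
            for comp in "ae":
                diag = 0.8 if comp == "a" else 0.5
                mapping[f"{comp}_{i + 1}{j + 1}"] = diag if i == j else 0.0
        theta = m.vector_from(mapping)
        from twinage.fiml import FitResult

        fr = FitResult(m, theta, 0.0, m.n_free, True, 10, 10)
        cc = component_correlations(fr)
        np.testing.assert_allclose(cc.rG.to_numpy(), np.eye(3), atol=1e-12)

    def test_nesting_holds_empirically(self, cp_wide):
        """Fitted correlated factors -2lnL is below every structured model's."""
        cf = fit(correlated_factors_model(4, "AE"), cp_wide, n_starts=3, seed=0)
        for m in (
            autoregression_model(4, "AE"),
            common_pathway_model(4, 1, "AE"),
            independent_pathway_model(4, "AE"),
        ):
            fr = fit(m, cp_wide, n_starts=3, seed=0)
            assert cf.minus2lnL <= fr.minus2lnL + 1e-4
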