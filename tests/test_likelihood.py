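import math

import numpy as np
import pytest

from triogxe import (
    GRRModelSpec,
    GRRParams,
    TrioDataset,
    TrioRecord,
    TrioSimConfig,
    child_genotype_probs,
    fit,
    log_grr,
    lrt_gxe,
    mendelian_probs,
    modifying_effect,
    simulate_trios,
    total_loglik,
)

from conftest import random_params, random_small_dataset


def oracle_loglik(data: TrioDataset, params: GRRParams, spec: GRRModelSpec) -> float:
    """Brute-force likelihood: enumerate compatible child genotypes per trio
    and normalize explicitly. Independent of the vectorized implementation."""
    total = 0.0
    for rec in data.records():
        m = mendelian_probs(rec.g_mother, rec.g_father)
        weights = []
        for g in range(3):
            lg = sum(
                log_grr(i, rec.exposure, rec.covariates, params, spec)
                for i in range(1, g + 1)
            )
            weights.append(m[g] * math.exp(lg))
        total += math.log(weights[rec.g_child] / sum(weights))
    return total


class TestLogGRR:
    def test_zero_params(self):
        spec = GRRModelSpec(k_covariates=1)
        p = GRRParams.zeros(spec)
        assert log_grr(1, 2.5, [1.0], p, spec) == 0.0

    def test_direct_substitution(self):
        # the generative values: beta_1 = log(3)/2, beta_1E = -0.10, e = 2
        spec = GRRModelSpec(k_covariates=0)
        p = GRRParams.zeros(spec)
        p.beta[0] = math.log(3) / 2
        p.beta_e[0] = -0.10
        assert log_grr(1, 2.0, [], p, spec) == pytest.approx(math.log(3) / 2 - 0.2)

    def test_covariate_main_effect_at_zero_exposure(self):
        # at e = 0, the log-GRR is the genetic main effect beta + beta_X x
        spec = GRRModelSpec(k_covariates=1)
        rng = np.random.default_rng(0)
        p = random_params(rng, spec)
        got = log_grr(2, 0.0, [1.0], p, spec)
        assert got == pytest.approx(p.beta[1] + p.beta_x[1, 0])

    def test_additive_levels_identical(self):
        spec = GRRModelSpec(genetic_model="additive", k_covariates=2)
        p = random_params(np.random.default_rng(1), spec)
        x = [0.3, -0.7]
        assert log_grr(1, 1.5, x, p, spec) == log_grr(2, 1.5, x, p, spec)

    def test_dimension_mismatch(self):
        spec = GRRModelSpec(k_covariates=2)
        with pytest.raises(ValueError):
            log_grr(1, 0.0, [1.0], GRRParams.zeros(spec), spec)


class TestChildGenotypeProbs:
    def test_null_params_reduce_to_mendel(self):
        spec = GRRModelSpec(k_covariates=0)
        rec = TrioRecord(1, 1, 1, exposure=0.7)
        np.testing.assert_allclose(
            child_genotype_probs(rec, GRRParams.zeros(spec), spec),
            mendelian_probs(1, 1),
        )

    def test_het_by_homref_with_grr2(self):
        # parents (1,0): children 0 or 1 equally likely a priori; GRR_1 = 2
        # tilts to P(1) = 2/3 for any exposure
        spec = GRRModelSpec(k_covariates=0)
        p = GRRParams.zeros(spec)
        p.beta[0] = math.log(2)
        for e in (-1.0, 0.0, 3.0):
            rec = TrioRecord(1, 1, 0, exposure=e)
            got = child_genotype_probs(rec, p, spec)
            np.testing.assert_allclose(got, [1 / 3, 2 / 3, 0.0], atol=1e-12)

    def test_noninformative_trio_degenerate(self):
        spec = GRRModelSpec(k_covariates=0)
        p = random_params(np.random.default_rng(2), spec)
        rec = TrioRecord(0, 0, 0, exposure=1.0)
        np.testing.assert_allclose(child_genotype_probs(rec, p, spec), [1, 0, 0])

    def test_sums_to_one_random(self):
        rng = np.random.default_rng(3)
        for model in ("codominant", "additive"):
            spec = GRRModelSpec(genetic_model=model, k_covariates=2)
            p = random_params(rng, spec, scale=1.5)
            rec = TrioRecord(1, 1, 2, exposure=rng.normal(), covariates=rng.normal(size=2))
            assert child_genotype_probs(rec, p, spec).sum() == pytest.approx(1.0)


class TestTotalLoglik:
    def test_single_trio_null(self):
        spec = GRRModelSpec(k_covariates=0)
        ds = TrioDataset(g_child=[1], g_mother=[1], g_father=[0], exposure=[0.0])
        assert total_loglik(ds, GRRParams.zeros(spec), spec) == pytest.approx(
            math.log(0.5)
        )

    def test_additivity_over_trios(self):
        spec = GRRModelSpec(k_covariates=0)
        p = random_params(np.random.default_rng(4), spec)
        one = TrioDataset(g_child=[1], g_mother=[1], g_father=[2], exposure=[0.4])
        two = TrioDataset(
            g_child=[1, 1], g_mother=[1, 1], g_father=[2, 2], exposure=[0.4, 0.4]
        )
        assert total_loglik(two, p, spec) == pytest.approx(
            2 * total_loglik(one, p, spec)
        )

    def test_noninformative_constant_in_params(self):
        spec = GRRModelSpec(k_covariates=0)
        ds = TrioDataset(g_child=[1, 2], g_mother=[0, 2], g_father=[2, 2],
                         exposure=[0.1, 0.2])
        rng = np.random.default_rng(5)
        for _ in range(3):
            assert total_loglik(ds, random_params(rng, spec), spec) == pytest.approx(
                0.0, abs=1e-12
            )

    @pytest.mark.parametrize("model,k", [("codominant", 0), ("codominant", 2),
                                         ("additive", 1)])
    def test_matches_bruteforce_oracle(self, model, k):
        """Vectorized likelihood equals explicit per-trio enumeration to
        1e-10 on 50 random small datasets."""
        rng = np.random.default_rng(6)
        for _ in range(50):
            ds = random_small_dataset(rng, n=int(rng.integers(4, 16)), k=k)
            spec = GRRModelSpec(genetic_model=model, k_covariates=k)
            p = random_params(rng, spec)
            assert total_loglik(ds, p, spec) == pytest.approx(
                oracle_loglik(ds, p, spec), abs=1e-10
            )

    def test_additive_equals_tied_codominant(self):
        """The additive model is the codominant model with both genotype
        levels sharing one parameter set."""
        rng = np.random.default_rng(7)
        ds = random_small_dataset(rng, n=30, k=1)
        add = GRRModelSpec(genetic_model="additive", k_covariates=1)
        cod = GRRModelSpec(genetic_model="codominant", k_covariates=1)
        pa = random_params(rng, add)
        pc = GRRParams(
            beta=np.repeat(pa.beta, 2),
            beta_x=np.repeat(pa.beta_x, 2, axis=0),
            beta_e=np.repeat(pa.beta_e, 2),
            beta_ex=np.repeat(pa.beta_ex, 2, axis=0),
        )
        assert total_loglik(ds, pa, add) == pytest.approx(
            total_loglik(ds, pc, cod), abs=1e-12
        )


class TestFit:
    def test_recovers_main_effect_single_stratum(self, single_stratum_data):
        """With the test locus in complete LD with the causal locus, the
        fitted per-level intercepts recover beta_g = log(3)/2 within 3 SE."""
        spec = GRRModelSpec(k_covariates=0)
        res = fit(single_stratum_data, spec)
        assert res.converged
        truth = math.log(3) / 2
        for l in range(2):
            se = math.sqrt(res.covariance[l * 2, l * 2])
            assert abs(res.params.beta[l] - truth) < 3 * se

    def test_nesting_full_geq_null(self, two_strata_null_data):
        from triogxe.adjustment import stratum_dummies

        ds = two_strata_null_data.with_covariates(
            stratum_dummies(two_strata_null_data.stratum)
        )
        spec = GRRModelSpec(k_covariates=1)
        full = fit(ds, spec)
        null = fit(ds, spec.null())
        assert full.loglik >= null.loglik - 1e-9

    def test_loglik_not_below_start(self):
        rng = np.random.default_rng(8)
        ds = random_small_dataset(rng, n=40, k=0)
        spec = GRRModelSpec(k_covariates=0)
        start = random_params(rng, spec)
        res = fit(ds, spec, start=start)
        assert res.loglik >= total_loglik(ds, start, spec) - 1e-9

    def test_no_informative_trios_errors(self):
        ds = TrioDataset(g_child=[0], g_mother=[0], g_father=[0], exposure=[0.0])
        with pytest.raises(ValueError, match="informative"):
            fit(ds, GRRModelSpec(k_covariates=0))

    def test_covariance_symmetric_psd(self, single_stratum_data):
        res = fit(single_stratum_data, GRRModelSpec(k_covariates=0))
        np.testing.assert_allclose(res.covariance, res.covariance.T)
        assert np.all(np.linalg.eigvalsh(res.covariance) > -1e-10)


class TestLRT:
    @pytest.mark.parametrize("model,k,df", [
        ("codominant", 1, 4), ("codominant", 2, 6), ("codominant", 3, 8),
        ("additive", 1, 2), ("additive", 0, 1), ("codominant", 0, 2),
    ])
    def test_degrees_of_freedom(self, model, k, df):
        assert GRRModelSpec(genetic_model=model, k_covariates=k).df_interaction == df

    def test_lrt_on_null_data(self, two_strata_null_data):
        from triogxe.adjustment import stratum_dummies

        ds = two_strata_null_data.with_covariates(
            stratum_dummies(two_strata_null_data.stratum)
        )
        res = lrt_gxe(ds, GRRModelSpec(k_covariates=1))
        assert res.df == 4
        assert res.statistic >= 0.0
        assert 0.0 <= res.p_value <= 1.0

    def test_invariant_to_affine_covariate_and_exposure_shift(
        self, two_strata_null_data
    ):
        """The LRT statistic is unchanged by rescaling covariate columns and
        shifting the exposure (the model re-parametrizes)."""
        from triogxe.adjustment import stratum_dummies

        base = two_strata_null_data.with_covariates(
            stratum_dummies(two_strata_null_data.stratum)
        )
        spec = GRRModelSpec(k_covariates=1)
        r1 = lrt_gxe(base, spec)
        shifted = TrioDataset(
            base.g_child, base.g_mother, base.g_father,
            base.exposure + 5.0, 3.0 * base.covariates - 1.0,
        )
        r2 = lrt_gxe(shifted, spec)
        assert r2.statistic == pytest.approx(r1.statistic, abs=1e-5)

    def test_result_table_roundtrip(self, tmp_path, two_strata_null_data):
        import pandas as pd

        from triogxe.adjustment import stratum_dummies

        ds = two_strata_null_data.with_covariates(
            stratum_dummies(two_strata_null_data.stratum)
        )
        res = lrt_gxe(ds, GRRModelSpec(k_covariates=1))
        path = tmp_path / "lrt.tsv"
        res.write(path)
        back = pd.read_csv(path, sep="\t")
        assert back.loc[0, "df"] == res.df
        assert back.loc[0, "p_value"] == pytest.approx(res.p_value)


class TestModifyingEffect:
    def test_exponentiates_interaction(self, single_stratum_data):
        spec = GRRModelSpec(k_covariates=0)
        res = fit(single_stratum_data, spec)
        est, lo, hi = modifying_effect(res, [], level=1)
        assert est == pytest.approx(math.exp(res.params.beta_e[0]))
        assert lo < est < hi

    def test_recovers_stratum_specific_interactions(self):
        """Two complete-LD strata with opposite-sign LD: a causal
        interaction beta_gE appears at the test locus with opposite signs,
        and the dummy-adjusted fit recovers both within 3 SE."""
        cfg = TrioSimConfig.for_strata(2, n_trios=3000, beta_gE=-0.20, seed=9)
        ds = simulate_trios(cfg)
        from triogxe.adjustment import stratum_dummies

        ds = ds.with_covariates(stratum_dummies(ds.stratum))
        spec = GRRModelSpec(k_covariates=1)
        res = fit(ds, spec)
        assert res.converged
        d, K = spec.d_per_level, 1
        for level, truth in ((1, 0.20), (2, 0.20)):
            # stratum 0 has r = -1: the slope at the test locus is -beta_gE
            est0, lo0, hi0 = modifying_effect(res, [0.0], level=level)
            est1, lo1, hi1 = modifying_effect(res, [1.0], level=level)
            l = level - 1
            se0 = math.sqrt(res.covariance[l * d + 1 + K, l * d + 1 + K])
            assert abs(math.log(est0) - truth) < 3 * se0
            c = np.zeros(spec.n_params)
            c[l * d + 1 + K] = 1.0
            c[l * d + 2 + K] = 1.0
            se1 = math.sqrt(c @ res.covariance @ c)
            assert abs(math.log(est1) - (-truth)) < 3 * se1

    def test_requires_interaction_terms(self, single_stratum_data):
        res = fit(single_stratum_data, GRRModelSpec(k_covariates=0).null())
        with pytest.raises(ValueError):
            modifying_effect(res, [])
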