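import math

import numpy as np
import pandas as pd
import pytest

from strokeconn import mediation as med
from strokeconn import synthetic_cohort as sc


def make_cohort_frame(n=2000, seed=0, **param_kwargs):
    params = sc.GenerativeParams(**param_kwargs)
    cohort = sc.generate_cohort(params, n, seed=seed)
    df = cohort.frame.copy()
    df["log_vol_T1"] = np.log(df["vol_T1"])
    return df, params


COVARIATES = ["age", "nihss", "log_vol_T1"]
ALL_MEDIATORS = ["log2_growth"] + [f"dchaco_{i:02d}" for i in range(8)]


class TestNaturalEffects:
    def test_worked_identity(self):
        probs = med.CounterfactualProbs(p_t_m_t=0.6, p_t_m_p=0.5, p_p_m_p=0.4)
        eff = med.natural_effects(probs)
        assert eff.nde == pytest.approx(1.5)
        assert eff.nie == pytest.approx(1.5)
        assert eff.te == pytest.approx(2.25)
        assert eff.proportion_mediated == pytest.approx(0.5)

    def test_null_probs_flagged(self):
        eff = med.natural_effects(med.CounterfactualProbs(0.5, 0.5, 0.5))
        assert eff.nde == eff.nie == eff.te == 1.0
        assert not eff.pm_defined

    def test_swapping_arms_inverts(self):
        a = med.natural_effects(med.CounterfactualProbs(0.6, 0.5, 0.4))
        b = med.natural_effects(med.CounterfactualProbs(0.4, 0.5, 0.6))
        assert b.nie == pytest.approx(1 / a.nie)
        assert b.nde == pytest.approx(1 / a.nde)
        assert b.te == pytest.approx(1 / a.te)

    def test_boundary_probability_rejected(self):
        with pytest.raises(ValueError):
            med.CounterfactualProbs(1.0, 0.5, 0.5)

    def test_te_identity_always(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.uniform(0.05, 0.95, size=3)
            eff = med.natural_effects(med.CounterfactualProbs(*p))
            assert eff.te == pytest.approx(eff.nie * eff.nde, rel=1e-12)


class TestCounterfactualProbs:
    def test_constant_mediator_gives_nie_one(self):
        df, _ = make_cohort_frame(n=400, seed=1)
        df["const_med"] = 1.0
        eff = med.estimate_natural_effects(df, ["const_med"], COVARIATES)
        assert eff.nie == pytest.approx(1.0, abs=1e-6)

    def test_missing_outcomes_excluded(self):
        df, _ = make_cohort_frame(n=400, seed=2)
        df.loc[df.index[:50], "favorable"] = np.nan
        probs = med.counterfactual_probabilities(df, ["log2_growth"], COVARIATES)
        assert 0 < probs.p_p_m_p < 1

    def test_oracle_recovery_large_sample(self):
        df, params = make_cohort_frame(n=20000, seed=3)
        oracle = sc.oracle_natural_effects(params, n_mc=400000, seed=10)
        est = med.estimate_natural_effects(df, ALL_MEDIATORS, COVARIATES)
        # coarse consistency check at large n (acceptance tightens this)
        assert est.nie == pytest.approx(oracle.nie, rel=0.08)
        assert est.nde == pytest.approx(oracle.nde, rel=0.12)
        assert est.te == pytest.approx(oracle.te, rel=0.10)

    def test_nonoverlap_raises(self):
        df, _ = make_cohort_frame(n=300, seed=4)
        with pytest.raises(med.NonOverlapError):
            med.counterfactual_probabilities(
                df, ["log2_growth"], COVARIATES, overlap_floor=0.9
            )

    def test_shared_base_fit_matches_individual(self):
        df, _ = make_cohort_frame(n=500, seed=5)
        specs = {"g": ["log2_growth"], "g2": ["log2_growth", "dchaco_01"]}
        joint = med.estimate_models(df, specs, COVARIATES)
        for name, meds in specs.items():
            single = med.estimate_natural_effects(df, meds, COVARIATES)
            assert joint[name].nie == pytest.approx(single.nie, rel=1e-12)


class TestBootstrap:
    @pytest.fixture(scope="class")
    def reps(self):
        df, _ = make_cohort_frame(n=400, seed=6)
        specs = {
            "growth_only": ["log2_growth"],
            "joint": ["log2_growth", "dchaco_01", "dchaco_02"],
        }
        return med.bootstrap_effects(df, specs, COVARIATES, k=200, seed=11)

    def test_deterministic(self):
        df, _ = make_cohort_frame(n=300, seed=7)
        specs = {"g": ["log2_growth"]}
        r1 = med.bootstrap_effects(df, specs, COVARIATES, k=100, seed=3)
        r2 = med.bootstrap_effects(df, specs, COVARIATES, k=100, seed=3)
        assert np.array_equal(r1.frames["g"].to_numpy(), r2.frames["g"].to_numpy())

    def test_te_identity_every_replicate(self, reps):
        for fr in reps.frames.values():
            assert np.allclose(fr["te"], fr["nde"] * fr["nie"], rtol=1e-10)

    def test_overlapping_models_correlated(self):
        # with real mediated signal, NIEs of overlapping mediator sets are
        # strongly correlated across replicates (paper reports 0.53-0.98)
        df, _ = make_cohort_frame(
            n=2000,
            seed=10,
            outcome_coefs=sc.OutcomeCoefs(region_effects=(-8.0, -8.0, -8.0)),
            surrogate=sc.SurrogateChacoParams(gamma_arm_eloquent=-0.015, noise_sd=0.03),
        )
        specs = {
            "growth_only": ["log2_growth"],
            "joint": ["log2_growth", "dchaco_01", "dchaco_02", "dchaco_03"],
        }
        reps = med.bootstrap_effects(df, specs, COVARIATES, k=200, seed=2)
        m = reps.matrix("nie")
        corr = np.corrcoef(np.log(m["growth_only"]), np.log(m["joint"]))[0, 1]
        assert corr > 0.5

    def test_k_minimum(self):
        df, _ = make_cohort_frame(n=200, seed=8)
        with pytest.raises(ValueError):
            med.bootstrap_effects(df, {"g": ["log2_growth"]}, COVARIATES, k=50)


class TestBCInterval:
    def test_symmetric_equals_percentile(self):
        rng = np.random.default_rng(0)
        reps = rng.normal(10.0, 1.0, size=4001)
        est = float(np.median(reps))
        lo, hi = med.bc_interval(reps, est)
        plo, phi = np.quantile(reps, [0.025, 0.975])
        assert lo == pytest.approx(plo, abs=0.05)
        assert hi == pytest.approx(phi, abs=0.05)

    def test_estimate_outside_range_clamped_with_warning(self):
        reps = np.random.default_rng(1).normal(size=500)
        with pytest.warns(UserWarning, match="clamping"):
            med.bc_interval(reps, 10.0)

    def test_degenerate_replicates_flagged(self):
        with pytest.warns(UserWarning, match="degenerate"):
            lo, hi = med.bc_interval(np.ones(200), 1.0)
        assert lo == hi == 1.0

    def test_coverage_quick(self):
        # small-scale coverage sanity check (full check in acceptance suite)
        rng = np.random.default_rng(2)
        cover = 0
        for _ in range(60):
            sample = rng.normal(0.0, 1.0, size=80)
            reps = np.array(
                [rng.choice(sample, size=80).mean() for _ in range(150)]
            )
            lo, hi = med.bc_interval(reps, sample.mean())
            cover += lo <= 0.0 <= hi
        assert cover >= 45  # ~93%+ of 60


class TestNieRatio:
    def test_identical_specs_ratio_one(self):
        df, _ = make_cohort_frame(n=300, seed=9)
        specs = {"a": ["log2_growth"], "b": ["log2_growth"]}
        reps = med.bootstrap_effects(df, specs, COVARIATES, k=100, seed=1)
        r = med.nie_ratio(reps, "a", "b")
        assert r.point == pytest.approx(1.0)
        assert r.ci == (pytest.approx(1.0), pytest.approx(1.0))

    def test_missing_spec_errors(self):
        df, _ = make_cohort_frame(n=300, seed=9)
        reps = med.bootstrap_effects(df, {"a": ["log2_growth"]}, COVARIATES, k=100, seed=1)
        with pytest.raises(KeyError):
            med.nie_ratio(reps, "a", "zzz")

    def test_strong_region_effects_give_excess(self):
        df, _ = make_cohort_frame(
            n=2000,
            seed=10,
            outcome_coefs=sc.OutcomeCoefs(region_effects=(-8.0, -8.0, -8.0)),
            surrogate=sc.SurrogateChacoParams(gamma_arm_eloquent=-0.015, noise_sd=0.03),
        )
        specs = {
            "growth_only": ["log2_growth"],
            "joint": ["log2_growth", "dchaco_01", "dchaco_02", "dchaco_03"],
        }
        reps = med.bootstrap_effects(df, specs, COVARIATES, k=300, seed=2)
        r = med.nie_ratio(reps, "joint", "growth_only")
        assert r.point > 1.0
        assert r.significant_excess


class TestStepdown:
    def _make_reps(self, df, n_models=3, seed=1, k=200, strong=()):
        specs = {"growth_only": ["log2_growth"]}
        for i in range(n_models):
            specs[f"m{i}"] = ["log2_growth", f"dchaco_{i + 1:02d}"]
        return med.bootstrap_effects(df, specs, COVARIATES, k=k, seed=seed)

    def test_perfectly_correlated_rejected_together(self):
        df, _ = make_cohort_frame(n=1500, seed=12)
        specs = {
            "a": ["log2_growth", "dchaco_01"],
            "b": ["log2_growth", "dchaco_01"],  # identical mediator set
        }
        reps = med.bootstrap_effects(df, specs, COVARIATES, k=200, seed=3)
        res = med.stepdown_fdr(reps, q=0.05)
        assert res.rejected[0] == res.rejected[1]

    def test_strong_effect_rejected_first(self):
        df, _ = make_cohort_frame(
            n=4000,
            seed=13,
            outcome_coefs=sc.OutcomeCoefs(region_effects=(-10.0, 0.0, 0.0)),
            surrogate=sc.SurrogateChacoParams(gamma_arm_eloquent=-0.02, noise_sd=0.03),
        )
        specs = {
            "strong": ["log2_growth", "dchaco_01"],
            "null1": ["log2_growth", "dchaco_05"],
            "null2": ["log2_growth", "dchaco_06"],
        }
        reps = med.bootstrap_effects(df, specs, COVARIATES, k=200, seed=4)
        res = med.stepdown_fdr(reps, q=0.05)
        assert res.names[0] == "strong"
        assert res.rejected[0]

    def test_thresholds_nonincreasing(self):
        df, _ = make_cohort_frame(n=800, seed=14)
        reps = self._make_reps(df, n_models=4)
        res = med.stepdown_fdr(reps, q=0.05)
        assert all(
            a >= b - 1e-12 for a, b in zip(res.thresholds, res.thresholds[1:])
        )

    def test_single_model_reduces_to_bootstrap_test(self):
        df, _ = make_cohort_frame(n=500, seed=15)
        reps = med.bootstrap_effects(df, {"g": ["log2_growth"]}, COVARIATES, k=150, seed=5)
        res = med.stepdown_fdr(reps, q=0.05)
        assert len(res.names) == 1


class TestRandomSubsetNull:
    def test_single_draw_percentile_degenerate(self):
        df, _ = make_cohort_frame(n=300, seed=16)
        null = med.random_subset_null(
            df, [f"dchaco_{i:02d}" for i in range(8)], "log2_growth", COVARIATES,
            k=1, seed=1,
        )
        assert len(null.nies) == 1
        assert null.percentile(null.nies[0]) == 100.0

    def test_null_centers_on_growth_only(self):
        df, params = make_cohort_frame(
            n=3000,
            seed=17,
            outcome_coefs=sc.OutcomeCoefs(region_effects=(0.0, 0.0, 0.0)),
            surrogate=sc.SurrogateChacoParams(gamma_arm_eloquent=0.0),
        )
        growth_eff = med.estimate_natural_effects(df, ["log2_growth"], COVARIATES)
        null = med.random_subset_null(
            df, [f"dchaco_{i:02d}" for i in range(8)], "log2_growth", COVARIATES,
            k=100, seed=2,
        )
        assert np.median(null.nies) == pytest.approx(growth_eff.nie, abs=0.02)

    def test_empty_pool_errors(self):
        df, _ = make_cohort_frame(n=300, seed=18)
        with pytest.raises(ValueError):
            med.random_subset_null(df, [], "log2_growth", COVARIATES, k=5, seed=0)
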