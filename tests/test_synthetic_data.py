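"""Generator calibration, determinism, and paired-scenario properties."""

import numpy as np
import pytest
from scipy import stats

from maictools.maic_weights import MatchSpec, fit_maic
from maictools.synthetic_data import (
    GeneratorConfig,
    TrueEffects,
    calibrate_marginals,
    generate_trial,
    load_scenario,
    make_paired_scenario,
)
from maictools.trial_data import AggregateTargets, TargetMoment


class TestCalibration:
    def test_bernoulli_proportion(self):
        targets = AggregateTargets([TargetMoment("male", "proportion", 0.698)])
        marg = calibrate_marginals(targets)
        assert marg["male"].params["p"] == 0.698

    def test_lognormal_mean_identity(self):
        targets = AggregateTargets([TargetMoment("upcr", "mean", 1.44)])
        marg = calibrate_marginals(targets, {"upcr": {"dist": "lognormal", "sigma": 0.6}})
        mu = marg["upcr"].params["mu"]
        assert mu == pytest.approx(np.log(1.44) - 0.18)
        assert np.exp(mu + 0.18) == pytest.approx(1.44)  # E X = exp(mu + sigma^2/2)

    def test_threshold_at_half_pins_median(self):
        targets = AggregateTargets(
            [TargetMoment("uacr", "threshold_proportion", 0.5, threshold=1.1)]
        )
        marg = calibrate_marginals(targets, {"uacr": {"sigma": 0.7}})
        median = np.exp(marg["uacr"].params["mu"])
        assert median == pytest.approx(1.1)

    def test_joint_mean_and_threshold_solved_for_sigma(self):
        targets = AggregateTargets(
            [
                TargetMoment("uacr", "mean", 1.5),
                TargetMoment("uacr", "threshold_proportion", 0.5, threshold=1.1),
            ]
        )
        marg = calibrate_marginals(targets)
        mu, sigma = marg["uacr"].params["mu"], marg["uacr"].params["sigma"]
        assert np.exp(mu) == pytest.approx(1.1)  # median constraint
        assert np.exp(mu + sigma**2 / 2) == pytest.approx(1.5)  # mean constraint

    def test_inconsistent_constraints_fail(self):
        # mean below the median of the exceedance constraint: impossible
        targets = AggregateTargets(
            [
                TargetMoment("uacr", "mean", 0.5),
                TargetMoment("uacr", "threshold_proportion", 0.9, threshold=1.1),
            ]
        )
        with pytest.raises(ValueError, match="no"):
            calibrate_marginals(targets)


class TestGenerateTrial:
    def test_same_seed_identical(self):
        cfg = load_scenario("nefigard_like", n=40)
        assert generate_trial(cfg, seed=5) == generate_trial(cfg, seed=5)

    def test_different_seed_differs(self):
        cfg = load_scenario("nefigard_like", n=40)
        assert generate_trial(cfg, seed=5) != generate_trial(cfg, seed=6)

    def test_large_sample_mean_age_converges(self):
        cfg = load_scenario("nefigard_like", n=100_000)
        recs = generate_trial(cfg, seed=11)
        ages = np.array([r.age for r in recs])
        se = ages.std() / np.sqrt(len(ages))
        assert abs(ages.mean() - 42.70) <= 3 * se + 0.02  # truncation bias is tiny

    def test_zero_noise_degenerates_to_constant_egfr(self):
        cfg = load_scenario("nefigard_like", n=20)
        cfg.egfr_intercept_sd = 0.0
        cfg.egfr_residual_cov = np.zeros((6, 6))
        cfg.egfr_effects = {a: {} for a in ("active", "control")}
        recs = generate_trial(cfg, seed=2)
        for r in recs:
            for v in r.visits:
                assert v.egfr == pytest.approx(r.egfr_baseline)

    def test_copula_induces_requested_dependence_sign(self):
        recs = generate_trial(load_scenario("nefigard_like", n=20_000), seed=3)
        upcr = np.array([r.upcr_baseline for r in recs])
        uacr = np.array([r.uacr_baseline for r in recs])
        egfr = np.array([r.egfr_baseline for r in recs])
        assert stats.spearmanr(upcr, uacr).statistic > 0.6
        assert stats.spearmanr(upcr, egfr).statistic < -0.05

    def test_non_pd_correlation_rejected(self):
        cfg = load_scenario("nefigard_like", n=10)
        bad = np.ones((7, 7))
        with pytest.raises(ValueError, match="positive definite"):
            GeneratorConfig(
                trial_id="x",
                n=10,
                marginals=cfg.marginals,
                correlation=bad,
                egfr_effects=cfg.egfr_effects,
                ratio_effects=cfg.ratio_effects,
                event_model=cfg.event_model,
            )

    def test_exact_moment_mode_hits_published_column(self, calibrated_trial):
        assert np.mean([r.age for r in calibrated_trial]) == pytest.approx(42.70, abs=1e-9)
        assert sum(r.male for r in calibrated_trial) == 240
        assert sum(r.white for r in calibrated_trial) == 275
        assert sum(r.uacr_baseline > 1.1 for r in calibrated_trial) == 148
        assert sum(r.uprot24h_baseline > 1.8 for r in calibrated_trial) == 239
        assert np.mean([r.upcr_baseline for r in calibrated_trial]) == pytest.approx(1.48)


def _single_visit_overrides(index_active=5.0, comparator_active=2.0):
    common = {
        "visit_months": (9.0,),
        "egfr_residual_cov": np.array([[36.0]]),
        "censor_month": 9.0,
    }
    return TrueEffects(
        index={
            **common,
            "n": 400,
            "egfr_effects": {"active": {9.0: index_active}, "control": {9.0: 0.0}},
        },
        comparator={
            **common,
            "n": 400,
            "egfr_effects": {"active": {9.0: comparator_active}, "control": {9.0: 0.0}},
        },
    )


class TestPairedScenario:
    def test_null_scenario_interval_covers_zero(self):
        from maictools.indirect_comparison import RelativeEffect, bucher_combine, se_from_interval
        from maictools.outcome_models import build_change_outcomes, fit_mmrm

        sc = make_paired_scenario(
            _single_visit_overrides(2.0, 2.0), seed=314, endpoints=("egfr",), analysis_months=(9.0,)
        )
        ws = fit_maic(sc.index_records, MatchSpec("anchored", sc.comparator_targets))
        fit = fit_mmrm(build_change_outcomes(sc.index_records, "egfr"), ws, visits=[9.0])
        est, se = fit.contrast_at(9.0)
        pub = sc.comparator_summary.lookup("egfr", 9.0)
        res = bucher_combine(
            RelativeEffect("mean_difference", 9.0, est, se),
            RelativeEffect(
                "mean_difference",
                9.0,
                pub.estimate,
                se_from_interval(pub.lower, pub.upper),
                source="comparator_published",
            ),
        )
        assert res.lower <= 0.0 <= res.upper

    def test_shifted_moments_reduce_ess(self):
        sc = make_paired_scenario(
            _single_visit_overrides(), seed=1001, endpoints=("egfr",), analysis_months=(9.0,)
        )
        ws = fit_maic(sc.index_records, MatchSpec("anchored", sc.comparator_targets))
        assert ws.ess < ws.n

    def test_comparator_summary_has_relative_and_arm_levels(self):
        sc = make_paired_scenario(
            _single_visit_overrides(), seed=7, endpoints=("egfr",), analysis_months=(9.0,)
        )
        assert sc.comparator_summary.lookup("egfr", 9.0).level == "relative"
        assert sc.comparator_summary.lookup("egfr", 9.0, level="arm", arm="active").arm == "active"

    def test_maic_removes_effect_modification_bias(self):
        """With the index drug's eGFR effect modified by baseline eGFR and a
        comparator population 8 units lower, the unadjusted indirect estimate
        is biased away from the population-adjusted truth while the weighted
        one recenters on it (directional, over replicates)."""
        from maictools.indirect_comparison import RelativeEffect, bucher_combine, se_from_interval
        from maictools.outcome_models import build_change_outcomes, fit_mmrm

        from maictools.synthetic_data import _finalize_truncnorm

        slope, ref = 0.25, 58.0
        comp_mean_egfr = 50.0
        est_unadj, est_adj, truths = [], [], []
        overrides = _single_visit_overrides()
        overrides.index["egfr_effect_modification"] = {"slope": slope, "ref": ref}
        for rep in range(40):
            cc = load_scenario("protect_like")
            cc.marginals["egfr"].params = _finalize_truncnorm(
                {"mean": comp_mean_egfr, "sd": 22.0, "low": 10.0}
            )
            cc.marginals["egfr"].target = {"mean": comp_mean_egfr}
            sc = make_paired_scenario(
                overrides,
                seed=5000 + rep,
                comparator_config=cc,
                endpoints=("egfr",),
                analysis_months=(9.0,),
            )
            egfr_target = next(m for m in sc.comparator_targets if m.covariate == "egfr")
            truths.append(5.0 + slope * (egfr_target.value - ref) - 2.0)
            pub = sc.comparator_summary.lookup("egfr", 9.0)
            comp_eff = RelativeEffect(
                "mean_difference",
                9.0,
                pub.estimate,
                se_from_interval(pub.lower, pub.upper),
                source="comparator_published",
            )
            table = build_change_outcomes(sc.index_records, "egfr")
            for adjusted in (False, True):
                w = (
                    fit_maic(sc.index_records, MatchSpec("anchored", sc.comparator_targets))
                    if adjusted
                    else None
                )
                est, se = fit_mmrm(table, w, visits=[9.0]).contrast_at(9.0)
                r = bucher_combine(RelativeEffect("mean_difference", 9.0, est, se), comp_eff)
                (est_adj if adjusted else est_unadj).append(r.estimate)
        truth = float(np.mean(truths))
        bias_unadj = abs(np.mean(est_unadj) - truth)
        bias_adj = abs(np.mean(est_adj) - truth)
        assert bias_unadj > 3 * bias_adj
        assert bias_adj <= 3 * np.std(est_adj, ddof=1) / np.sqrt(len(est_adj)) + 0.15
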