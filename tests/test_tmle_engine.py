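"""TMLE correctness: exact agreement with enumeration on a saturated design,
null and confounded recovery against the Monte-Carlo oracle, the solved
score equation, double robustness, bounded-outcome scaling, and the
stratified reporting contract."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from septrial import (DGPConfig, counterfactual_mean, estimate_ate, scale_bounded,
                      stratified_ates, tmle_from_nuisances, unscale_bounded)
from septrial.stacking import FAST_LIBRARY
from septrial.tmle_engine import EstimationError, covariate_columns

from conftest import simulate_and_build


def _saturated_example(seed=0, n=4000):
    """Randomized design, one binary confounder, saturated outcome model."""
    rng = np.random.default_rng(seed)
    z = (rng.random(n) < 0.4).astype(float)
    a = (rng.random(n) < 0.5).astype(float)
    p = expit(-0.5 + 0.9 * a + 0.7 * z - 0.4 * a * z)
    y = (rng.random(n) < p).astype(float)
    return z, a, y


def _empirical_g_formula(z, a, y):
    """Exhaustive enumeration of the standardized risk difference over the
    2x2x2 table (the nonparametric g-formula)."""
    est = 0.0
    for zv in (0.0, 1.0):
        pz = np.mean(z == zv)
        m1 = y[(z == zv) & (a == 1)].mean()
        m0 = y[(z == zv) & (a == 0)].mean()
        est += pz * (m1 - m0)
    return est


class TestOracleEquivalence:
    def test_saturated_tmle_equals_enumerated_g_formula(self):
        """With the true constant propensity and a saturated outcome model,
        the targeted estimate reproduces the enumerated standardized risk
        difference to numerical precision."""
        z, a, y = _saturated_example()
        Q0 = np.array([y[(z == zv) & (a == 0)].mean() for zv in z])
        Q1 = np.array([y[(z == zv) & (a == 1)].mean() for zv in z])
        res = tmle_from_nuisances(Q0, Q1, np.full_like(a, 0.5), a, y)
        assert res.estimate == pytest.approx(_empirical_g_formula(z, a, y), abs=1e-6)
        assert abs(res.epsilon) < 1e-6  # saturated fit needs no fluctuation

    def test_estimate_ate_with_overrides_matches(self):
        z, a, y = _saturated_example(seed=1)
        Q0 = np.array([y[(z == zv) & (a == 0)].mean() for zv in z])
        Q1 = np.array([y[(z == zv) & (a == 1)].mean() for zv in z])
        res = estimate_ate(z[:, None], a, y, g_override=0.5, q_override=(Q0, Q1),
                           g_bounds=(0.01, 0.99))
        assert res.estimate == pytest.approx(_empirical_g_formula(z, a, y), abs=1e-6)


class TestScoreEquation:
    @pytest.mark.parametrize("outcome,loss", [("Y_mortality", "binomial"),
                                              ("Y_parity", "binomial")])
    def test_mean_clever_covariate_residual_vanishes(self, cohort, outcome, loss):
        x = cohort[covariate_columns(cohort)]
        res = estimate_ate(x, cohort["A_imv"].to_numpy(),
                           cohort[outcome].to_numpy(float), loss,
                           seed=0, learners=FAST_LIBRARY)
        assert abs(res.score_residual) <= 1e-6

    def test_residual_vanishes_for_bounded_continuous_outcome(self, cohort):
        x = cohort[covariate_columns(cohort)]
        y = scale_bounded(cohort["Y_hfd"].to_numpy(float), 0, 28)
        res = estimate_ate(x, cohort["A_imv"].to_numpy(), y, "squared_error",
                           seed=0, learners=FAST_LIBRARY)
        assert abs(res.score_residual) <= 1e-6

    def test_residual_vanishes_for_counterfactual_mean(self, cohort):
        x = cohort[covariate_columns(cohort)]
        res = counterfactual_mean(x, cohort["A_imv"].to_numpy(),
                                  cohort["Y_mortality"].to_numpy(float),
                                  a_target=0, seed=0, learners=FAST_LIBRARY)
        assert abs(res.score_residual) <= 1e-6


class TestRecovery:
    def test_null_effect_recovered(self):
        cfg = DGPConfig(n_stays=20_000, seed=0)
        coefs = {k: (0.0 if k.startswith("treat:imv") else v)
                 for k, v in cfg.outcome_coefficients.items()}
        cfg = cfg.replace(outcome_coefficients=coefs)
        built = simulate_and_build(cfg, seed=0)
        x = built[covariate_columns(built)]
        res = estimate_ate(x, built["A_imv"].to_numpy(),
                           built["Y_mortality"].to_numpy(float), seed=0,
                           learners=FAST_LIBRARY)
        assert abs(res.estimate) < 3 * res.se

    def test_confounded_recovery_beats_naive(self, default_config, truth):
        """A small seed-averaged check that TMLE lands near oracle truth while
        the difference in means carries the designed confounding bias."""
        truth_val = truth.true_ate_mortality[("imv", "overall")]
        ests, naives = [], []
        cfg = default_config.replace(n_stays=20_000)
        for seed in range(5):
            built = simulate_and_build(cfg, seed=seed)
            a = built["A_imv"].to_numpy()
            y = built["Y_mortality"].to_numpy(float)
            naives.append(y[a == 1].mean() - y[a == 0].mean())
            x = built[covariate_columns(built)]
            ests.append(estimate_ate(x, a, y, seed=seed, learners=FAST_LIBRARY).estimate)
        assert np.mean(ests) == pytest.approx(truth_val, abs=0.012)
        assert abs(np.mean(naives) - truth_val) >= 0.03

    def test_double_robustness_with_misspecified_q(self, default_config, truth):
        """Intercept-only outcome model but the true propensity: the targeted
        estimate must still land within 3 SEs of oracle truth."""
        from septrial.synthetic_cohort import (_draw_cancer, _draw_covariates,
                                               _linear_predictor, generate_cohort)

        cfg = default_config.replace(n_stays=20_000)
        rec = generate_cohort(cfg.replace(seed=1))
        from septrial import build_cohort

        built, _ = build_cohort(rec, calibration=cfg.pmp_calibration)
        kept = rec.set_index("stay_id").loc[built["stay_id"]]
        # effective-arm propensity: ever treated AND initiated inside 24 h
        g_true = expit(_linear_predictor(
            cfg, cfg.propensity_coefficients["imv"],
            kept[[s.name for s in cfg.covariate_spec]].reset_index(drop=True),
            kept["cancer_latent"].to_numpy()))
        g_true = g_true * cfg.treatment_start_distribution["imv"]["p_within"]
        a = built["A_imv"].to_numpy()
        y = built["Y_mortality"].to_numpy(float)
        q_flat = np.full_like(y, y.mean())
        res = estimate_ate(None, a, y, g_override=g_true,
                           q_override=(q_flat, q_flat), g_bounds=(0.01, 0.99))
        truth_val = truth.true_ate_mortality[("imv", "overall")]
        assert res.estimate == pytest.approx(truth_val, abs=3 * res.se)

    def test_counterfactual_baseline_matches_oracle(self, default_config):
        """E[Y(0)] in a single-treatment DGP (so 'untreated' really is the
        all-interventions-off world the oracle baseline describes)."""
        from septrial import compute_truth

        base = default_config
        cfg = DGPConfig(
            n_stays=20_000,
            treatments=("imv",),
            propensity_coefficients={"imv": base.propensity_coefficients["imv"]},
            treatment_start_distribution={
                "imv": base.treatment_start_distribution["imv"]},
            outcome_coefficients={k: v for k, v in base.outcome_coefficients.items()
                                  if "vasopressors" not in k},
        )
        tr = compute_truth(cfg, n_mc=100_000, seed=8)
        built = simulate_and_build(cfg, seed=3)
        x = built[covariate_columns(built)]
        res = counterfactual_mean(x, built["A_imv"].to_numpy(),
                                  built["Y_mortality"].to_numpy(float), a_target=0,
                                  seed=3, learners=FAST_LIBRARY)
        assert 0.0 <= res.estimate <= 1.0
        assert res.estimate == pytest.approx(tr.true_baseline_mean["overall"],
                                             abs=3 * res.se)


class TestGuards:
    def test_single_arm_raises_positivity_error(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 2))
        y = (rng.random(100) < 0.3).astype(float)
        with pytest.raises(EstimationError, match="positivity"):
            estimate_ate(X, np.zeros(100), y)

    def test_tiny_sample_rejected(self):
        with pytest.raises(EstimationError, match="too small"):
            estimate_ate(np.zeros((10, 1)), np.r_[np.ones(5), np.zeros(5)],
                         np.zeros(10))

    def test_non_binary_treatment_rejected(self):
        with pytest.raises(EstimationError):
            estimate_ate(np.zeros((60, 1)), np.linspace(0, 2, 60), np.zeros(60))

    def test_out_of_range_outcome_rejected(self):
        a = np.r_[np.ones(30), np.zeros(30)]
        with pytest.raises(EstimationError):
            estimate_ate(np.zeros((60, 1)), a, np.full(60, 3.0))

    def test_widening_g_bounds_never_increases_truncation(self, cohort):
        x = cohort[covariate_columns(cohort)].iloc[:4000]
        a = cohort["A_imv"].to_numpy()[:4000]
        y = cohort["Y_mortality"].to_numpy(float)[:4000]
        counts = []
        for bounds in [(0.1, 0.9), (0.025, 0.975), (0.001, 0.999)]:
            res = estimate_ate(x, a, y, g_bounds=bounds, seed=0, learners=FAST_LIBRARY)
            at_bound = int(res.g_range[0] <= bounds[0] + 1e-12) + \
                int(res.g_range[1] >= bounds[1] - 1e-12)
            counts.append(at_bound)
        assert counts == sorted(counts, reverse=True)


class TestBoundedScaling:
    def test_endpoints(self):
        assert scale_bounded(np.array([0.0]))[0] == 0.0
        assert scale_bounded(np.array([28.0]))[0] == 1.0

    def test_back_transform(self):
        assert float(unscale_bounded(0.1) - unscale_bounded(0.0)) == pytest.approx(2.8)

    @given(st.lists(st.floats(0, 28), min_size=1, max_size=30))
    @settings(deadline=None, derandomize=True)
    def test_round_trip_identity(self, values):
        y = np.asarray(values)
        assert np.allclose(unscale_bounded(scale_bounded(y)), y, atol=1e-12)

    def test_out_of_range_rejected_with_rows(self):
        with pytest.raises(ValueError, match="rows"):
            scale_bounded(np.array([1.0, 29.0]))

    def test_lo_ge_hi_rejected(self):
        with pytest.raises(ValueError):
            scale_bounded(np.array([1.0]), 5, 5)


class TestStratified:
    @pytest.fixture(scope="class")
    def balanced_cohort(self):
        cfg = DGPConfig(n_stays=8000, seed=21, cancer_prevalences={
            "solid": 0.25, "hematological": 0.25, "metastasized": 0.25})
        return simulate_and_build(cfg, seed=21)

    def test_result_count_is_full_cross_product(self, balanced_cohort):
        out = stratified_ates(balanced_cohort, treatments=("imv", "vasopressors"),
                              categories=["none", "solid", "hematological", "metastasized"],
                              strata=["0%-100%", "low", "moderate", "high"],
                              learners=FAST_LIBRARY, k=3, seed=0)
        assert len(out) == 2 * 4 * 4

    def test_empty_arm_reported_as_skip(self, balanced_cohort):
        crippled = balanced_cohort.copy()
        mask = (crippled["cancer_category"] == "solid") & \
            (crippled["severity_stratum"] == "low")
        crippled.loc[mask, "A_imv"] = 0
        out = stratified_ates(crippled, treatments=("imv",),
                              categories=["solid"], strata=["low"],
                              learners=FAST_LIBRARY, seed=0)
        assert len(out) == 1
        assert "positivity" in out.iloc[0]["skipped_reason"]
        assert np.isnan(out.iloc[0]["estimate"])

    def test_interaction_sign_recovered_across_pmp_strata(self, default_config, truth):
        """The DGP's treatment x severity interaction makes the high-PMP ATE
        exceed the low-PMP ATE; the stratified estimates must recover the
        ordering."""
        built = simulate_and_build(default_config.replace(n_stays=50_000), seed=17)
        out = stratified_ates(built, treatments=("imv",), categories=["all"],
                              strata=["low", "high"], learners=FAST_LIBRARY, seed=0)
        est = out.set_index("stratum")["estimate"]
        true_gap = truth.true_ate_mortality[("imv", "pmp:high")] \
            - truth.true_ate_mortality[("imv", "pmp:low")]
        assert true_gap > 0
        assert est["high"] - est["low"] > 0

    def test_hfd_effects_reported_in_days(self, cohort, truth):
        out = stratified_ates(cohort, treatments=("imv",), outcome="Y_hfd",
                              categories=["all"], strata=["0%-100%"],
                              learners=FAST_LIBRARY, seed=0)
        est = out.iloc[0]["estimate"]
        assert -28 <= est <= 28
        # designed harm: treatment reduces hospital-free days
        assert est == pytest.approx(truth.true_ate_hfd[("imv", "overall")], abs=1.0)
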