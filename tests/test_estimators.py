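"""Estimator correctness against closed forms, brute force, and reference fits."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from lifelines import CoxPHFitter, NelsonAalenFitter
from scipy.optimize import minimize_scalar

from curegwas import (
    BaselineSurvival,
    SimDesign,
    breslow_baseline,
    estep_weights,
    fit_cox,
    fit_cure_cox,
    fit_logistic,
    resolve_effects,
    simulate_cohort,
)
from curegwas.estimators import IdentifiabilityError, _cox_nr
from conftest import make_toy_cohort


def expand_2x2(carrier_case, carrier_control, noncarrier_case, noncarrier_control):
    genotype = [1] * (carrier_case + carrier_control) + [0] * (
        noncarrier_case + noncarrier_control
    )
    event = (
        [True] * carrier_case
        + [False] * carrier_control
        + [True] * noncarrier_case
        + [False] * noncarrier_control
    )
    return make_toy_cohort(genotype, np.ones(len(genotype)), event)


def brute_force_cox(time, event, x, weights=None):
    """Directly maximize the written-out Breslow partial likelihood."""
    time, event, x = map(np.asarray, (time, event, x))
    w = np.ones(len(time)) if weights is None else np.asarray(weights, float)

    def neg_pl(beta):
        ll = 0.0
        for i in np.flatnonzero(event):
            risk = time >= time[i]
            ll += w[i] * (beta * x[i] - math.log(np.sum(w[risk] * np.exp(beta * x[risk]))))
        return -ll

    res = minimize_scalar(neg_pl, bounds=(-5, 5), method="bounded",
                          options={"xatol": 1e-8})
    return res.x


class TestLogistic:
    def test_no_association(self):
        cohort = expand_2x2(5, 5, 5, 5)
        fit = fit_logistic(cohort)
        assert fit.converged
        assert fit.estimate == pytest.approx(0.0, abs=1e-8)

    def test_cross_product_ratio(self):
        """Saturated binary model: MLE equals the log cross-product ratio."""
        cohort = expand_2x2(6, 4, 2, 8)
        fit = fit_logistic(cohort)
        assert fit.estimate == pytest.approx(math.log(6), abs=1e-8)

    @pytest.mark.parametrize("counts", [(3, 7, 5, 5), (9, 1, 4, 6), (2, 2, 7, 3)])
    def test_cross_product_ratio_family(self, counts):
        a, b, c, d = counts
        fit = fit_logistic(expand_2x2(a, b, c, d))
        assert fit.estimate == pytest.approx(math.log(a * d / (b * c)), abs=1e-8)

    def test_all_events_flagged(self):
        cohort = make_toy_cohort([0, 1, 2, 1], [1, 2, 3, 4], [True] * 4)
        fit = fit_logistic(cohort)
        assert not fit.converged

    def test_separation_flagged(self):
        cohort = expand_2x2(5, 0, 0, 5)
        assert not fit_logistic(cohort).converged

    def test_matches_statsmodels(self, effect_cohort):
        fit = fit_logistic(effect_cohort)
        X = sm.add_constant(effect_cohort["genotype"].to_numpy(dtype=float))
        ref = sm.GLM(
            effect_cohort["event"].to_numpy(dtype=float), X, family=sm.families.Binomial()
        ).fit()
        assert fit.estimate == pytest.approx(ref.params[1], abs=1e-6)
        assert fit.se == pytest.approx(ref.bse[1], abs=1e-6)
        assert fit.p_value == pytest.approx(ref.pvalues[1], abs=1e-6)

    def test_fractional_response_matches_statsmodels(self, effect_cohort):
        rng = np.random.default_rng(0)
        w = np.where(
            effect_cohort["event"], 1.0, rng.uniform(0, 1, len(effect_cohort))
        )
        fit = fit_logistic(effect_cohort, weights=w)
        X = sm.add_constant(effect_cohort["genotype"].to_numpy(dtype=float))
        ref = sm.GLM(w, X, family=sm.families.Binomial()).fit()
        assert fit.estimate == pytest.approx(ref.params[1], abs=1e-6)
        assert fit.intercept == pytest.approx(ref.params[0], abs=1e-6)


class TestCox:
    def test_matches_bruteforce_small(self):
        cohort = make_toy_cohort([0, 1, 0, 1], [1, 2, 3, 4], [True] * 4)
        fit = fit_cox(cohort)
        oracle = brute_force_cox([1, 2, 3, 4], [1, 1, 1, 1], [0, 1, 0, 1])
        assert fit.converged
        assert fit.estimate == pytest.approx(oracle, abs=1e-4)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        x = rng.integers(0, 3, n)
        time = rng.uniform(1, 10, n)
        event = np.ones(n, dtype=bool)
        fit = fit_cox(make_toy_cohort(x, time, event))
        if fit.converged:
            oracle = brute_force_cox(time, event, x)
            assert fit.estimate == pytest.approx(oracle, abs=1e-4)

    def test_weighted_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        n = 8
        x = rng.integers(0, 3, n)
        time = rng.uniform(1, 10, n)
        event = np.array([1, 1, 0, 1, 1, 0, 1, 1], dtype=bool)
        w = np.where(event, 1.0, rng.uniform(0.2, 1.0, n))
        fit = fit_cox(make_toy_cohort(x, time, event), weights=w)
        oracle = brute_force_cox(time, event, x, weights=w)
        assert fit.estimate == pytest.approx(oracle, abs=1e-4)

    def test_no_covariate_variation_flagged(self):
        cohort = make_toy_cohort([1, 1, 1, 1], [1, 2, 3, 4], [True] * 4)
        assert not fit_cox(cohort).converged

    def test_monotone_likelihood_flagged(self):
        cohort = make_toy_cohort([1, 1, 0, 0], [1, 2, 3, 4], [True, True, False, False])
        assert not fit_cox(cohort).converged

    def test_unit_weights_identity(self, effect_cohort):
        plain = fit_cox(effect_cohort)
        weighted = fit_cox(effect_cohort, weights=np.ones(len(effect_cohort)))
        assert plain.estimate == weighted.estimate
        assert plain.se == weighted.se

    def test_matches_lifelines(self, effect_cohort):
        fit = fit_cox(effect_cohort)
        frame = effect_cohort[["obs_time", "event", "genotype"]].copy()
        frame["event"] = frame["event"].astype(int)
        ref = CoxPHFitter().fit(frame, duration_col="obs_time", event_col="event")
        assert fit.estimate == pytest.approx(ref.params_["genotype"], abs=1e-5)
        assert fit.se == pytest.approx(ref.standard_errors_["genotype"], abs=1e-5)


class TestBreslowBaseline:
    def test_reduces_to_nelson_aalen(self, null_cohort):
        baseline = breslow_baseline(null_cohort, beta=0.0)
        naf = NelsonAalenFitter().fit(
            null_cohort["obs_time"], event_observed=null_cohort["event"]
        )
        times = baseline.times[::25]
        ref = naf.cumulative_hazard_at_times(times).to_numpy()
        assert np.allclose(baseline.cumulative_hazard(times), ref, atol=1e-10)

    def test_single_event_increment(self):
        cohort = make_toy_cohort([0, 1, 0], [5.0, 2.0, 3.0], [False, True, False])
        baseline = breslow_baseline(cohort, beta=0.0)
        # one event at t=2 with all 3 subjects at risk
        assert baseline.cumulative_hazard(2.0) == pytest.approx(1 / 3)

    def test_zero_weight_censored_hand_check(self):
        """5 subjects, censored weights 0: risk sets reduce to the events."""
        time = [1.0, 2.0, 3.0, 4.0, 5.0]
        event = [True, False, True, False, True]
        x = [0, 1, 0, 1, 1]
        w = [1.0, 0.0, 1.0, 0.0, 1.0]
        beta = 0.5
        cohort = make_toy_cohort(x, time, event)
        baseline = breslow_baseline(cohort, beta=beta, weights=np.array(w))
        e = math.exp(beta)
        expected = [1 / (2 + e), 1 / (2 + e) + 1 / (1 + e), 1 / (2 + e) + 1 / (1 + e) + 1 / e]
        assert np.allclose(baseline.cumhaz, expected)

    def test_shape_constraints(self, effect_cohort):
        baseline = breslow_baseline(effect_cohort, beta=0.2)
        surv = baseline(baseline.times)
        assert np.all(np.diff(surv) <= 0)
        assert baseline(0.0) == 1.0
        assert baseline(baseline.last_event_time + 1e-9) == 0.0


class TestEStep:
    def test_event_subjects_are_one(self, effect_cohort):
        baseline = breslow_baseline(effect_cohort, beta=0.0)
        w = estep_weights(effect_cohort, (0.0, 0.0), 0.0, baseline)
        assert np.all(w[effect_cohort["event"].to_numpy()] == 1.0)
        assert np.all((w >= 0.0) & (w <= 1.0))

    def test_censored_beyond_last_event_is_zero(self):
        cohort = make_toy_cohort([0, 1], [1.0, 9.0], [True, False])
        baseline = breslow_baseline(cohort, beta=0.0)
        w = estep_weights(cohort, (5.0, 0.0), 0.0, baseline)
        assert w[1] == 0.0

    def test_half_half_gives_third(self):
        cohort = make_toy_cohort([0], [10.0], [False])
        baseline = BaselineSurvival(np.array([10.0]), np.array([math.log(2)]))
        w = estep_weights(cohort, (0.0, 0.0), 0.0, baseline)
        assert w[0] == pytest.approx(1 / 3, abs=1e-12)


class TestCureCox:
    def test_all_events_unidentified(self):
        cohort = make_toy_cohort([0, 1, 0, 1], [1, 2, 3, 4], [True] * 4)
        with pytest.raises(IdentifiabilityError):
            fit_cure_cox(cohort, bootstrap_reps=0)

    def test_no_events_unidentified(self):
        cohort = make_toy_cohort([0, 1, 0, 1], [1, 2, 3, 4], [False] * 4)
        with pytest.raises(IdentifiabilityError):
            fit_cure_cox(cohort, bootstrap_reps=0)

    def test_determinism(self, effect_cohort):
        a = fit_cure_cox(effect_cohort, bootstrap_reps=20, seed=42)
        b = fit_cure_cox(effect_cohort, bootstrap_reps=20, seed=42)
        assert a.logistic_part == b.logistic_part
        assert a.survival_part == b.survival_part
        assert a.bootstrap_reps_used == b.bootstrap_reps_used

    def test_mstep_reduces_to_cox_with_unit_weights(self, effect_cohort):
        time = effect_cohort["obs_time"].to_numpy(dtype=float)
        event = effect_cohort["event"].to_numpy(dtype=bool)
        x = effect_cohort["genotype"].to_numpy(dtype=float)
        beta_w, _, conv, _ = _cox_nr(time, event, x, np.ones(len(time)))
        plain = fit_cox(effect_cohort)
        assert conv
        assert beta_w == plain.estimate

    def test_loglik_nondecreasing(self, effect_cohort):
        fit = fit_cure_cox(effect_cohort, bootstrap_reps=0, track_loglik=True)
        trace = np.asarray(fit.loglik_trace)
        assert trace.size >= 2
        assert np.all(np.diff(trace) >= -1e-8)

    def test_parameter_recovery(self):
        """EM recovers the simulated log-OR and log-HR within 3 bootstrap SEs."""
        design = SimDesign(
            cure_fraction=0.5,
            h2_snp_logistic=0.01,
            h2_snp_survival=0.01,
            n_subjects=5000,
        )
        effects = resolve_effects(design)
        cohort = simulate_cohort(design, effects, seed=2024)
        fit = fit_cure_cox(cohort, bootstrap_reps=40, seed=9)
        assert fit.em_converged
        assert fit.bootstrap_reps_used >= 30
        assert abs(fit.logistic_part.estimate - effects.beta_snp_logistic) < (
            3 * fit.logistic_part.se
        )
        assert abs(fit.survival_part.estimate - effects.beta_snp_loghr) < (
            3 * fit.survival_part.se
        )
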