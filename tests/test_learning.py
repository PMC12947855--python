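"""Delta-rule updates, choice likelihood, hierarchical fit, model comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import special

from reachvigor import cohort, learning as lr


class TestValueUpdates:
    def test_single_update(self):
        state = lr.ValueState()
        state, vpe = lr.update_value(state, 1, 1.0, eta=0.5, effort_cost=0.0)
        assert state.V[0] == pytest.approx(0.5)
        assert vpe == pytest.approx(1.0)

    def test_effort_applies_only_to_high_effort_targets(self):
        s1, vpe1 = lr.update_value(lr.ValueState(), 1, 1.0, 0.5, -0.4)
        s2, vpe2 = lr.update_value(lr.ValueState(), 2, 1.0, 0.5, -0.4)
        assert vpe1 == pytest.approx(1.0)
        assert vpe2 == pytest.approx(0.6)

    def test_eta_bounds_enforced(self):
        with pytest.raises(ValueError):
            lr.update_value(lr.ValueState(), 1, 1.0, 0.0, 0.0)

    def test_fixed_point_p_plus_e(self):
        """Under constant Bernoulli(2/3) reward on a high-effort target the
        value converges to p + e = 2/3 - 0.429."""
        rng = np.random.default_rng(0)
        state = lr.ValueState()
        vals = []
        for i in range(10_000):
            r = float(rng.random() < 2 / 3)
            state, _ = lr.update_value(state, 2, r, eta=0.182, effort_cost=-0.429)
            if i > 2000:
                vals.append(state.V[1])
        assert np.mean(vals) == pytest.approx(2 / 3 - 0.429, abs=0.02)

    def test_alternative_model_fixed_points(self):
        rng = np.random.default_rng(1)
        state = lr.ValueState()
        rhats = []
        for i in range(10_000):
            r = float(rng.random() < 2 / 3)
            state, _ = lr.update_value_alternative(state, 2, r, 0.182, -0.429)
            if i > 2000:
                rhats.append(state.R_hat[1])
        assert np.mean(rhats) == pytest.approx(2 / 3, abs=0.02)
        # decision value adds the effort cost -> same asymptote as VPE model
        dv = lr.decision_values(state, -0.429, "alternative")
        assert dv[1] == pytest.approx(state.R_hat[1] - 0.429)

    def test_models_coincide_without_effort(self):
        rng = np.random.default_rng(2)
        s_vpe, s_alt = lr.ValueState(), lr.ValueState()
        for _ in range(200):
            t = int(rng.integers(1, 5))
            r = float(rng.random() < 0.5)
            s_vpe, _ = lr.update_value(s_vpe, t, r, 0.3, 0.0)
            s_alt, _ = lr.update_value_alternative(s_alt, t, r, 0.3, 0.0)
        assert np.allclose(s_vpe.V, lr.decision_values(s_alt, 0.0, "alternative"))

    def test_simple_alternative_update(self):
        s = lr.ValueState(R_hat=np.array([0.0, 0.5, 0.0, 0.0]))
        s, _ = lr.update_value_alternative(s, 2, 0.0, 0.2, 0.0)
        assert s.R_hat[1] == pytest.approx(0.4)

    def test_contraction_toward_fixed_point(self):
        """|V' - (p+e)| <= (1-eta)|V - (p+e)| in expectation."""
        p, e, eta = 2 / 3, -0.3, 0.25
        fp = p + e
        for v0 in (-1.0, 0.0, 0.5, 2.0):
            expected_v1 = v0 + eta * (p + e - v0)  # expectation over R
            assert abs(expected_v1 - fp) <= (1 - eta) * abs(v0 - fp) + 1e-12


class TestChoiceLoglik:
    def test_indifference(self):
        ll = lr.choice_loglik([0.3, -0.2, 0.5], [1, 0, 1], tau=0.0)
        assert ll == pytest.approx(3 * np.log(0.5))

    def test_manual_three_choice_example(self):
        diffs, choices, tau = [0.2, -0.1, 0.4], [1, 0, 1], 3.0
        manual = (np.log(special.expit(3 * 0.2))
                  + np.log(1 - special.expit(3 * -0.1))
                  + np.log(special.expit(3 * 0.4)))
        assert lr.choice_loglik(diffs, choices, tau) == pytest.approx(manual)

    def test_separable_limit(self):
        ll = lr.choice_loglik([1.0, 2.0], [1, 1], tau=200.0)
        assert -1e-10 < ll <= 0.0

    def test_analytic_gradient_matches_finite_differences(self, learned_schedules):
        agent = cohort.AgentParams(zeta=-1.2, e=-0.5, tau=3.0, subject=0)
        rec, _ = cohort.simulate_experiment(agent, learned_schedules, seed=3)
        rec["subject"] = 0
        data = lr.ChoiceData.from_records(rec)
        st, sr = data.single_targets[0], data.single_rewards[0]
        ca, cb, ya = data.choice_a[0], data.choice_b[0], data.chose_a[0]
        x0 = np.array([-1.0, -0.3, 2.5])

        def f(x):
            return lr.cohort_loglik(np.array([x[0]]), np.array([x[1]]),
                                    np.array([x[2]]), data)

        grad = lr.choice_loglik_grad(*x0, st, sr, ca, cb, ya)
        h = 1e-6
        for i in range(3):
            xp, xm = x0.copy(), x0.copy()
            xp[i] += h
            xm[i] -= h
            fd = (f(xp) - f(xm)) / (2 * h)
            assert grad[i] == pytest.approx(fd, abs=1e-4 * max(1, abs(fd)))


class TestAicc:
    def test_closed_form_hand_computation(self):
        ll, k, n = -42.0, 3, 50
        expected = -2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        assert lr.aicc(ll, k, n) == pytest.approx(expected)
        assert lr.aicc(ll, k, n) == pytest.approx(90.52173913, abs=1e-6)

    def test_degenerate_sample_size(self):
        assert lr.aicc(-1.0, 5, 6) == np.inf


class TestHierarchicalFit:
    def test_map_recovers_effort_sign_and_scale(self, small_learned_cohort):
        fit = lr.fit_hierarchical(small_learned_cohort, method="map", seed=0)
        assert fit.e_pop_mean < 0
        assert 0.0 < fit.eta_pop_mean < 1.0
        assert np.isfinite(fit.aicc)
        assert 0.5 < fit.accuracy <= 1.0

    def test_needs_two_subjects(self, small_learned_cohort):
        one = small_learned_cohort[small_learned_cohort.subject == 0]
        with pytest.raises(ValueError):
            lr.fit_hierarchical(one, method="map")

    def test_prior_predictive_eta_in_unit_interval(self):
        rng = np.random.default_rng(0)
        zeta = rng.normal(0, 10, 1000)
        eta = special.expit(zeta)
        assert np.all((eta > 0) & (eta < 1))


class TestModelComparison:
    @pytest.fixture(scope="class")
    def fits(self, small_learned_cohort):
        data = lr.ChoiceData.from_records(small_learned_cohort)
        f_vpe = lr.fit_hierarchical(data, model="vpe", method="map", seed=0)
        f_alt = lr.fit_hierarchical(data, model="alternative", method="map", seed=0)
        return data, f_vpe, f_alt

    def test_identical_models_give_null_comparison(self, fits):
        data, f_vpe, _ = fits
        rep = lr.compare_models(f_vpe, f_vpe, data, n_boot=200, seed=1)
        assert rep["auc_difference"] == 0.0
        assert rep["p_value"] == pytest.approx(1.0, abs=0.05)

    def test_vpe_model_fits_vpe_generated_data_better(self, fits):
        """Data generated with a strong effort cost inside the learning loop
        should favor the VPE model on predictive accuracy."""
        data, f_vpe, f_alt = fits
        rep = lr.compare_models(f_vpe, f_alt, data, n_boot=200, seed=2)
        assert rep["accuracy_vpe"] >= rep["accuracy_alternative"] - 0.01
        assert rep["auc_vpe"] >= rep["auc_alternative"] - 0.01


class TestValueUpdateCorrelates:
    def test_positive_correlation_with_value_gain(self):
        kin = cohort.KinematicGenParams(value_gain=0.5, gamma_shape=1e4)
        rec, _ = cohort.simulate_cohort(n_subjects=6, kin=kin, seed=5)
        rep = lr.value_update_correlates(rec)
        assert rep["r"] > 0
        assert rep["p"] < 0.01
        # effort-matched, different-direction control carries no target-specific update
        assert abs(rep["control_r"]) < rep["r"]

    def test_shuffled_vpes_uncorrelated(self):
        kin = cohort.KinematicGenParams(value_gain=0.5, gamma_shape=1e4)
        rec, _ = cohort.simulate_cohort(n_subjects=6, kin=kin, seed=5)
        rng = np.random.default_rng(0)
        rec = rec.copy()
        rec["vpe"] = rng.permutation(rec["vpe"].to_numpy())
        rep = lr.value_update_correlates(rec)
        assert abs(rep["r"]) < 0.05

    def test_insufficient_pairs_raises(self, small_learned_cohort):
        with pytest.raises(ValueError):
            lr.value_update_correlates(small_learned_cohort.head(3))
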