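"""Unit and property tests for the dose-toxicity model core."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit, logit

import bayesdose as bd
from bayesdose.model import InferenceSettings, TrialData

from conftest import grid_oracle


class TestLogisticRisk:
    def test_control_anchor(self):
        # d0 = 0 pins the control risk at expit(theta1) whatever theta2 is
        for theta2 in (0.0, 0.5, 7.0):
            assert bd.logistic_risk(logit(0.1), theta2, 0.0) == pytest.approx(0.1)

    def test_flat_model(self):
        assert bd.logistic_risk(0.0, 0.0, 5.0) == pytest.approx(0.5)

    def test_direct_evaluation(self):
        assert bd.logistic_risk(logit(0.1), 1.0, 1.0) == pytest.approx(0.2320, abs=5e-5)

    def test_negative_theta2_rejected(self):
        with pytest.raises(ValueError):
            bd.logistic_risk(0.0, -0.1, 1.0)

    def test_extreme_linear_predictor_stable(self):
        assert bd.logistic_risk(-700.0, 0.0, 0.0) == pytest.approx(0.0)
        assert bd.logistic_risk(350.0, 350.0, 1.0) == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        theta1=st.floats(-5, 5),
        theta2=st.floats(0, 5),
        d_lo=st.floats(-3, 3),
        d_inc=st.floats(0, 3),
    )
    def test_monotone_in_dose(self, theta1, theta2, d_lo, d_inc):
        assert bd.logistic_risk(theta1, theta2, d_lo + d_inc) >= bd.logistic_risk(
            theta1, theta2, d_lo
        )


class TestSkeleton:
    def test_calibrated_increment(self):
        sk = bd.build_skeleton(0.10, 0.075, 4)
        assert sk.p_prior == pytest.approx([0.175, 0.25, 0.325, 0.40])

    def test_equal_spacing(self):
        assert bd.build_skeleton(0.10, 0.05, 4).p_prior == pytest.approx(
            [0.15, 0.20, 0.25, 0.30]
        )

    def test_leaving_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            bd.build_skeleton(0.10, 0.25, 4)

    def test_non_increasing_rejected(self):
        with pytest.raises(ValueError):
            bd.Skeleton(p0=0.1, nu=0.05, p_prior=(0.3, 0.2, 0.4))


class TestStandardizedDoses:
    def test_round_trip_identity(self, design):
        # evaluating the model at the prior locations must recover the skeleton
        mu20 = design.prior.theta2_location(design.theta2_location)
        sk = design.skeleton
        for d_j, p_j in zip(design.std_doses.d, sk.p_prior):
            assert bd.logistic_risk(design.prior.mu1, mu20, d_j) == pytest.approx(
                p_j, abs=1e-10
            )

    def test_lognormal_mean_location_formula(self):
        # sigma2 = 0.30 as an SD: theta2 location exp(-0.05 + 0.30^2/2) = 0.9950
        prior = bd.PriorSpec(mu1=float(logit(0.1)), mu2=-0.05, sigma1=1.10, sigma2=0.30)
        assert prior.theta2_location("mean") == pytest.approx(0.99501, abs=1e-5)
        sk = bd.build_skeleton(0.10, 0.075, 4)
        sd = bd.standardize_doses(sk, prior)
        assert sd.d[0] == pytest.approx(0.6499, abs=2e-4)

    def test_median_location(self):
        prior = bd.PriorSpec(mu1=0.0, mu2=-0.05, sigma1=1.0, sigma2=0.30)
        assert prior.theta2_location("median") == pytest.approx(np.exp(-0.05))

    def test_first_dose_at_prior_control_risk_is_zero(self):
        prior = bd.PriorSpec(mu1=float(logit(0.2)), mu2=0.0, sigma1=1.0, sigma2=0.3)
        sk = bd.Skeleton(p0=0.1, nu=0.1, p_prior=(0.2, 0.3))
        sd = bd.standardize_doses(sk, prior)
        assert sd.d[0] == pytest.approx(0.0, abs=1e-12)

    def test_control_level_fixed_at_zero(self, design):
        assert design.std_doses.with_control[0] == 0.0


class TestPriorState:
    def test_control_risk_mean_above_nominal(self, design):
        # the prior control-risk mean exceeds expit(mu1) (nonlinear transform)
        state = bd.prior_state(design.prior, n_support=100_000, seed=2)
        mean_p0 = float(state.weights @ state.risk_matrix(design.std_doses)[:, 0])
        # 1-D numeric oracle for E[expit(N(mu1, sigma1^2))]
        z = np.linspace(-8, 8, 20_001)
        pdf = np.exp(-0.5 * z**2)
        oracle = float(
            (expit(design.prior.mu1 + design.prior.sigma1 * z) * pdf).sum() / pdf.sum()
        )
        assert mean_p0 > 0.10
        assert mean_p0 == pytest.approx(oracle, abs=0.005)

    def test_degenerate_prior_is_point_mass(self, design):
        prior = bd.PriorSpec(mu1=float(logit(0.1)), mu2=-0.05, sigma1=1e-9, sigma2=1e-9)
        state = bd.prior_state(prior, n_support=2000, seed=0)
        mean_p0 = float(state.weights @ state.risk_matrix(design.std_doses)[:, 0])
        assert mean_p0 == pytest.approx(0.10, abs=1e-6)

    def test_marginal_moments(self, design):
        state = bd.prior_state(design.prior, n_support=200_000, seed=7)
        assert np.mean(state.theta1) == pytest.approx(design.prior.mu1, abs=0.02)
        assert np.std(state.theta1) == pytest.approx(design.prior.sigma1, abs=0.02)
        lt2 = np.log(state.theta2)
        assert np.mean(lt2) == pytest.approx(design.prior.mu2, abs=0.01)
        assert np.std(lt2) == pytest.approx(design.prior.sigma2, abs=0.01)

    def test_requires_support(self, design):
        with pytest.raises(ValueError):
            bd.prior_state(design.prior, n_support=0)


class TestUpdatePosterior:
    def test_empty_data_reproduces_prior(self, design):
        post = bd.update_posterior(design.prior, design.std_doses, TrialData.empty(4))
        prior = bd.prior_state(design.prior, n_support=400_000, seed=3)
        for j in range(5):
            a = bd.query_dose(post, design.std_doses, j)
            b = bd.query_dose(prior, design.std_doses, j)
            assert a.mean_risk == pytest.approx(b.mean_risk, abs=0.005)
            assert a.prob_target == pytest.approx(b.prob_target, abs=0.005)

    def test_clean_data_lowers_risk_below_skeleton(self, design):
        data = TrialData([10, 20, 0, 0, 0], [0, 0, 0, 0, 0])
        post = bd.update_posterior(design.prior, design.std_doses, data)
        q1 = bd.query_dose(post, design.std_doses, 1)
        assert q1.mean_risk < design.skeleton.p_prior[0]
        # verify against the independent fine-grid oracle
        _, _, mean_risks = grid_oracle(design.prior, design.std_doses, data)
        assert q1.mean_risk == pytest.approx(mean_risks[1], abs=0.005)

    def test_arm_mismatch_rejected(self, design):
        with pytest.raises(ValueError):
            bd.update_posterior(design.prior, design.std_doses, TrialData.empty(3))

    @pytest.mark.parametrize(
        "n,y",
        [
            ([2, 4, 0, 0, 0], [0, 3, 0, 0, 0]),
            ([10, 4, 12, 4, 0], [1, 1, 4, 2, 0]),
            ([10, 20, 0, 0, 0], [1, 10, 0, 0, 0]),
        ],
    )
    def test_quadrature_matches_grid_oracle(self, design, n, y):
        data = TrialData(n, y)
        post = bd.update_posterior(design.prior, design.std_doses, data)
        over, target, means = grid_oracle(design.prior, design.std_doses, data)
        for j in range(1, 5):
            q = bd.query_dose(post, design.std_doses, j)
            assert q.prob_overdose == pytest.approx(over[j - 1], abs=0.01)
            assert q.prob_target == pytest.approx(target[j - 1], abs=0.01)
            assert q.mean_risk == pytest.approx(means[j], abs=0.01)

    def test_mcmc_matches_quadrature(self, design):
        data = TrialData([10, 4, 12, 4, 0], [1, 1, 4, 2, 0])
        quad = bd.update_posterior(design.prior, design.std_doses, data)
        mcmc = bd.update_posterior(
            design.prior,
            design.std_doses,
            data,
            InferenceSettings(backend="mcmc", n_samples=1500, n_burn=500, seed=4),
        )
        for j in range(5):
            a = bd.query_dose(quad, design.std_doses, j)
            b = bd.query_dose(mcmc, design.std_doses, j)
            assert a.mean_risk == pytest.approx(b.mean_risk, abs=0.01)
            assert a.prob_overdose == pytest.approx(b.prob_overdose, abs=0.01)
            assert a.prob_target == pytest.approx(b.prob_target, abs=0.01)

    def test_posterior_mean_risks_monotone(self, design):
        data = TrialData([6, 8, 8, 4, 4], [1, 1, 2, 2, 3])
        post = bd.update_posterior(design.prior, design.std_doses, data)
        means = post.mean_risks(design.std_doses)
        assert np.all(np.diff(means) >= 0)


class TestQueryDose:
    def test_point_mass_ardlt(self, design):
        from conftest import FixedRiskState

        state = FixedRiskState([[0.10, 0.30, 0.45, 0.60, 0.70]])
        q = bd.query_dose(state, design.std_doses, 1)
        assert q.ardlt_mean == pytest.approx(0.20)
        assert q.prob_target == 1.0
        assert q.prob_overdose == 0.0

    def test_point_mass_overdose(self, design):
        from conftest import FixedRiskState

        state = FixedRiskState([[0.10, 0.45, 0.5, 0.6, 0.7]])
        q = bd.query_dose(state, design.std_doses, 1)
        assert q.prob_overdose == 1.0

    def test_hand_weighted_support(self, design):
        from conftest import FixedRiskState

        rng = np.random.default_rng(5)
        p0 = rng.uniform(0.05, 0.2, size=10)
        risks = np.column_stack([p0] + [np.clip(p0 + rng.uniform(0, 0.5, 10), 0, 1) for _ in range(4)])
        risks[:, 1:] = np.sort(risks[:, 1:], axis=1)
        w = rng.uniform(0.5, 1.5, 10)
        state = FixedRiskState(risks, w)
        q = bd.query_dose(state, design.std_doses, 2)
        # brute-force enumeration over the 10 support points
        wn = w / w.sum()
        ardlt = risks[:, 2] - risks[:, 0]
        assert q.prob_overdose == pytest.approx(float(wn @ (ardlt >= 0.30)))
        assert q.prob_target == pytest.approx(
            float(wn @ ((ardlt >= 0.15) & (ardlt <= 0.25)))
        )
        assert q.mean_risk == pytest.approx(float(wn @ risks[:, 2]))

    def test_control_invariant_to_theta2(self, design):
        t2 = np.array([0.1, 1.0, 5.0])
        state = bd.PosteriorState(np.full(3, logit(0.2)), t2, np.full(3, 1 / 3))
        q = bd.query_dose(state, design.std_doses, 0)
        assert q.mean_risk == pytest.approx(0.2)
        assert q.ci_low == pytest.approx(q.ci_high, abs=1e-12)

    def test_out_of_range_arm(self, design):
        post = bd.update_posterior(design.prior, design.std_doses, TrialData.empty(4))
        with pytest.raises(IndexError):
            bd.query_dose(post, design.std_doses, 5)

    def test_weights_conservation(self, design):
        post = bd.update_posterior(
            design.prior, design.std_doses, TrialData([2, 4, 0, 0, 0], [1, 2, 0, 0, 0])
        )
        assert post.weights.sum() == pytest.approx(1.0, abs=1e-10)
        q = bd.query_dose(post, design.std_doses, 3)
        assert 0 <= q.prob_overdose <= 1
        assert 0 <= q.prob_target <= 1
        assert q.ci_low <= q.mean_risk <= q.ci_high
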