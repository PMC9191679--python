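"""Unit and property tests for the two-stage binary network model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from antquorum import spin_model as sm


def colony(n=10, beta2=10.0, **kw):
    kw.setdefault("thresholds", np.zeros(n))
    return sm.SpinColony(beta2=beta2, **kw)


class TestSampleThresholds:
    def test_zero_variance_gives_constant(self, rng):
        dist = sm.ThresholdDistribution(34.0, 0.0)
        out = sm.sample_thresholds(dist, 5, rng)
        assert np.allclose(out, 34.0)

    def test_law_of_large_numbers(self, rng):
        dist = sm.ThresholdDistribution(34.0, 2.0)
        out = sm.sample_thresholds(dist, 10**5, rng)
        assert abs(out.mean() - 34.0) < 0.02
        assert abs(out.std(ddof=1) - 2.0) < 0.02

    def test_rejects_nonpositive_n(self, rng):
        with pytest.raises(ValueError):
            sm.sample_thresholds(sm.ThresholdDistribution(), 0, rng)


class TestActivation:
    def test_symmetry_at_zero_input(self):
        for beta in (0.1, 1.0, 100.0):
            assert sm.activation_probability(0.0, beta) == 0.5

    def test_closed_form(self):
        assert np.isclose(sm.activation_probability(np.log(3.0), 1.0), 0.75)

    def test_extreme_arguments_do_not_overflow(self):
        p = sm.activation_probability(-0.1, 1000.0)
        assert 0.0 < p < 1e-40
        assert sm.activation_probability(0.1, 1000.0) == pytest.approx(1.0, abs=1e-40)
        # far beyond exp underflow: saturates cleanly
        assert sm.activation_probability(-10.0, 1000.0) == 0.0
        assert sm.activation_probability(10.0, 1000.0) == 1.0

    @given(h=st.floats(-50, 50), beta=st.floats(0, 50))
    @settings(max_examples=50, derandomize=True)
    def test_bounded_and_monotone_in_h(self, h, beta):
        p = sm.activation_probability(h, beta)
        assert 0.0 <= p <= 1.0
        assert sm.activation_probability(h + 1.0, beta) >= p


class TestStage1:
    def test_all_thresholds_exceeded(self, rng):
        col = colony(20, thresholds=np.full(20, 34.0), beta1=50.0)
        out, m0 = sm.stage1_response(col, 34.0 + 10 * 2.0, rng)
        assert m0 == 1.0
        assert np.all(out.states == 1)

    def test_median_activation_at_mean_threshold(self, rng):
        n = 20000
        th = rng.normal(34.0, 2.0, n)
        col = colony(n, thresholds=th, beta1=1000.0)
        _, m0 = sm.stage1_response(col, 34.0, rng)
        assert abs(m0 - 0.5) < 0.02

    def test_per_ant_probabilities(self, rng):
        # T=34, thresholds {33,35}, beta=10: p = sigmoid(+-10)
        col = colony(2, thresholds=np.array([33.0, 35.0]), beta1=10.0)
        p = sm.activation_probability(34.0 - col.thresholds, col.beta1)
        assert np.allclose(p, [1 / (1 + np.exp(-10)), 1 / (1 + np.exp(10))])
        # order parameter definition: m = (1/2N) sum(sigma+1)
        out, m0 = sm.stage1_response(col, 34.0, rng)
        assert m0 == np.sum(out.states + 1) / (2 * 2)


class TestSocialInput:
    def test_symmetric_balance_point(self):
        col = colony(10, j_p=0.3, j_r=0.3)
        assert sm.social_input(0.5, col) == pytest.approx(0.0)

    def test_asymmetric_scaling_arithmetic(self):
        col = colony(10, j_p=1.0, j_r=0.1, alpha_p=0.0, alpha_r=1.0)
        # h = 1*0.5 - 10*0.1*0.5 = 0
        assert sm.social_input(0.5, col) == pytest.approx(0.0)

    def test_state_independent_pull_at_zero(self):
        col = colony(10, j_p=0.5, j_r=0.2, inhibition_mode="state_independent")
        assert sm.social_input(0.0, col) == pytest.approx(-10 * 0.2)

    def test_rejects_m_outside_unit_interval(self):
        with pytest.raises(ValueError):
            sm.social_input(1.2, colony())


class TestSeparatrix:
    def test_equal_strengths(self):
        assert sm.separatrix(colony(10, j_p=1.0, j_r=1.0)).m_c == pytest.approx(0.5)

    def test_double_inhibition(self):
        assert sm.separatrix(colony(10, j_p=1.0, j_r=2.0)).m_c == pytest.approx(2 / 3)

    def test_asymmetric_saturates_toward_one(self):
        mc = sm.separatrix(
            colony(10**6, j_p=1.0, j_r=1.0, alpha_p=0.0, alpha_r=1.0)
        ).m_c
        assert mc > 0.999

    def test_state_independent_no_response_flag(self):
        col = colony(10, j_p=0.1, j_r=0.5, alpha_p=1.0, alpha_r=1.0,
                     inhibition_mode="state_independent")
        sep = sm.separatrix(col)
        assert not sep.valid and sep.m_c >= 1.0

    def test_rejects_zero_interactions(self):
        with pytest.raises(ValueError):
            sm.separatrix(colony(10, j_p=0.0, j_r=0.0))


class TestPredictThreshold:
    def test_median_is_mean_threshold(self):
        dist = sm.ThresholdDistribution(34.0, 2.0)
        assert sm.predict_threshold(0.5, dist) == pytest.approx(34.0)

    def test_degenerate_distribution(self):
        dist = sm.ThresholdDistribution(34.0, 0.0)
        for mc in (0.1, 0.5, 0.9):
            assert sm.predict_threshold(mc, dist) == pytest.approx(34.0)

    def test_one_sigma_quantile(self):
        dist = sm.ThresholdDistribution(34.0, 2.0)
        assert sm.predict_threshold(norm.cdf(1.0), dist) == pytest.approx(36.0, abs=1e-9)

    def test_rejects_degenerate_mc(self):
        with pytest.raises(ValueError):
            sm.predict_threshold(1.0, sm.ThresholdDistribution())


class TestStage2:
    def test_all_active_is_fixed_point(self, rng):
        col = colony(20, beta2=100.0, j_p=1.0, j_r=1.0,
                     states=np.ones(20, dtype=np.int8))
        run = sm.stage2_dynamics(col, rng=rng)
        assert run.final_m == 1.0 and run.responded

    def test_all_inactive_is_fixed_point(self, rng):
        col = colony(20, beta2=100.0, j_p=1.0, j_r=1.0)
        run = sm.stage2_dynamics(col, rng=rng)
        assert run.final_m == 0.0 and not run.responded

    def test_trajectory_bookkeeping(self, rng):
        col = colony(7, states=np.array([1, 1, 1, -1, -1, -1, -1], dtype=np.int8))
        run = sm.stage2_dynamics(col, n_cycles=5, rng=rng)
        assert run.m_trajectory.shape == (6,)
        assert run.m0 == pytest.approx(3 / 7)
        assert np.all((run.m_trajectory >= 0) & (run.m_trajectory <= 1))

    def test_permutation_update_mode(self, rng):
        col = colony(12, beta2=100.0, j_p=1.0, j_r=1.0,
                     states=np.ones(12, dtype=np.int8))
        run = sm.stage2_dynamics(col, rng=rng, update="permutation")
        assert run.final_m == 1.0


def _brute_force_absorption(n, beta2, j_p, j_r, n_cycles=20):
    """Exhaustive 2^n Markov chain for the asynchronous dynamics: one-step
    matrix over full state space, powered over all update steps."""
    from antquorum._logistic import sigmoid

    n_states = 2**n
    T = np.zeros((n_states, n_states))
    for s in range(n_states):
        bits = np.array([(s >> i) & 1 for i in range(n)])
        m = bits.mean()
        h = n * j_p * m - n * j_r * (1 - m)
        p_act = sigmoid(beta2 * h)
        for i in range(n):
            for new_bit, pb in ((1, p_act), (0, 1 - p_act)):
                s2 = (s & ~(1 << i)) | (new_bit << i)
                T[s, s2] += (1.0 / n) * pb
    M = np.linalg.matrix_power(T, n_cycles * n)
    # P(final m >= 0.5) grouped by initial active count
    popcount = np.array([bin(s).count("1") for s in range(n_states)])
    final_resp = popcount >= int(np.ceil(n / 2))
    probs = np.zeros(n + 1)
    for k in range(n + 1):
        states_k = np.nonzero(popcount == k)[0]
        probs[k] = M[states_k][:, final_resp].sum(axis=1).mean()
    return probs


class TestExactChain:
    def test_matches_exhaustive_enumeration(self):
        """Birth-death reduction equals the full 2^5 transition matrix."""
        col = colony(5, beta2=50.0, j_p=1.0, j_r=1.0)
        exact = sm.exact_response_probabilities(col)
        brute = _brute_force_absorption(5, 50.0, 1.0, 1.0)
        assert np.allclose(exact, brute, atol=1e-9)

    def test_deterministic_limit_attractors(self):
        """beta -> inf: the colony responds iff m0 > mc = 1/2."""
        col = colony(5, beta2=50.0, j_p=1.0, j_r=1.0)
        probs = sm.exact_response_probabilities(col)
        assert np.allclose(probs, [0, 0, 0, 1, 1, 1], atol=1e-6)

    def test_matches_stochastic_simulation(self, rng):
        col = colony(6, beta2=5.0, j_p=0.5, j_r=0.5)
        exact = sm.exact_response_probabilities(col)
        k0 = 2
        hits = 0
        n_runs = 2000
        from antquorum.spin_model import _batch_stage2

        states0 = np.zeros((n_runs, 6), dtype=bool)
        states0[:, :k0] = True
        m = _batch_stage2(states0, col, 20, rng)
        hits = np.sum(m[:, -1] >= 0.5)
        se = np.sqrt(exact[k0] * (1 - exact[k0]) / n_runs)
        assert abs(hits / n_runs - exact[k0]) < 4 * se + 1e-3

    def test_absorbing_states_stay_put(self):
        """With high beta the all-active/all-inactive states are absorbing
        to within ~1e-10 per step (bistability condition)."""
        from antquorum.spin_model import _birth_death_matrix

        col = colony(20, beta2=50.0 / (20 * 1.0), j_p=1.0, j_r=1.0)
        T = _birth_death_matrix(col)
        assert T[0, 1] < 1e-10
        assert T[20, 19] < 1e-10


class TestResponseCurve:
    def test_far_below_thresholds_never_responds(self, rng):
        dist = sm.ThresholdDistribution(34.0, 1.0)
        rc = sm.simulate_response_curve(
            dist, 30, np.array([20.0, 22.0]), rng, n_runs=30, beta1=5.0
        )
        assert np.all(rc.response_prob == 0.0)
        assert rc.degenerate and rc.fit is None

    def test_symmetric_model_recovers_theta_m(self, rng):
        dist = sm.ThresholdDistribution(34.0, 2.0)
        rc = sm.simulate_response_curve(
            dist, 50, np.arange(30.0, 38.5, 0.5), rng,
            n_runs=150, beta1=10.0, beta2=20.0, j_p=0.1, j_r=0.1,
        )
        assert rc.fit is not None
        assert abs(rc.fit.theta_c - 34.0) < 0.25

    def test_run_records_are_tidy(self, rng):
        dist = sm.ThresholdDistribution(34.0, 2.0)
        rc = sm.simulate_response_curve(
            dist, 10, np.array([30.0, 38.0]), rng, n_runs=5, keep_runs=True
        )
        assert len(rc.runs) == 10
        assert set(rc.runs.columns) == {
            "temperature", "n_ants", "run_id", "m0", "final_m", "responded"
        }


class TestColonyValidation:
    def test_state_vector_must_be_spins(self):
        with pytest.raises(ValueError):
            sm.SpinColony(thresholds=np.zeros(3), states=np.array([1, 0, -1]))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            sm.SpinColony(thresholds=np.zeros(3), states=np.ones(4, dtype=np.int8))

    def test_negative_couplings_rejected(self):
        with pytest.raises(ValueError):
            sm.SpinColony(thresholds=np.zeros(3), j_p=-0.1)
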