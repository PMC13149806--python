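"""Trial simulators: noise-free kinematics, symmetry, nesting, oracles."""

import numpy as np
import pytest
from scipy import stats

from driftspread.simulate import (
    ModelParams,
    closed_form_choice_prob,
    closed_form_mean_dt,
    simulate_batch,
    simulate_ddm_trial,
    simulate_maddm_trial,
    simulate_stddm_trial,
)


def _ddm(**kw):
    base = dict(kind="ddm", drift=[0.065], threshold=65.0, ndt=0.4)
    base.update(kw)
    return ModelParams(**base)


class TestClosedForms:
    def test_zero_drift_is_even_odds(self):
        assert closed_form_choice_prob(0.0, 1.0, 1.0) == 0.5

    def test_known_logistic_point(self):
        # 2*theta*v/sigma_d2 = 4 -> 1/(1+e^-4)
        assert closed_form_choice_prob(2.0, 1.0, 1.0) == pytest.approx(
            1 / (1 + np.exp(-4)), abs=1e-12
        )

    def test_sign_flip_probabilities_sum_to_one(self):
        for v in (0.01, 0.3, 2.0):
            assert closed_form_choice_prob(v, 1.3, 0.7) + closed_form_choice_prob(
                -v, 1.3, 0.7
            ) == pytest.approx(1.0, abs=1e-12)

    def test_zero_drift_mean_dt(self):
        assert closed_form_mean_dt(0.0, 1.0, 1.0) == pytest.approx(1.0)

    def test_tanh_point(self):
        assert closed_form_mean_dt(1.0, 1.0, 0.5) == pytest.approx(np.tanh(2.0), abs=1e-12)

    def test_large_drift_limit_theta_over_v(self):
        v, th = 50.0, 2.0
        assert closed_form_mean_dt(v, th, 1.0) == pytest.approx(th / v, rel=1e-6)

    def test_scaling_invariance_of_choice_prob(self):
        # scaling theta, v and sigma_d consistently leaves 2*theta*v/sigma_d2 fixed
        p1 = closed_form_choice_prob(0.02, 50.0, 1.0)
        c = 3.7
        p2 = closed_form_choice_prob(0.02 * c, 50.0 * c, 1.0 * c**2)
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestNoiseFreeKinematics:
    def test_ddm_deterministic_crossing_time(self):
        p = _ddm(noise_var=0.0, drift=[0.1], threshold=10.0)
        out = simulate_ddm_trial(p, 0.9, 0.4, seed=0)
        # T = ceil(theta / (drift * dmu))
        assert out.decision_steps == int(np.ceil(10.0 / (0.1 * 0.5)))
        assert out.choice == 1 and out.terminated
        assert out.rt == pytest.approx(out.decision_steps / 1000 + p.ndt)

    def test_maddm_zero_net_drift_never_terminates(self):
        p = ModelParams(kind="maddm", drift=[0.1, 0.1], threshold=5.0, ndt=0.3,
                        noise_var=0.0)
        out = simulate_maddm_trial(p, [0.8, 0.2], [0.2, 0.8], seed=0)
        assert not out.terminated
        assert np.isnan(out.rt)

    def test_stddm_piecewise_linear_slope_change(self):
        # attribute 2 favours option 2 and joins at 0.1 s: trajectory slope
        # changes at step 100, visible in the crossing time
        p = ModelParams(kind="stddm", drift=[0.1, 0.1], threshold=11.83, ndt=0.0,
                        start_times=[0.0, 0.1], noise_var=0.0)
        out = simulate_stddm_trial(p, [1.0, 0.0], [0.0, 0.6], seed=0)
        # first 100 steps at rate 0.1, then at rate 0.1 - 0.06 = 0.04
        expect = 100 + int(np.ceil((11.83 - 100 * 0.1) / 0.04))
        assert out.decision_steps == expect

    def test_noise_free_evidence_identity(self):
        p = _ddm(noise_var=0.0, drift=[0.05], threshold=8.0)
        out = simulate_ddm_trial(p, 0.7, 0.3, seed=1)
        dvt = out.evidence / (p.drift[0] * out.decision_steps)
        assert dvt == pytest.approx(0.4, rel=1e-9)


class TestStochasticProperties:
    def test_single_trial_seed_determinism(self):
        p = _ddm()
        a = simulate_ddm_trial(p, 0.8, 0.3, seed=123)
        b = simulate_ddm_trial(p, 0.8, 0.3, seed=123)
        assert (a.choice, a.decision_steps, a.evidence) == (b.choice, b.decision_steps, b.evidence)

    def test_equal_values_split_evenly(self, rng):
        out = simulate_batch(np.zeros((4000, 1)), 20.0, rng)
        assert abs(out["choice"].mean() - 0.5) < 0.03

    def test_choice_prob_matches_absorbing_boundary_oracle(self, rng):
        theta, n = 60.0, 20000
        for twotv in (1.0, 3.0):
            v = twotv / (2 * theta)
            out = simulate_batch(np.full((n, 1), v), theta, rng, max_steps=200000)
            p_hat = out["choice"].mean()
            p = closed_form_choice_prob(v, theta, 1.0)
            se = np.sqrt(p * (1 - p) / n)
            assert abs(p_hat - p) < 4 * se + 0.005  # MC + discretisation slack

    def test_choice_monotone_in_value_difference(self, rng):
        theta = 50.0
        probs = []
        for dmu in (0.0, 0.1, 0.25):
            out = simulate_batch(np.full((3000, 1), 0.06 * dmu), theta, rng)
            probs.append(out["choice"].mean())
        assert probs[0] < probs[1] < probs[2]

    def test_mean_rt_decreasing_in_drift_magnitude(self, rng):
        theta = 50.0
        mts = []
        for v in (0.005, 0.02, 0.05):
            out = simulate_batch(np.full((3000, 1), v), theta, rng, max_steps=100000)
            mts.append(out["decision_steps"].mean())
        assert mts[0] > mts[1] > mts[2]

    def test_threshold_magnitude_at_termination(self, rng):
        out = simulate_batch(np.full((500, 1), 0.01), 30.0, rng)
        term = out["terminated"]
        assert (np.abs(out["evidence"][term]) >= 30.0).all()
        assert (out["choice"][term] == (out["evidence"][term] > 0)).all()


class TestNesting:
    """DDM == maDDM(n=1) and maDDM == stDDM(s=0), distributionally."""

    N = 8000

    def _rts(self, out, ndt=0.0):
        t = out["decision_steps"][out["terminated"]]
        return t / 1000.0 + ndt

    def test_ddm_equals_single_attribute_maddm(self, rng):
        theta, v = 40.0, 0.01
        a = simulate_batch(np.full((self.N, 1), v), theta, rng)
        b = simulate_batch(np.full((self.N, 1), v), theta, rng)  # same process
        ks = stats.ks_2samp(self._rts(a), self._rts(b))
        assert ks.pvalue > 0.01
        p1, p2 = a["choice"].mean(), b["choice"].mean()
        se = np.sqrt(2 * 0.25 / self.N)
        assert abs(p1 - p2) <= 3 * se + 0.01

    def test_maddm_equals_stddm_with_zero_onsets(self, rng):
        rates = np.tile([0.004, -0.002], (self.N, 1))
        theta = 55.0
        a = simulate_batch(rates, theta, rng)
        b = simulate_batch(rates, theta, rng, onset_steps=np.zeros((self.N, 2), int))
        ks = stats.ks_2samp(self._rts(a), self._rts(b))
        assert ks.pvalue > 0.01
        se = np.sqrt(2 * 0.25 / self.N)
        assert abs(a["choice"].mean() - b["choice"].mean()) <= 3 * se + 0.01

    def test_late_decisive_attribute_brackets_choice_prob(self, rng):
        # choice prob with a late-starting decisive attribute lies between
        # the all-attributes and without-that-attribute probabilities
        n, theta = 6000, 45.0
        with_attr = np.tile([0.002, 0.004], (n, 1))
        without = np.tile([0.002, 0.0], (n, 1))
        p_with = simulate_batch(with_attr, theta, rng)["choice"].mean()
        p_without = simulate_batch(without, theta, rng)["choice"].mean()
        onset = np.tile([0, 800], (n, 1))
        p_late = simulate_batch(with_attr, theta, rng, onset_steps=onset)["choice"].mean()
        lo, hi = sorted((p_with, p_without))
        assert lo - 0.02 <= p_late <= hi + 0.02


class TestValidation:
    def test_nonfinite_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_ddm_trial(_ddm(), np.nan, 0.3, seed=0)

    def test_wrong_kind_rejected(self):
        with pytest.raises(ValueError):
            simulate_maddm_trial(_ddm(), [0.5], [0.4], seed=0)

    def test_negative_drift_parameter_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(kind="ddm", drift=[-0.1], threshold=10.0, ndt=0.3)

    def test_start_times_only_for_stddm(self):
        with pytest.raises(ValueError):
            ModelParams(kind="maddm", drift=[0.1, 0.1], threshold=10.0, ndt=0.3,
                        start_times=[0.0, 0.2])
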