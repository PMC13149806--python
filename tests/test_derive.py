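"""Derived quantities and exclusion rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from driftspread.derive import (
    compute_disparity,
    compute_trial_differences,
    filter_trials,
    fit_attribute_weights,
    screen_participants,
)


def _ratings(pid, P, N, V):
    return pd.DataFrame(
        {"participant_id": pid, "option_id": range(len(P)), "P": P, "N": N, "V": V}
    )


class TestAttributeWeights:
    def test_exact_linear_data_recovered(self, rng):
        P = rng.uniform(size=30)
        N = rng.uniform(size=30)
        V = 0.3 * P + 0.7 * N
        w = fit_attribute_weights(_ratings(0, P, N, V))
        assert w.loc[0, "w_P"] == pytest.approx(0.3, abs=1e-10)
        assert w.loc[0, "w_N"] == pytest.approx(0.7, abs=1e-10)
        assert w.loc[0, "fit_r2"] == pytest.approx(1.0, abs=1e-10)
        assert not w.loc[0, "flagged"]

    def test_pure_noise_weights_near_zero(self, rng):
        n = 4000
        P, N = rng.uniform(size=n), rng.uniform(size=n)
        V = rng.uniform(size=n)  # independent of attributes
        w = fit_attribute_weights(_ratings(0, P, N, V))
        # CI half-width ~ 3.5 * sd(V)/ (sd(P) sqrt(n)) ~ 0.06
        assert abs(w.loc[0, "w_P"]) < 0.06
        assert abs(w.loc[0, "w_N"]) < 0.06

    def test_collinear_attributes_flagged(self, rng):
        P = rng.uniform(size=20)
        w = fit_attribute_weights(_ratings(0, P, P, P))
        assert bool(w.loc[0, "flagged"])
        assert np.isnan(w.loc[0, "w_P"])


class TestDisparity:
    def test_hand_example_sqrt2(self):
        assert compute_disparity(1, 0, 0, 1, 1, 1) == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_identical_options_zero(self):
        assert compute_disparity(0.4, 0.7, 0.4, 0.7, 1.2, 0.8) == pytest.approx(0.0, abs=1e-12)

    def test_pure_value_difference_zero(self):
        # both options project identically onto the iso-value vector
        assert compute_disparity(1, 1, 0, 0, 1, 1) == pytest.approx(0.0, abs=1e-12)

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            compute_disparity(1, 0, 0, 1, 0, 0)

    @given(
        p_i=st.floats(0, 1), n_i=st.floats(0, 1),
        p_j=st.floats(0, 1), n_j=st.floats(0, 1),
        w_p=st.floats(0.05, 2), w_n=st.floats(0.05, 2),
        c=st.floats(0.1, 10),
    )
    @settings(derandomize=True, max_examples=200)
    def test_swap_and_scale_invariance(self, p_i, n_i, p_j, n_j, w_p, w_n, c):
        d = compute_disparity(p_i, n_i, p_j, n_j, w_p, w_n)
        d_swap = compute_disparity(p_j, n_j, p_i, n_i, w_p, w_n)
        d_scale = compute_disparity(p_i, n_i, p_j, n_j, c * w_p, c * w_n)
        assert d == pytest.approx(d_swap, rel=1e-9, abs=1e-12)
        assert d == pytest.approx(d_scale, rel=1e-9, abs=1e-12)


class TestTrialDifferences:
    def test_dv_is_option_i_minus_option_j(self, derived_trials, small_cohort):
        _, ratings, pairings, _, _ = small_cohort
        weights, trials = derived_trials
        row = trials.iloc[0]
        r = ratings.set_index(["participant_id", "option_id"])
        vi = r.loc[(row["participant_id"], row["option_i"]), "V"]
        vj = r.loc[(row["participant_id"], row["option_j"]), "V"]
        assert row["dv"] == pytest.approx(vi - vj)
        assert row["abs_dv"] == pytest.approx(abs(row["dv"]))

    def test_swapped_pair_flips_dv_keeps_disparity(self, derived_trials, small_cohort):
        _, ratings, pairings, _, _ = small_cohort
        weights, trials = derived_trials
        swapped = pairings.rename(columns={"option_i": "option_j", "option_j": "option_i"})
        trials_sw = compute_trial_differences(ratings, swapped, weights)
        np.testing.assert_allclose(trials_sw["dv"], -trials["dv"])
        np.testing.assert_allclose(trials_sw["disparity"], trials["disparity"])

    def test_missing_rating_names_trial(self, derived_trials, small_cohort):
        _, ratings, pairings, _, _ = small_cohort
        weights, _ = derived_trials
        bad = pairings.copy()
        bad.loc[0, "option_j"] = 9999
        with pytest.raises(ValueError, match="trial"):
            compute_trial_differences(ratings, bad, weights)


class TestFilterTrials:
    def test_toy_rt_set(self):
        t = pd.DataFrame({"rt": [0.3, 0.5, 2.0, 10.0, 11.2], "terminated": True})
        kept, logrec = filter_trials(t)
        assert sorted(kept["rt"]) == [0.5, 2.0, 10.0]  # boundaries retained
        assert logrec["n_kept"] == 3 and logrec["n_too_fast"] == 1

    def test_all_in_range_identity(self):
        t = pd.DataFrame({"rt": [1.0, 2.0, 3.0], "terminated": True})
        kept, logrec = filter_trials(t)
        pd.testing.assert_frame_equal(kept, t)
        assert logrec["excluded_fraction"] == 0.0

    def test_negative_rt_is_integrity_error(self):
        with pytest.raises(ValueError):
            filter_trials(pd.DataFrame({"rt": [-0.1, 1.0], "terminated": True}))

    def test_non_terminated_trials_dropped(self):
        t = pd.DataFrame({"rt": [1.0, np.nan], "terminated": [True, False]})
        kept, logrec = filter_trials(t)
        assert len(kept) == 1 and logrec["n_not_terminated"] == 1

    @given(st.lists(st.floats(0.0, 12.0), min_size=1, max_size=50))
    @settings(derandomize=True, max_examples=100)
    def test_pure_row_subset(self, rts):
        t = pd.DataFrame({"rt": rts, "terminated": True})
        kept, _ = filter_trials(t)
        assert kept.index.isin(t.index).all()
        pd.testing.assert_frame_equal(kept, t.loc[kept.index])


class TestScreening:
    def _table(self, dv, choice):
        return pd.DataFrame({"participant_id": 0, "dv": dv, "choice": choice})

    def test_coin_flip_choices_dropped(self, rng):
        dv = rng.uniform(-0.5, 0.5, size=400)
        choice = rng.integers(0, 2, size=400)
        out = screen_participants(self._table(dv, choice))
        assert abs(out.loc[0, "slope"]) < 1
        assert not out.loc[0, "keep"]

    def test_perfectly_consistent_kept_via_separation(self, rng):
        dv = rng.uniform(-0.5, 0.5, size=60)
        out = screen_participants(self._table(dv, (dv > 0).astype(int)))
        assert np.isinf(out.loc[0, "slope"])
        assert out.loc[0, "keep"]
        assert out.loc[0, "note"] == "separation"

    def test_generating_slope_recovered_and_kept(self, rng):
        dv = rng.uniform(-1, 1, size=2000)
        choice = (rng.uniform(size=2000) < expit(5 * dv)).astype(int)
        out = screen_participants(self._table(dv, choice))
        assert out.loc[0, "keep"]
        assert out.loc[0, "slope"] == pytest.approx(5.0, abs=1.0)

    def test_too_few_trials_flagged(self):
        out = screen_participants(self._table([0.1] * 5, [1] * 5))
        assert out.loc[0, "note"] == "too_few_trials"
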