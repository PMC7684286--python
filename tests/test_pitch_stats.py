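import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pitchsub.pitch_stats import (
    ThresholdController,
    average_daily_change,
    binomial_direction_prob,
    daily_changes,
    daily_summaries,
    direction_and_magnitude,
    dprime,
    paradigm_criteria,
    pitch_trace_dprime,
    update_threshold,
)


def make_summaries(means, variances, bird="b1"):
    return pd.DataFrame(
        {
            "bird_id": bird,
            "day": np.arange(1, len(means) + 1),
            "mean": means,
            "variance": variances,
            "count": 200,
        }
    )


class TestDprime:
    def test_identity(self):
        assert dprime(800.0, 25.0, 800.0, 30.0) == 0.0

    def test_unit_effect(self):
        # one-sigma mean shift at equal variances is exactly d' = 1
        assert dprime(700.0, 49.0, 707.0, 49.0) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # (805-800)/sqrt((100+300)/2) = 5/sqrt(200)
        assert dprime(800.0, 100.0, 805.0, 300.0) == pytest.approx(
            0.35355339, abs=1e-8
        )

    def test_zero_variances_rejected(self):
        with pytest.raises(ValueError):
            dprime(1.0, 0.0, 2.0, 0.0)

    @given(
        st.floats(500, 900), st.floats(1, 100),
        st.floats(500, 900), st.floats(1, 100),
        st.floats(0.1, 10),
    )
    def test_antisymmetry_and_scale_invariance(self, m1, v1, m2, v2, c):
        d = dprime(m1, v1, m2, v2)
        assert dprime(m2, v2, m1, v1) == pytest.approx(-d, rel=1e-12)
        # rescaling all pitches by c rescales means by c and variances by c^2
        assert dprime(c * m1, c * c * v1, c * m2, c * c * v2) == pytest.approx(
            d, rel=1e-9
        )


class TestDailySummaries:
    def test_constant_day(self):
        table = pd.DataFrame(
            {
                "bird_id": "b", "day": 1, "rendition": [1, 2, 3],
                "pitch_hz": [100.0, 100.0, 100.0], "stimulus": False,
            }
        )
        s = daily_summaries(table).iloc[0]
        assert s["mean"] == 100 and s["variance"] == 0 and s["cv"] == 0

    def test_sample_variance_and_cv(self):
        table = pd.DataFrame(
            {
                "bird_id": "b", "day": 1, "rendition": [1, 2],
                "pitch_hz": [99.0, 101.0], "stimulus": [True, False],
            }
        )
        s = daily_summaries(table).iloc[0]
        assert s["variance"] == pytest.approx(2.0)  # n-1 denominator
        assert s["cv"] == pytest.approx(100 * math.sqrt(2) / 100, abs=1e-6)
        assert s["contingency"] == pytest.approx(0.5)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            daily_summaries(pd.DataFrame(columns=["bird_id", "day", "pitch_hz"]))


class TestThresholdController:
    def test_median_odd_and_even(self):
        c = ThresholdController("high")
        assert update_threshold(c, [1.0, 2.0, 3.0]) == 2.0
        assert update_threshold(c, [1.0, 2.0, 3.0, 4.0]) == 2.5

    def test_crash_day_carries_threshold_forward(self):
        c = ThresholdController("high")
        c.update([5.0, 6.0, 7.0])
        assert c.update([]) == 6.0  # recording crash: reuse yesterday's value
        c2 = ThresholdController("high", carry_forward=False)
        with pytest.raises(ValueError):
            c2.update(None)

    def test_boundary_equality_never_triggers(self):
        c = ThresholdController("high", current_threshold=100.0)
        flags = c.assign(np.array([99.0, 100.0, 101.0]))
        assert flags.tolist() == [False, False, True]
        c_low = ThresholdController("low", current_threshold=100.0)
        assert c_low.assign(np.array([99.0, 100.0, 101.0])).tolist() == [
            True, False, False,
        ]

    def test_median_split_fixed_point_contingency(self, rng):
        """If consecutive days share a distribution, the median threshold
        splits it and expected contingency is 1/2."""
        c = ThresholdController("high")
        hits = total = 0
        for _ in range(200):
            yesterday = rng.normal(700, 7, size=300)
            today = rng.normal(700, 7, size=300)
            c.update(yesterday)
            flags = c.assign(today)
            hits += flags.sum()
            total += flags.size
        assert hits / total == pytest.approx(0.5, abs=0.01)

    def test_random_side_is_fair_coin(self, rng):
        c = ThresholdController("random")
        flags = c.assign(np.full(20000, 700.0), rng)
        assert flags.mean() == pytest.approx(0.5, abs=0.02)


class TestAverageDailyChange:
    def test_constant_pitch_gives_zero(self):
        s = make_summaries([700.0] * 6, [49.0] * 6)
        assert average_daily_change(s, days=[3, 4, 5, 6]) == 0.0

    def test_constant_increments(self):
        # 0.2 d'/day: each day's mean rises by 0.2 sigma at constant variance
        sd = 7.0
        means = 700.0 + 0.2 * sd * np.arange(6)
        s = make_summaries(means, [sd**2] * 6)
        assert average_daily_change(s, days=[2, 3, 4, 5, 6]) == pytest.approx(0.2)

    def test_window_without_predecessor_rejected(self):
        s = make_summaries([700.0] * 3, [49.0] * 3)
        with pytest.raises(ValueError):
            average_daily_change(s, days=[1])  # day 0 never summarized


class TestDirectionAndMagnitude:
    def test_upward_shift_is_positive_direction(self):
        means = [700.0] * 5 + list(700 + 3.0 * np.arange(1, 6))
        s = make_summaries(means, [49.0] * 10)
        delta, mag = direction_and_magnitude(s, baseline_last_day=5, stimulus_last_day=10)
        assert delta == 1 and mag > 0

    def test_mirrored_series_flips_direction_keeps_magnitude(self):
        up = [700.0] * 5 + list(700 + 3.0 * np.arange(1, 6))
        down = [700.0] * 5 + list(700 - 3.0 * np.arange(1, 6))
        s_up = make_summaries(up, [49.0] * 10)
        s_down = make_summaries(down, [49.0] * 10)
        d_up, m_up = direction_and_magnitude(s_up, 5, 10)
        d_down, m_down = direction_and_magnitude(s_down, 5, 10)
        assert d_up == -d_down == 1
        assert m_up == pytest.approx(m_down)

    def test_zero_overall_shift_defaults_positive(self, caplog):
        s = make_summaries([700.0] * 8, [49.0] * 8)
        with caplog.at_level("WARNING"):
            delta, _ = direction_and_magnitude(s, 5, 8)
        assert delta == 1


class TestParadigmCriteria:
    def test_flat_baseline_starts(self):
        s = make_summaries([700.0] * 5, [49.0] * 5)
        assert paradigm_criteria(s, "baseline") == "start_ok"

    def test_boundary_half_dprime_continues(self):
        # |d'| exactly 0.5 fails the strict start criterion
        sd = 8.0
        means = [700.0, 700.0, 700.0, 700.0, 700.0 + 0.5 * sd]
        s = make_summaries(means, [sd**2] * 5)
        assert paradigm_criteria(s, "baseline") == "continue"

    def test_cumulative_three_dprime_ends_with_shift(self):
        sd = 7.0
        means = [700.0] * 5 + list(700 + 0.6 * sd * np.arange(1, 6))
        s = make_summaries(means, [sd**2] * 10)
        assert paradigm_criteria(s, "stimulus", baseline_end=5) == "end_shift"

    def test_stable_stimulus_phase_ends_stable(self):
        s = make_summaries([700.0] * 10, [49.0] * 10)
        assert paradigm_criteria(s, "stimulus", baseline_end=5) == "end_stable"

    def test_too_few_days_rejected(self):
        s = make_summaries([700.0] * 4, [49.0] * 4)
        with pytest.raises(ValueError):
            paradigm_criteria(s, "baseline")


class TestPitchTraceDprime:
    def test_identical_sets_give_zero_curve(self, rng):
        traces = rng.normal(700, 7, size=(40, 60))
        curve = pitch_trace_dprime(traces, traces.copy())
        assert np.allclose(curve, 0.0)

    def test_shift_localized_to_band(self, rng):
        a = rng.normal(700, 7, size=(200, 80))
        b = rng.normal(700, 7, size=(200, 80))
        b[:, 30:46] += 21.0  # 3-sigma shift inside a 16-ms band
        curve = pitch_trace_dprime(a, b)
        assert curve[30:46].min() > 1.5
        outside = np.r_[curve[:25], curve[51:]]
        assert np.abs(outside).max() < 0.5

    def test_global_unit_shift_gives_flat_unit_curve(self, rng):
        a = rng.normal(700, 7, size=(400, 50))
        b = a + 7.0
        curve = pitch_trace_dprime(a, b)
        # sample-variance noise in the denominator: ~4 sigma at n = 400
        assert np.allclose(curve, 1.0, atol=0.15)
        assert np.allclose(pitch_trace_dprime(a, b, flip=True), -1.0, atol=0.15)

    def test_time_shuffled_traces_are_flat(self, rng):
        a = rng.normal(700, 7, size=(150, 60))
        b = rng.normal(700, 7, size=(150, 60))
        b[:, 20:36] += 10.0
        shuffled = b.copy()
        for row in shuffled:
            rng.shuffle(row)
        curve = pitch_trace_dprime(a, shuffled)
        # permutation bound: max |d'| of pure-noise curves at this n
        null_max = max(
            np.abs(
                pitch_trace_dprime(
                    rng.normal(700, 7, size=(150, 60)),
                    rng.normal(700, 7, size=(150, 60)),
                )
            ).max()
            for _ in range(20)
        )
        assert np.abs(curve - curve.mean()).max() < 2 * null_max

    def test_misaligned_grids_rejected(self, rng):
        with pytest.raises(ValueError):
            pitch_trace_dprime(rng.normal(size=(5, 10)), rng.normal(size=(5, 12)))


class TestBinomialDirection:
    def test_all_same_direction(self):
        assert binomial_direction_prob(10, 10, "greater") == pytest.approx(
            1 / 1024, abs=1e-12
        )

    def test_most_balanced_two_sided_is_one(self):
        assert binomial_direction_prob(5, 10, "two-sided") == pytest.approx(1.0)

    def test_tail_conventions_against_exhaustive_enumeration(self):
        """Brute force over all 2^10 outcome sequences."""
        n, k = 10, 9
        outcomes = list(itertools.product([0, 1], repeat=n))
        n_up = np.array([sum(o) for o in outcomes])
        p_ge = np.mean(n_up >= k)
        p_le = np.mean(n_up <= k)
        p_two = np.mean((n_up >= k) | (n_up <= n - k))
        assert binomial_direction_prob(k, n, "greater") == pytest.approx(p_ge, abs=1e-12)
        assert binomial_direction_prob(k, n, "less") == pytest.approx(p_le, abs=1e-12)
        assert binomial_direction_prob(k, n, "two-sided") == pytest.approx(p_two, abs=1e-12)
        # neither standard tail reaches 1%: the conventions matter
        assert p_ge == pytest.approx(11 / 1024)
        assert p_two == pytest.approx(22 / 1024)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            binomial_direction_prob(11, 10)


def test_daily_changes_are_consecutive_day_dprimes(small_cohort):
    summaries = daily_summaries(small_cohort)
    changes = daily_changes(summaries)
    one = changes.iloc[0]
    s = summaries[summaries["bird_id"] == one["bird_id"]].set_index("day")
    expected = dprime(
        s.loc[one["prev_day"], "mean"], s.loc[one["prev_day"], "variance"],
        s.loc[one["day"], "mean"], s.loc[one["day"], "variance"],
    )
    assert one["dprime"] == pytest.approx(expected)
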