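import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from songeval import spikes as sk


def _segments(onsets, offsets):
    return pd.DataFrame(
        {
            "syllable_id": [f"s{i}" for i in range(len(onsets))],
            "onset_s": onsets,
            "offset_s": offsets,
        }
    )


class TestEpisodes:
    def test_gap_threshold_splits_runs(self):
        # gaps of 100, 350, 200 ms between four syllables -> two episodes
        on = [0.0, 0.2, 0.65, 0.95]
        off = [0.1, 0.3, 0.75, 1.05]
        eps = sk.segment_episodes(_segments(on, off))
        assert len(eps) == 2
        assert [len(e.syllable_ids) for e in eps] == [2, 2]

    def test_single_syllable_is_one_episode(self):
        eps = sk.segment_episodes(_segments([1.0], [1.2]))
        assert len(eps) == 1
        assert eps[0].onset == 1.0 and eps[0].offset == 1.2

    def test_gap_of_exactly_300ms_splits(self):
        eps = sk.segment_episodes(_segments([0.0, 0.4], [0.1, 0.5]))
        assert len(eps) == 2

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            sk.segment_episodes(_segments([0.0, 0.05], [0.1, 0.2]))


class TestBaselines:
    def test_guard_trims_flanked_silence(self):
        ann = pd.DataFrame({"onset_s": [0.0, 20.0], "offset_s": [10.0, 25.0]})
        b = sk.find_baselines(ann, (0.0, 25.0))
        assert len(b) == 1
        assert b[0].onset == pytest.approx(12.0)
        assert b[0].offset == pytest.approx(18.0)

    def test_short_silence_yields_no_baseline(self):
        ann = pd.DataFrame({"onset_s": [0.0, 13.9], "offset_s": [10.0, 20.0]})
        assert sk.find_baselines(ann, (0.0, 20.0)) == []

    def test_fully_silent_record_spans_guards(self):
        b = sk.find_baselines(pd.DataFrame(columns=["onset_s", "offset_s"]),
                              (0.0, 30.0))
        assert len(b) == 1
        assert (b[0].onset, b[0].offset) == (2.0, 28.0)


class TestResponseStrength:
    def test_equal_rates_give_zero(self):
        assert sk.response_strength([5.0, 7.0, 9.0], [5.0, 7.0, 9.0]) == 0.0

    def test_worked_example_matches_paired_t(self):
        rs = sk.response_strength([10.0, 12.0, 14.0], [8.0, 9.0, 10.0])
        assert rs == pytest.approx(3.0 / np.sqrt(1.0 / 3.0))
        assert rs == pytest.approx(5.196, abs=1e-3)

    def test_antisymmetric_under_swap(self):
        s = np.array([4.0, 9.0, 6.0, 8.0])
        b = np.array([2.0, 3.0, 5.0, 1.0])
        assert sk.response_strength(s, b) == pytest.approx(
            -sk.response_strength(b, s)
        )

    def test_matches_scipy_paired_t_on_fuzz(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(3, 30))
            s = rng.gamma(2.0, 3.0, n)
            b = rng.gamma(2.0, 3.0, n)
            if np.var(s - b) == 0:
                continue
            assert sk.response_strength(s, b) == pytest.approx(
                stats.ttest_rel(s, b).statistic
            )

    def test_constant_offset_has_undefined_strength(self):
        assert np.isnan(sk.response_strength([3.0, 4.0], [1.0, 2.0]))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            sk.response_strength([1.0], [2.0])


class TestResponsiveness:
    def test_clear_excitation_flagged(self):
        rng = np.random.default_rng(1)
        s = rng.normal(10.0, 1.0, 20)
        b = rng.normal(2.0, 1.0, 20)
        stat, p, flag = sk.responsiveness_test(s, b)
        assert flag == "excited" and p < 1e-6

    def test_single_value_groups_rejected(self):
        with pytest.raises(ValueError):
            sk.responsiveness_test([5.0], [1.0, 2.0])


class TestBurstFraction:
    @pytest.mark.parametrize(
        "isis_ms, expected",
        [((5, 5, 90), 2 / 3), ((5, 5, 5), 1.0), ((50, 50, 50), 0.0)],
    )
    def test_isi_counting(self, isis_ms, expected):
        t = np.concatenate([[0.0], np.cumsum(np.asarray(isis_ms) / 1000.0)])
        assert sk.burst_fraction(t + 1.0, [(0.0, 10.0)]) == pytest.approx(expected)

    def test_isis_do_not_cross_interval_boundaries(self):
        spikes = np.array([0.1, 0.105, 5.0, 5.005])
        frac = sk.burst_fraction(spikes, [(0.0, 1.0), (4.9, 5.1)])
        assert frac == 1.0  # the 4.9 s gap between intervals is not an ISI

    def test_too_few_spikes_undefined(self):
        assert np.isnan(sk.burst_fraction(np.array([1.0]), [(0.0, 2.0)]))


class TestRates:
    def test_syllable_rate_includes_premotor_window(self):
        spikes = np.array([0.96, 1.02, 1.08])
        # 3 spikes in a 100 ms syllable + 50 ms premotor window
        assert sk.syllable_rate(spikes, 1.0, 1.1) == pytest.approx(20.0)

    def test_no_spikes_zero_rate(self):
        assert sk.syllable_rate(np.array([]), 1.0, 1.1) == 0.0

    def test_left_edge_closed(self):
        spikes = np.array([0.95])
        assert sk.syllable_rate(spikes, 1.0, 1.1) == pytest.approx(1.0 / 0.15)

    @pytest.mark.parametrize(
        "rate, baseline, expected", [(20.0, 5.0, 15.0), (5.0, 5.0, 0.0), (1.0, 6.0, -5.0)]
    )
    def test_baseline_correction(self, rate, baseline, expected):
        assert sk.baseline_corrected_rate(rate, baseline) == expected


class TestTimeWarp:
    def test_midpoint_scales_linearly(self):
        w = sk.linear_time_warp(np.array([0.05]), 0.0, 0.1, 0.2)
        assert w[0] == pytest.approx(0.1)

    def test_identity_when_durations_match(self):
        t = np.array([0.01, 0.07])
        assert np.allclose(sk.linear_time_warp(t, 0.0, 0.1, 0.1), t)

    def test_onset_spike_stays_at_onset(self):
        assert sk.linear_time_warp(np.array([2.0]), 2.0, 0.1, 0.3)[0] == 2.0


class TestActivityFraction:
    def test_uniform_rates_no_selectivity(self):
        assert sk.activity_fraction(np.full(5, 3.0)) == pytest.approx(0.0)

    def test_one_hot_rates_maximal_selectivity(self):
        assert sk.activity_fraction(np.array([0.0, 0.0, 4.0])) == pytest.approx(1.0)

    def test_worked_example(self):
        assert sk.activity_fraction(np.array([2.0, 1.0, 1.0, 0.0])) == pytest.approx(4 / 9)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(0.0, 100.0), min_size=2, max_size=12).filter(
            lambda r: max(r) > 1e-3
        )
    )
    def test_bounded_between_zero_and_one(self, rates):
        af = sk.activity_fraction(np.asarray(rates))
        assert -1e-9 <= af <= 1.0 + 1e-9

    def test_all_zero_rates_undefined(self):
        assert np.isnan(sk.activity_fraction(np.zeros(4)))


class TestCV:
    def test_constant_rates_zero(self):
        assert sk.cv_firing(np.full(6, 4.0)) == 0.0

    def test_sample_sd_convention(self):
        assert sk.cv_firing(np.array([5.0, 10.0, 15.0])) == pytest.approx(0.5)

    def test_zero_mean_excluded(self):
        assert np.isnan(sk.cv_firing(np.zeros(5)))
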