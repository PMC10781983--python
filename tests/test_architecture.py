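"""Bout detection, state proportions, transitions, latencies, curves."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somnoscope import (
    Hypnogram,
    bout_distribution_curve,
    detect_bouts,
    effective_labels,
    group_distribution_curves,
    state_proportions,
    state_time_course,
    transition_proportions,
    wake_latency_profile,
)
from .conftest import brute_force_effective_labels


def hyp(s: str) -> Hypnogram:
    return Hypnogram(np.array(list(s)))


class TestDetectBouts:
    def test_three_epochs_is_one_bout(self):
        bouts = detect_bouts(hyp("NNN"))
        assert len(bouts) == 1
        assert bouts[0].state == "N" and bouts[0].duration == 12.0

    def test_all_wake_single_bout(self):
        bouts = detect_bouts(hyp("W" * 50))
        assert len(bouts) == 1
        assert bouts[0].state == "W" and bouts[0].duration == 200.0

    def test_short_intrusion_absorbed(self):
        bouts = detect_bouts(hyp("NNNWWNNN"))
        assert len(bouts) == 1
        assert bouts[0].state == "N" and bouts[0].duration == 32.0

    def test_sustained_change_opens_bout(self):
        bouts = detect_bouts(hyp("NNNWWWNNN"))
        assert [b.state for b in bouts] == ["N", "W", "N"]
        assert [b.duration for b in bouts] == [12.0, 12.0, 12.0]

    def test_first_bout_opens_unconditionally(self):
        bouts = detect_bouts(hyp("WNNNN"))  # single leading W epoch
        assert bouts[0].state == "W" and bouts[0].start == 0.0

    def test_partition_conserves_duration(self):
        rng = np.random.default_rng(0)
        labels = rng.choice(list("WNR"), size=500)
        h = Hypnogram(labels)
        bouts = detect_bouts(h)
        assert sum(b.duration for b in bouts) == h.duration_s
        for a, b in zip(bouts[:-1], bouts[1:]):
            assert a.end == b.start and a.state != b.state

    @given(st.lists(st.sampled_from("WNR"), min_size=1, max_size=100))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_oracle(self, labels):
        h = Hypnogram(np.array(labels))
        assert (effective_labels(h) == brute_force_effective_labels(labels)).all()


class TestStateProportions:
    def test_single_full_phase_bout(self):
        props = state_proportions(detect_bouts(hyp("W" * 10)))
        assert props == {"W": 1.0, "N": 0.0, "R": 0.0}

    def test_six_hours_nrems_in_light_phase(self):
        labels = "N" * 5400 + "W" * 5400  # 6 h NREMS + 6 h WAKE
        props = state_proportions(detect_bouts(hyp(labels)), phase_duration_s=12 * 3600)
        assert props["N"] == pytest.approx(0.5)

    def test_matches_epoch_count_oracle(self):
        rng = np.random.default_rng(1)
        h = Hypnogram(rng.choice(list("WNR"), size=800))
        props = state_proportions(detect_bouts(h))
        eff = effective_labels(h)
        for state in "WNR":
            assert props[state] == pytest.approx(np.mean(eff == state))

    def test_empty_bouts_rejected(self):
        with pytest.raises(ValueError):
            state_proportions([])


class TestTransitions:
    def test_direct_enumeration_example(self):
        # bout states W,N,R,W,N -> W->N twice of four transitions
        h = hyp("WWWNNNRRRWWWNNN")
        tc = transition_proportions(detect_bouts(h))
        props = tc.proportions
        assert props[("W", "N")] == pytest.approx(0.5)
        assert props[("N", "R")] == pytest.approx(0.25)
        assert props[("R", "W")] == pytest.approx(0.25)

    def test_alternating_symmetry(self):
        h = hyp("WWWNNN" * 4)
        props = transition_proportions(detect_bouts(h)).proportions
        assert props[("W", "N")] == pytest.approx(4 / 7)
        assert props[("N", "W")] == pytest.approx(3 / 7)

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(2)
        h = Hypnogram(rng.choice(list("WNR"), size=1000))
        tc = transition_proportions(detect_bouts(h))
        assert sum(tc.proportions.values()) == pytest.approx(1.0)

    def test_wake_to_rems_flagged_as_anomaly(self):
        # short N intrusion absorbed into W bout, then sustained R
        tc = transition_proportions(detect_bouts(hyp("WWWNRRR")))
        assert tc.anomaly_w_r == 1
        assert tc.total == 0


class TestLatencyProfile:
    def test_phase_starting_with_wake(self):
        lp = wake_latency_profile(detect_bouts(hyp("WWWNNN")))
        assert lp.latencies[0] == 0.0

    def test_direct_arithmetic_example(self):
        from somnoscope.architecture import Bout

        bouts = []
        for i in range(5):
            bouts.append(Bout("W", start=100.0 * i, duration=60.0))
            bouts.append(Bout("N", start=100.0 * i + 60.0, duration=40.0))
        lp = wake_latency_profile(bouts)
        assert lp.latencies == (0.0, 100.0, 200.0, 300.0, 400.0)
        assert lp.median_first5_bout_length == 60.0
        assert lp.combined_metric == 460.0
        assert lp.complete

    def test_latencies_nondecreasing(self):
        rng = np.random.default_rng(3)
        h = Hypnogram(rng.choice(list("WNR"), size=600))
        lp = wake_latency_profile(detect_bouts(h))
        assert all(a <= b for a, b in zip(lp.latencies, lp.latencies[1:]))

    def test_incomplete_profile_flagged(self):
        lp = wake_latency_profile(detect_bouts(hyp("WWWNNNWWW")))
        assert not lp.complete and len(lp.latencies) == 2


class TestDistributionCurves:
    def test_equal_bouts_constant_curve(self):
        _, y = bout_distribution_curve([30.0] * 5)
        np.testing.assert_allclose(y, 0.2)

    def test_raw_normalization_example(self):
        x, y = bout_distribution_curve([10.0, 30.0, 60.0], n_points=None)
        np.testing.assert_allclose(x, [1 / 3, 2 / 3, 1.0])
        np.testing.assert_allclose(y, [0.1, 0.3, 0.6])

    def test_curve_nondecreasing(self):
        rng = np.random.default_rng(4)
        _, y = bout_distribution_curve(rng.exponential(60, size=40))
        assert (np.diff(y) >= -1e-12).all()

    def test_single_bout_rejected(self):
        with pytest.raises(ValueError):
            bout_distribution_curve([10.0])

    def test_group_bands_order(self):
        rng = np.random.default_rng(5)
        curves = [bout_distribution_curve(rng.exponential(60, size=30))[1] for _ in range(6)]
        g = group_distribution_curves(curves)
        assert (g["q1"] <= g["median"] + 1e-12).all()
        assert (g["median"] <= g["q3"] + 1e-12).all()


class TestTimeCourse:
    def test_all_wake_every_bin_100(self):
        h = Hypnogram(np.array(["W"] * (4 * 1800)))  # 8 h
        df = state_time_course([h], n_boot=50, seed=0)
        wake = df[df.state == "W"]
        assert (wake.median_pct == 100.0).all()
        assert (df[df.state != "W"].median_pct == 0.0).all()

    def test_identical_mice_zero_ci_width(self):
        rng = np.random.default_rng(6)
        h = Hypnogram(rng.choice(list("WNR"), size=4 * 1800))
        df = state_time_course([h, h, h], n_boot=200, seed=0)
        np.testing.assert_allclose(df.ci_lo, df.median_pct)
        np.testing.assert_allclose(df.ci_hi, df.median_pct)

    def test_median_matches_direct_oracle(self):
        rng = np.random.default_rng(7)
        hyps = [Hypnogram(rng.choice(list("WNR"), size=4 * 1800)) for _ in range(5)]
        df = state_time_course(hyps, n_boot=10, seed=0)
        effs = [effective_labels(h) for h in hyps]
        row = df[(df.bin_index == 2) & (df.state == "N")].iloc[0]
        direct = np.median([100 * np.mean(e[3600:5400] == "N") for e in effs])
        assert row.median_pct == pytest.approx(direct)

    def test_23h_window_has_truncated_final_bin(self):
        h = Hypnogram(np.array(["W"] * (23 * 900)))
        df = state_time_course([h], n_boot=10, seed=0)
        assert df.bin_index.nunique() == 12
        last = df[df.bin_index == 11]
        assert last.truncated.all()
        assert (last.bin_end_h - last.bin_start_h).iloc[0] == pytest.approx(1.0)
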