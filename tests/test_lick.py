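"""Lick rate, circular-shift permutation test, bouts, and reward comparisons."""

import numpy as np
import pytest
from scipy.signal import fftconvolve

from axovis import synth
from axovis.lick import (bout_matched_comparison, detect_bouts, lick_rate,
                         lick_correlation_perm, rewarded_vs_unrewarded)
from axovis.session import FluorescenceSet
from conftest import make_trials


def dff_set(values, dt=0.1):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return FluorescenceSet(values=values,
                           frame_times=np.arange(values.shape[1]) * dt,
                           roi_pixels=np.full(values.shape[0], 5), kind="dff")


def test_lick_rate_empty_raster_is_zero():
    assert np.all(lick_rate(np.array([]), np.arange(0, 10, 0.1)) == 0)


def test_lick_rate_burst_peak_equals_count():
    licks = 5.0 + np.arange(6) * 0.05  # six licks within 0.3 s
    rate = lick_rate(licks, np.arange(0, 10, 0.1))
    assert rate.max() == 6


def test_lick_rate_matches_brute_force_interval_count():
    rng = np.random.default_rng(0)
    licks = np.sort(rng.uniform(0, 100, 400))
    frame_times = np.arange(0, 100, 0.1)
    rate = lick_rate(licks, frame_times)
    oracle = np.array([np.sum((licks >= t - 0.5) & (licks < t + 0.5))
                       for t in frame_times])
    np.testing.assert_array_equal(rate, oracle)


def _session_with_licks(duration=600.0, dt=0.1, seed=0):
    rng = np.random.default_rng(seed)
    bouts = np.sort(rng.uniform(5, duration - 5, 40))
    licks = np.sort(np.concatenate([b + np.arange(6) / 7.0 for b in bouts]))
    frame_times = np.arange(0, duration, dt)
    return licks, frame_times, rng


def test_lick_coupled_bouton_is_significant_and_highly_correlated():
    licks, frame_times, rng = _session_with_licks()
    rate = lick_rate(licks, frame_times)
    kernel = synth.double_exp_kernel(0.2, 1.5, 0.1)
    trace = fftconvolve(rate, kernel)[:rate.size]
    trace = trace + 0.1 * rng.standard_normal(rate.size)
    res = lick_correlation_perm(dff_set(trace), rate, n_perm=500, seed=1)
    assert res.significant[0]
    assert res.r_obs[0] > 0.2
    assert res.highly_correlated[0]


def test_every_shift_respects_minimum_distance():
    licks, frame_times, rng = _session_with_licks()
    rate = lick_rate(licks, frame_times)
    trace = rng.standard_normal(rate.size)
    res = lick_correlation_perm(dff_set(trace), rate, n_perm=1000,
                                min_shift_s=10.0, seed=2)
    min_shift = int(round(10.0 / 0.1))
    assert res.shifts.min() >= min_shift
    assert res.shifts.max() <= rate.size - min_shift
    assert np.all(res.p_perm >= 1 / 1001) and np.all(res.p_perm <= 1)


def test_zero_variance_trace_excluded():
    licks, frame_times, rng = _session_with_licks()
    rate = lick_rate(licks, frame_times)
    traces = np.vstack([np.zeros(rate.size), rng.standard_normal(rate.size)])
    res = lick_correlation_perm(dff_set(traces), rate, n_perm=100, seed=0)
    assert res.excluded == [0]
    assert not res.significant[0] and np.isnan(res.r_obs[0])


def bilateral_trials():
    rows = []
    for i, side in enumerate(["contra", "ipsi", "contra", "ipsi"]):
        t = 20.0 * i + 5.0
        rows.append({"tone_time": t, "trial_type": "go", "side": side,
                     "response": "lick", "correct": True,
                     "reward_time": t + 3.5})
    return make_trials(rows)


def set_windows(trials, unrew_value, rew_contra, rew_ipsi, dt=0.1):
    frame_times = np.arange(0, 90, dt)
    values = np.zeros((1, frame_times.size))
    for _, tr in trials.iterrows():
        u0 = np.searchsorted(frame_times, tr.stim_on)
        u1 = np.searchsorted(frame_times, tr.stim_on + 2.0)
        values[0, u0:u1] = unrew_value
        r0 = np.searchsorted(frame_times, tr.reward_time)
        r1 = np.searchsorted(frame_times, tr.stim_off)
        values[0, r0:r1] = rew_contra if tr.side == "contra" else rew_ipsi
    return FluorescenceSet(values=values, frame_times=frame_times,
                           roi_pixels=np.array([5]), kind="dff")


def trial_licks(trials):
    out = []
    for _, tr in trials.iterrows():
        out.append(tr.stim_on + 0.5)                       # impulsive lick
        out.extend(tr.reward_time + np.arange(4) / 7.0)    # rewarded bout
    return np.sort(np.array(out))


def test_identical_periods_give_zero_difference_and_zero_rti():
    trials = bilateral_trials()
    fset = set_windows(trials, 0.4, 0.4, 0.4)
    cmp_ = rewarded_vs_unrewarded(fset, trials, trial_licks(trials),
                                  scope="per_side")
    assert cmp_.dff_rewarded[0] == pytest.approx(cmp_.dff_unrewarded[0])
    assert cmp_.rti[0] == 0.0


def test_contra_only_reward_activity_gives_unit_rti():
    trials = bilateral_trials()
    fset = set_windows(trials, 0.0, rew_contra=0.5, rew_ipsi=0.0)
    cmp_ = rewarded_vs_unrewarded(fset, trials, trial_licks(trials),
                                  scope="per_side")
    assert cmp_.rti[0] == pytest.approx(1.0)


def test_rti_arithmetic_matches_reported_means():
    # per-side rewarded means 0.48 (contra) and 0.39 (ipsi)
    trials = bilateral_trials()
    fset = set_windows(trials, 0.2, rew_contra=0.48, rew_ipsi=0.39)
    cmp_ = rewarded_vs_unrewarded(fset, trials, trial_licks(trials),
                                  scope="per_side")
    assert cmp_.c_reward[0] == pytest.approx(0.48, abs=1e-6)
    assert cmp_.i_reward[0] == pytest.approx(0.39, abs=1e-6)
    assert cmp_.rti[0] == pytest.approx((0.48 - 0.39) / (0.48 + 0.39), abs=1e-6)


def test_unrewarded_periods_require_licks():
    trials = bilateral_trials()
    fset = set_windows(trials, 0.9, 0.5, 0.5)
    licks = trial_licks(trials)
    # remove impulsive licks -> no unrewarded licking periods at all
    licks = licks[~np.isin(licks, trials.stim_on.to_numpy() + 0.5)]
    with pytest.raises(ValueError, match="unrewarded"):
        rewarded_vs_unrewarded(fset, trials, licks)


def test_per_side_scope_requires_both_sides():
    trials = bilateral_trials()
    trials["side"] = "contra"
    fset = set_windows(trials, 0.2, 0.5, 0.5)
    with pytest.raises(ValueError, match="ipsi"):
        rewarded_vs_unrewarded(fset, trials, trial_licks(trials),
                               scope="per_side")


def test_bout_at_silence_boundary_detected():
    bouts = detect_bouts(np.array([5.0, 5.2, 5.4]))
    assert len(bouts) == 1 and bouts[0].start == 5.0
    assert not bouts[0].rewarded


def test_preceding_lick_blocks_bout():
    assert detect_bouts(np.array([4.5, 5.0, 5.2, 5.4])) == []


def test_slow_triple_is_not_a_bout():
    assert detect_bouts(np.array([5.0, 5.3, 5.6])) == []


def brute_force_bouts(licks):
    """Exhaustive scan: count licks in [t, t+0.5) after 1 s of silence."""
    licks = np.sort(licks)
    out = []
    for i, t in enumerate(licks):
        if np.any((licks >= t - 1.0) & (licks < t)):
            continue
        in_half_s = licks[(licks >= t) & (licks < t + 0.5)]
        if len(in_half_s) >= 3:
            out.append((t, tuple(in_half_s[:3])))
    return out


def test_bout_detector_matches_brute_force_on_fuzzed_rasters():
    rng = np.random.default_rng(3)
    for _ in range(300):
        n_sparse = rng.integers(0, 15)
        n_bursts = rng.integers(0, 5)
        licks = list(rng.uniform(0, 60, n_sparse))
        for _ in range(n_bursts):
            t0 = rng.uniform(0, 60)
            licks.extend(t0 + np.cumsum(rng.exponential(0.15, rng.integers(2, 8))))
        licks = np.unique(np.round(np.array(licks), 4))
        got = [(b.start, tuple(b.lick_times)) for b in detect_bouts(licks)]
        assert got == brute_force_bouts(licks)


def test_bout_matched_comparison_recovers_reward_gain():
    trials = bilateral_trials()
    licks = trial_licks(trials)
    # unrewarded (impulsive) bout windows sit in the first 2 s of the
    # stimulus at activity 1.0; rewarded bout windows at 2.0
    extra = []
    for _, tr in trials.iterrows():
        extra.extend(tr.stim_on + 0.5 + np.arange(3) * 0.2)
    licks = np.sort(np.unique(np.concatenate([licks, extra])))
    fset = set_windows(trials, unrew_value=1.0, rew_contra=2.0, rew_ipsi=2.0)
    bouts = detect_bouts(licks, trials)
    assert any(b.rewarded for b in bouts) and any(not b.rewarded for b in bouts)
    cmp_ = bout_matched_comparison(fset, bouts)
    assert cmp_.dff_rewarded[0] == pytest.approx(2.0 * cmp_.dff_unrewarded[0])


def test_bout_matched_single_bout_per_class_flagged():
    licks = np.array([5.0, 5.1, 5.2, 20.0, 20.1, 20.2])
    trials = make_trials([{"tone_time": 16.0, "trial_type": "go",
                           "response": "lick", "correct": True,
                           "reward_time": 19.5}])
    fset = dff_set(np.ones(300))
    bouts = detect_bouts(licks, trials)
    cmp_ = bout_matched_comparison(fset, bouts)
    assert cmp_.degenerate


def test_bout_matched_requires_both_classes():
    licks = np.array([5.0, 5.1, 5.2])
    fset = dff_set(np.ones(300))
    with pytest.raises(ValueError, match="rewarded"):
        bout_matched_comparison(fset, detect_bouts(licks))
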