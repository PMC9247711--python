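"""d' computation, sliding windows, and the correctness linear model."""

from statistics import NormalDist

import numpy as np
import pytest

from axovis import synth
from axovis.accuracy import (DPrimeSeries, compute_dprime, correctness_model,
                             dprime_activity_regression, sliding_dprime)
from conftest import make_trials

norminv = NormalDist().inv_cdf  # stdlib oracle, independent of scipy


def test_equal_rates_give_zero():
    for r in (0.2, 0.5, 0.9):
        assert compute_dprime(r, r, correction="none") == pytest.approx(0.0)


def test_phi_of_one_closed_form():
    assert compute_dprime(0.8413, 0.5, correction="none") == pytest.approx(1.0, abs=0.01)


def test_half_count_correction_matches_arithmetic():
    got = compute_dprime(1.0, 0.2, n_go=100, n_nogo=50)
    expected = norminv(1 - 1 / 200) - norminv(0.2)
    assert got == pytest.approx(expected, abs=1e-12)


def test_loglinear_correction_matches_arithmetic():
    got = compute_dprime(0.9, 0.0, correction="loglinear", n_go=40, n_nogo=40)
    expected = norminv((0.9 * 40 + 0.5) / 41) - norminv(0.5 / 41)
    assert got == pytest.approx(expected, abs=1e-12)


def test_uncorrected_perfect_rate_warns_and_is_infinite():
    with pytest.warns(UserWarning):
        assert np.isinf(compute_dprime(1.0, 0.2, correction="none"))


def test_dprime_monotone_in_both_rates():
    rates = np.linspace(0.02, 0.98, 50)
    grid = compute_dprime(rates[None, :], rates[:, None], correction="none")
    assert np.all(np.diff(grid, axis=1) > 0)   # increasing in hit rate
    assert np.all(np.diff(grid, axis=0) < 0)   # decreasing in fa rate


def alternating_trials(n, lick_go=True, lick_nogo=False):
    rows = []
    for i in range(n):
        go = i % 2 == 0
        lick = lick_go if go else lick_nogo
        rows.append({"tone_time": 12.0 * i + 5.0,
                     "trial_type": "go" if go else "nogo",
                     "response": "lick" if lick else "no_lick",
                     "correct": lick if go else not lick,
                     "reward_time": 12.0 * i + 8.5 if (go and lick) else np.nan,
                     "airpuff_time": 12.0 * i + 8.5 if (not go and lick) else np.nan})
    return make_trials(rows)


def test_perfect_alternating_agent_hits_corrected_maximum():
    trials = alternating_trials(60)
    series = sliding_dprime(trials, window=20)
    expected = norminv(1 - 1 / 20) - norminv(1 / 20)
    np.testing.assert_allclose(series.dprime, expected, atol=1e-12)


def test_lick_everything_agent_has_zero_dprime():
    trials = alternating_trials(60, lick_go=True, lick_nogo=True)
    series = sliding_dprime(trials, window=20)
    np.testing.assert_allclose(series.dprime, 0.0, atol=1e-12)


def test_sliding_windows_match_brute_force():
    rng = np.random.default_rng(0)
    rows = []
    for i in range(80):
        go = rng.random() < 0.5
        lick = rng.random() < (0.8 if go else 0.3)
        rows.append({"tone_time": 12.0 * i + 5.0,
                     "trial_type": "go" if go else "nogo",
                     "response": "lick" if lick else "no_lick",
                     "correct": lick if go else not lick,
                     "reward_time": 12.0 * i + 8.5 if (go and lick) else np.nan,
                     "airpuff_time": 12.0 * i + 8.5 if (not go and lick) else np.nan})
    trials = make_trials(rows)
    series = sliding_dprime(trials, window=20)
    for start, h, f, d in zip(series.starts, series.hit_rate, series.fa_rate,
                              series.dprime):
        sub = trials.iloc[start:start + 20]
        go = sub[sub.trial_type == "go"]
        nogo = sub[sub.trial_type == "nogo"]
        h0 = (go.response == "lick").mean()
        f0 = (nogo.response == "lick").mean()
        assert h == pytest.approx(h0) and f == pytest.approx(f0)
        h0c = min(max(h0, 1 / (2 * len(go))), 1 - 1 / (2 * len(go)))
        f0c = min(max(f0, 1 / (2 * len(nogo))), 1 - 1 / (2 * len(nogo)))
        assert d == pytest.approx(norminv(h0c) - norminv(f0c), abs=1e-12)


def test_all_go_session_yields_empty_series_with_warning():
    trials = make_trials([{"tone_time": 12.0 * i + 5.0, "trial_type": "go",
                           "response": "lick", "correct": True,
                           "reward_time": 12.0 * i + 8.5} for i in range(30)])
    with pytest.warns(UserWarning):
        series = sliding_dprime(trials, window=20)
    assert series.dprime.size == 0


def test_sliding_dprime_tracks_latent_accuracy_drift():
    session, gt = synth.simulate_session(
        synth.TaskConfig(n_trials=300),
        synth.AgentParams(accuracy_drift_sd=0.04), [synth.BoutonSpec()],
        seed=21)
    series = sliding_dprime(session.trials, window=20)
    latent = np.array([norminv(gt.trial_hit_rate[c]) - norminv(gt.trial_fa_rate[c])
                       for c in series.centers])
    r = np.corrcoef(series.dprime, latent)[0, 1]
    assert r > 0.5


def test_correctness_model_exact_effect_and_cmi():
    trials = alternating_trials(40)
    # half the trials of each type correct, so correctness and trial type
    # are orthogonal predictors
    trials["correct"] = [True, True, False, False] * 10
    activity = np.where(trials.correct.to_numpy(), 1.0, 0.5)[None, :]
    fit = correctness_model(activity, trials)
    assert fit.coefficients[0, 1] == pytest.approx(0.5, abs=1e-10)
    assert fit.coefficients[0, 2] == pytest.approx(0.0, abs=1e-10)
    assert fit.cmi[0] == pytest.approx(1.0 / 3.0)


def test_correctness_model_null_calibration():
    rng = np.random.default_rng(5)
    n_trials = 120
    trials = alternating_trials(n_trials)
    trials["correct"] = rng.random(n_trials) < 0.7
    activity = rng.normal(0, 1, size=(800, n_trials))
    fit = correctness_model(activity, trials)
    frac = (fit.p_values[:, 1] < 0.05).mean()
    assert abs(frac - 0.05) < 2.576 * np.sqrt(0.05 * 0.95 / 800)


def test_correctness_effect_recovery_is_unbiased():
    rng = np.random.default_rng(6)
    n_trials, n_b, effect = 200, 200, 0.5
    trials = alternating_trials(n_trials)
    trials["correct"] = rng.random(n_trials) < 0.7
    c = trials["correct"].to_numpy(float)
    activity = effect * c[None, :] + rng.normal(0, 0.3, size=(n_b, n_trials))
    fit = correctness_model(activity, trials)
    bias = fit.coefficients[:, 1].mean() - effect
    assert abs(bias) < 0.05 * effect


def test_single_correctness_level_rejected():
    trials = alternating_trials(20)
    trials["correct"] = True
    with pytest.raises(ValueError, match="correctness levels"):
        correctness_model(np.zeros((1, 20)), trials)


def test_collinear_design_skips_all_boutons():
    trials = alternating_trials(20)
    trials["correct"] = trials.trial_type == "go"  # correct == trial type
    fit = correctness_model(np.random.default_rng(0).normal(size=(3, 20)), trials)
    assert len(fit.skipped) == 3
    assert np.all(np.isnan(fit.coefficients))


def test_previous_correct_predictor_shifts_by_one():
    trials = alternating_trials(30)
    rng = np.random.default_rng(7)
    trials["correct"] = rng.random(30) < 0.5
    prev = trials["correct"].to_numpy(float)[:-1]
    activity = np.zeros((1, 30))
    activity[0, 1:] = 2.0 * prev  # driven purely by previous correctness
    fit = correctness_model(activity, trials, predictor="previous_correct")
    assert fit.coefficients[0, 1] == pytest.approx(2.0, abs=1e-10)


def _series(dprime):
    n = len(dprime)
    return DPrimeSeries(window=20, centers=np.arange(n), starts=np.arange(n),
                        hit_rate=np.full(n, 0.8), fa_rate=np.full(n, 0.2),
                        dprime=np.asarray(dprime, float))


def test_exact_linear_relation_recovers_slope():
    x = np.linspace(0.1, 0.5, 30)
    sessions = [(_series(3.0 * x + 1.0), x), (_series(3.0 * x - 0.5), x)]
    reg = dprime_activity_regression(sessions)
    np.testing.assert_allclose(reg.slopes, 3.0, atol=1e-10)


def test_opposite_slopes_cancel_in_group_test():
    x = np.linspace(0.1, 0.5, 30)
    sessions = [(_series(x), x), (_series(-x), x)]
    reg = dprime_activity_regression(sessions)
    assert reg.slopes.mean() == pytest.approx(0.0, abs=1e-12)
    assert reg.p_value == pytest.approx(1.0)


def test_constant_population_activity_excluded():
    x = np.linspace(0.1, 0.5, 30)
    sessions = [(_series(x), x), (_series(x), x),
                (_series(x), np.full(30, 0.2))]
    reg = dprime_activity_regression(sessions)
    assert reg.excluded == [(2, "constant population activity")]
    assert reg.slopes.size == 2


def test_group_test_calibrated_under_null():
    rng = np.random.default_rng(8)
    rejections = 0
    n_rep = 300
    for _ in range(n_rep):
        sessions = []
        for _ in range(5):
            pop = rng.normal(0.3, 0.05, 25)
            dp = rng.normal(1.5, 0.3, 25)  # independent of activity
            sessions.append((_series(dp), pop))
        if dprime_activity_regression(sessions).p_value < 0.05:
            rejections += 1
    frac = rejections / n_rep
    assert abs(frac - 0.05) < 2.576 * np.sqrt(0.05 * 0.95 / n_rep) + 0.01
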