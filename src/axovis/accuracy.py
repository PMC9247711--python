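"""Behavioral accuracy and its association with bouton activity.

d' is the signal-detection discriminability norminv(hit rate) -
norminv(false-alarm rate).  Perfect rates (0 or 1) make the quantile infinite,
so an edge-correction policy is applied first: the default replaces 0 with
1/(2n) and 1 with 1 - 1/(2n); a log-linear alternative ((k + 0.5) / (n + 1))
is also available.  A sliding 20-trial window gives a within-session d'
series.  The per-bouton correctness model is an OLS fit of per-trial activity
on trial correctness, trial type and their interaction (treatment coding),
with BH correction across boutons, plus the correct-modulation index
CMI = (R_correct - R_incorrect) / (R_correct + R_incorrect).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

COEF_NAMES = ("intercept", "correct", "trial_type", "interaction")


def _correct_rate(rate: np.ndarray, n: np.ndarray, correction: str) -> np.ndarray:
    rate = np.asarray(rate, dtype=float)
    if correction == "none":
        if np.any((rate == 0) | (rate == 1)):
            warnings.warn("rate at 0 or 1 with correction='none': d' is infinite")
        return rate
    if n is None:
        raise ValueError(f"correction={correction!r} needs trial counts")
    n = np.asarray(n, dtype=float)
    if correction == "half_count":
        return np.clip(rate, 1.0 / (2 * n), 1.0 - 1.0 / (2 * n))
    if correction == "loglinear":
        return (rate * n + 0.5) / (n + 1.0)
    raise ValueError(f"unknown correction policy {correction!r}")


def compute_dprime(hit_rate, fa_rate, correction: str = "half_count",
                   n_go=None, n_nogo=None):
    """d' = norminv(hit rate) - norminv(false-alarm rate), edge-corrected."""
    for r, name in ((hit_rate, "hit_rate"), (fa_rate, "fa_rate")):
        if np.any((np.asarray(r) < 0) | (np.asarray(r) > 1)):
            raise ValueError(f"{name} must be in [0, 1]")
    h = _correct_rate(hit_rate, n_go, correction)
    f = _correct_rate(fa_rate, n_nogo, correction)
    return stats.norm.ppf(h) - stats.norm.ppf(f)


@dataclass
class DPrimeSeries:
    """Sliding-window hit/false-alarm rates and d' along the session."""

    window: int
    centers: np.ndarray     # trial index at window center
    starts: np.ndarray      # first trial index of each window
    hit_rate: np.ndarray
    fa_rate: np.ndarray
    dprime: np.ndarray


def sliding_dprime(trials: pd.DataFrame, window: int = 20,
                   correction: str = "half_count") -> DPrimeSeries:
    """d' over a window of ``window`` consecutive trials, stepped by one.

    Windows lacking either trial type are dropped; an all-go (or all-nogo)
    session therefore yields an empty series, with a warning.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    is_go = (trials["trial_type"] == "go").to_numpy()
    licked = (trials["response"] == "lick").to_numpy()
    n = len(trials)
    if n < window:
        raise ValueError("fewer trials than the window length")
    starts, centers, hits, fas, dps = [], [], [], [], []
    for i in range(n - window + 1):
        g = is_go[i:i + window]
        lk = licked[i:i + window]
        n_go, n_nogo = int(g.sum()), int((~g).sum())
        if n_go == 0 or n_nogo == 0:
            continue
        h = lk[g].mean()
        f = lk[~g].mean()
        starts.append(i)
        centers.append(i + window // 2)
        hits.append(h)
        fas.append(f)
        dps.append(float(compute_dprime(h, f, correction, n_go, n_nogo)))
    if not starts:
        warnings.warn("no window contained both trial types; empty d' series")
    return DPrimeSeries(window=window, centers=np.array(centers, int),
                        starts=np.array(starts, int),
                        hit_rate=np.array(hits), fa_rate=np.array(fas),
                        dprime=np.array(dps))


@dataclass
class CorrectnessFit:
    """Per-bouton OLS of trial activity on correctness/type/interaction."""

    coefficients: np.ndarray  # (n_boutons, 4) in COEF_NAMES order
    p_values: np.ndarray      # raw, same shape
    p_adjusted: np.ndarray    # BH across boutons, per coefficient
    cmi: np.ndarray
    predictor: str
    skipped: list[tuple[int, str]] = field(default_factory=list)


def correctness_model(activity: np.ndarray, trials: pd.DataFrame,
                      predictor: str = "correct", alpha: float = 0.05,
                      ) -> CorrectnessFit:
    """Fit ``activity ~ correctness + trial_type + interaction`` per bouton.

    ``activity`` is (n_boutons, n_trials) of per-trial mean ΔF/F aligned with
    ``trials``.  ``predictor='previous_correct'`` uses the preceding trial's
    correctness instead (the first trial is dropped).  Gaussian identity-link
    OLS with coefficient t-tests; the design matrix is shared across boutons.
    """
    activity = np.atleast_2d(np.asarray(activity, dtype=float))
    correct = trials["correct"].to_numpy(dtype=float)
    is_go = (trials["trial_type"] == "go").to_numpy(dtype=float)
    if predictor == "previous_correct":
        cvar = correct[:-1]
        is_go = is_go[1:]
        activity = activity[:, 1:]
    elif predictor == "correct":
        cvar = correct
    else:
        raise ValueError(f"unknown predictor {predictor!r}")
    n_b, n_t = activity.shape
    if n_t < 4:
        raise ValueError("need at least 4 trials")
    if len(np.unique(cvar)) < 2:
        raise ValueError("both correctness levels must be present")

    X = np.column_stack([np.ones(n_t), cvar, is_go, cvar * is_go])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        return CorrectnessFit(
            coefficients=np.full((n_b, 4), np.nan),
            p_values=np.full((n_b, 4), np.nan),
            p_adjusted=np.full((n_b, 4), np.nan),
            cmi=_cmi(activity, cvar), predictor=predictor,
            skipped=[(i, "rank-deficient design") for i in range(n_b)])

    xtx_inv = np.linalg.inv(X.T @ X)
    beta = activity @ X @ xtx_inv            # (n_b, 4)
    resid = activity - beta @ X.T
    dof = n_t - X.shape[1]
    sigma2 = (resid ** 2).sum(axis=1) / dof
    se = np.sqrt(np.outer(sigma2, np.diag(xtx_inv)))
    with np.errstate(all="ignore"):
        tvals = beta / se
    p = 2 * stats.t.sf(np.abs(tvals), dof)
    p_adj = np.column_stack([
        multipletests(p[:, j], alpha=alpha, method="fdr_bh")[1]
        for j in range(4)])
    return CorrectnessFit(coefficients=beta, p_values=p, p_adjusted=p_adj,
                          cmi=_cmi(activity, cvar), predictor=predictor)


def _cmi(activity: np.ndarray, correct: np.ndarray) -> np.ndarray:
    rc = activity[:, correct == 1].mean(axis=1)
    ri = activity[:, correct == 0].mean(axis=1)
    with np.errstate(all="ignore"):
        cmi = (rc - ri) / (rc + ri)
    return np.where(rc == ri, 0.0, cmi)


def sliding_population_dff(dff, trials: pd.DataFrame, series: DPrimeSeries,
                           activity_window: str = "pre_trial") -> np.ndarray:
    """Mean population ΔF/F over each d' window's trials.

    ``activity_window`` selects the per-trial epoch: ``pre_trial`` (1 s before
    tone), ``stim2s`` (first 2 s of stimulus, before responses can matter) or
    ``response`` (2-4 s after stimulus onset).
    """
    per_trial = []
    for _, tr in trials.iterrows():
        if activity_window == "pre_trial":
            t0, t1 = tr.tone_time - 1.0, tr.tone_time
        elif activity_window == "stim2s":
            t0, t1 = tr.stim_on, tr.stim_on + 2.0
        elif activity_window == "response":
            t0, t1 = tr.stim_on + 2.0, tr.stim_on + 4.0
        else:
            raise ValueError(f"unknown activity_window {activity_window!r}")
        per_trial.append(np.nanmean(dff.window_mean(t0, t1)))
    per_trial = np.asarray(per_trial)
    return np.array([np.nanmean(per_trial[s:s + series.window])
                     for s in series.starts])


@dataclass
class DPrimeRegression:
    """Per-session d'-vs-activity slopes and the across-session group test."""

    slopes: np.ndarray
    t_stat: float
    p_value: float
    excluded: list[tuple[int, str]] = field(default_factory=list)


def dprime_activity_regression(sessions: list[tuple[DPrimeSeries, np.ndarray]],
                               ) -> DPrimeRegression:
    """Regress windowed d' on windowed population ΔF/F, session by session.

    Each element pairs a d' series with the matching population-activity
    series.  The group test is a two-sided one-sample t-test of the
    per-session slopes against zero.  Sessions with constant population
    activity have an undefined slope and are excluded.
    """
    if len(sessions) < 2:
        raise ValueError("need at least 2 sessions for the group test")
    slopes, excluded = [], []
    for i, (series, pop) in enumerate(sessions):
        pop = np.asarray(pop, dtype=float)
        if pop.size != series.dprime.size:
            raise ValueError(f"session {i}: series length mismatch")
        if np.all(pop == pop[0]):
            excluded.append((i, "constant population activity"))
            continue
        slope = np.polyfit(pop, series.dprime, 1)[0]
        slopes.append(slope)
    slopes = np.asarray(slopes)
    if slopes.size < 2:
        raise ValueError("fewer than 2 usable sessions after exclusions")
    t, p = stats.ttest_1samp(slopes, 0.0)
    return DPrimeRegression(slopes=slopes, t_stat=float(t), p_value=float(p),
                            excluded=excluded)
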