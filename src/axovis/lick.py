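"""Licking analyses: lick rate, circular-shift permutation test, rewarded vs
unrewarded activity, lick bouts, and the reward-targeting index.

The lick rate is the lick count in a centered 1 s window slid over the binary
lick raster.  Because ΔF/F and lick rate are both autocorrelated, the
significance of their Pearson correlation is tested against a null built by
circularly shifting the lick-rate trace (1,000 shifts, minimum ±10 s); a
bouton is significant when its observed correlation exceeds the 95th
percentile of its own null.  Rewarded licking is compared with unrewarded
licking (first 2 s of the go stimulus) within go trials; in the bilateral
task the reward-targeting index RTI = (C_reward - I_reward) /
(C_reward + I_reward) measures the hemispheric bias of reward-period
activity.  Lick bouts (>= 3 licks within 0.5 s after >= 1 s of silence)
support the frequency- and count-matched comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .session import FluorescenceSet


def lick_rate(licks: np.ndarray, frame_times: np.ndarray) -> np.ndarray:
    """Licks in the centered 1 s window [t - 0.5, t + 0.5) per frame."""
    licks = np.asarray(licks, dtype=float)
    t = np.asarray(frame_times, dtype=float)
    lo = np.searchsorted(licks, t - 0.5, side="left")
    hi = np.searchsorted(licks, t + 0.5, side="left")
    return (hi - lo).astype(float)


@dataclass
class LickCorrResult:
    """Observed lick-rate correlations against their circular-shift null."""

    r_obs: np.ndarray
    null_quantile_95: np.ndarray
    p_perm: np.ndarray
    significant: np.ndarray
    highly_correlated: np.ndarray  # r_obs > 0.2
    shifts: np.ndarray
    excluded: list[int] = field(default_factory=list)


def lick_correlation_perm(dff: FluorescenceSet, rate: np.ndarray,
                          n_perm: int = 1000, min_shift_s: float = 10.0,
                          seed: int = 0) -> LickCorrResult:
    """Circular-shift permutation test of bouton-vs-lick-rate correlation.

    Shifts are uniform over [min_shift, T - min_shift] in whole frames (both
    directions fold onto one circular index).  Significance is one-sided
    exceedance of the 95th percentile of the per-bouton null; ``p_perm`` is
    the add-one permutation p-value.  Zero-variance boutons are excluded.
    """
    rate = np.asarray(rate, dtype=float)
    n = dff.n_frames
    if rate.size != n:
        raise ValueError("rate and traces must be frame-aligned")
    dt = dff.dt
    min_shift = int(round(min_shift_s / dt))
    if n <= 2 * min_shift:
        raise ValueError("session shorter than twice the minimum shift")
    if rate.std() == 0:
        raise ValueError("lick rate has zero variance")

    sd = dff.values.std(axis=1)
    excluded = np.nonzero(sd == 0)[0]
    bz = np.zeros_like(dff.values)
    ok = sd > 0
    bz[ok] = (dff.values[ok] - dff.values[ok].mean(axis=1, keepdims=True)) / sd[ok][:, None]
    rz = (rate - rate.mean()) / rate.std()

    r_obs = bz @ rz / n
    rng = np.random.default_rng(seed)
    shifts = rng.integers(min_shift, n - min_shift + 1, size=n_perm)
    idx = (np.arange(n)[None, :] - shifts[:, None]) % n
    null = (rz[idx] @ bz.T) / n                   # (n_perm, n_boutons)
    q95 = np.percentile(null, 95, axis=0)
    p_perm = (1.0 + (null >= r_obs[None, :]).sum(axis=0)) / (n_perm + 1.0)
    significant = r_obs > q95
    significant[excluded] = False
    r_obs[excluded] = np.nan
    return LickCorrResult(r_obs=r_obs, null_quantile_95=q95, p_perm=p_perm,
                          significant=significant,
                          highly_correlated=r_obs > 0.2, shifts=shifts,
                          excluded=excluded.tolist())


@dataclass
class RewardComparison:
    """Rewarded vs unrewarded licking activity (optionally per stimulus side)."""

    dff_unrewarded: np.ndarray
    dff_rewarded: np.ndarray
    paired_t: float
    paired_p: float
    c_reward: np.ndarray | None = None
    i_reward: np.ndarray | None = None
    rti: np.ndarray | None = None
    rti_t: float | None = None
    rti_p: float | None = None
    degenerate: bool = False


def _period_means(dff: FluorescenceSet, periods: list[tuple[float, float]],
                  ) -> np.ndarray:
    """Mean per bouton of per-period window means; NaN if no periods."""
    if not periods:
        return np.full(dff.n_rois, np.nan)
    vals = [dff.window_mean(t0, t1) for t0, t1 in periods]
    return np.nanmean(np.column_stack(vals), axis=1)


def reward_periods(trials: pd.DataFrame, side: str | None = None,
                   ) -> list[tuple[float, float]]:
    """Reward periods of (optionally side-filtered) go trials: reward to stim_off."""
    sel = trials[trials["reward_time"].notna()]
    if side is not None:
        sel = sel[sel["side"] == side]
    return [(float(r.reward_time), float(r.stim_off)) for _, r in sel.iterrows()]


def _unrewarded_periods(trials: pd.DataFrame, licks: np.ndarray,
                        side: str | None = None) -> list[tuple[float, float]]:
    sel = trials[trials["trial_type"] == "go"]
    if side is not None:
        sel = sel[sel["side"] == side]
    out = []
    for _, r in sel.iterrows():
        t0, t1 = float(r.stim_on), float(r.stim_on) + 2.0
        if np.any((licks >= t0) & (licks < t1)):
            out.append((t0, t1))
    return out


def rewarded_vs_unrewarded(dff: FluorescenceSet, trials: pd.DataFrame,
                           licks: np.ndarray, scope: str = "all",
                           ) -> RewardComparison:
    """Compare ΔF/F during rewarded vs unrewarded licking within go trials.

    Unrewarded licking periods are the first 2 s of the go stimulus (where
    responses do not count) and contribute only when they contain a lick;
    rewarded periods run from reward delivery to stimulus offset.  With
    ``scope='per_side'`` the per-bouton contra/ipsi rewarded means C and I
    and RTI = (C - I)/(C + I) are added, with a two-tailed one-sample t-test
    of the RTI population against zero.
    """
    licks = np.asarray(licks, dtype=float)
    rew = reward_periods(trials)
    unrew = _unrewarded_periods(trials, licks)
    if not rew or not unrew:
        raise ValueError("need at least one rewarded and one unrewarded "
                         "licking period among go trials")
    m_rew = _period_means(dff, rew)
    m_unrew = _period_means(dff, unrew)
    t, p = stats.ttest_rel(m_rew, m_unrew)
    result = RewardComparison(dff_unrewarded=m_unrew, dff_rewarded=m_rew,
                              paired_t=float(t), paired_p=float(p))
    if scope == "per_side":
        for side in ("contra", "ipsi"):
            if not len(trials[(trials["side"] == side)
                              & trials["reward_time"].notna()]):
                raise ValueError(f"no rewarded {side} trials; per-side scope "
                                 "needs both sides")
        c = _period_means(dff, reward_periods(trials, "contra"))
        i = _period_means(dff, reward_periods(trials, "ipsi"))
        with np.errstate(all="ignore"):
            rti = (c - i) / (c + i)
        rti = np.where((c == i), 0.0, rti)
        ok = np.isfinite(rti)
        t2, p2 = stats.ttest_1samp(rti[ok], 0.0)
        result.c_reward, result.i_reward, result.rti = c, i, rti
        result.rti_t, result.rti_p = float(t2), float(p2)
    elif scope != "all":
        raise ValueError(f"unknown scope {scope!r}")
    return result


@dataclass
class LickBout:
    """A lick bout: >= 3 licks within 0.5 s, preceded by >= 1 s of silence."""

    start: float
    lick_times: np.ndarray  # first three licks
    rewarded: bool


def detect_bouts(licks: np.ndarray, trials: pd.DataFrame | None = None,
                 ) -> list[LickBout]:
    """Find all lick bouts; label each rewarded if it starts in a reward period.

    A lick starts a bout when no lick occurred in the preceding 1 s and the
    two following licks fall within 0.5 s of it (windows half-open, so the
    third lick must be strictly earlier than start + 0.5 s).
    """
    licks = np.sort(np.asarray(licks, dtype=float))
    periods = reward_periods(trials) if trials is not None else []
    bouts = []
    for i in range(len(licks) - 2):
        if i > 0 and licks[i] - licks[i - 1] < 1.0:
            continue
        if licks[i + 2] - licks[i] < 0.5:
            start = float(licks[i])
            rewarded = any(t0 <= start < t1 for t0, t1 in periods)
            bouts.append(LickBout(start=start, lick_times=licks[i:i + 3].copy(),
                                  rewarded=rewarded))
    return bouts


def bout_matched_comparison(dff: FluorescenceSet, bouts: list[LickBout],
                            ) -> RewardComparison:
    """Rewarded vs unrewarded activity over first-3-lick bout windows only.

    Each bout contributes the mean ΔF/F over [first lick, third lick); if no
    frame falls inside, the causal frame at bout start is used.  The paired
    t-test runs across boutons on the per-bouton class means; with a single
    bout in a class the comparison is marked degenerate.
    """
    rew = [b for b in bouts if b.rewarded]
    unrew = [b for b in bouts if not b.rewarded]
    for name, group in (("rewarded", rew), ("unrewarded", unrew)):
        if not group:
            raise ValueError(f"no {name} bouts")

    def bout_mean(b: LickBout) -> np.ndarray:
        m = dff.window_mean(b.lick_times[0], b.lick_times[2])
        if np.any(np.isnan(m)):
            m = dff.values[:, dff.frame_at(b.start)]
        return m

    m_rew = np.column_stack([bout_mean(b) for b in rew]).mean(axis=1)
    m_unrew = np.column_stack([bout_mean(b) for b in unrew]).mean(axis=1)
    t, p = stats.ttest_rel(m_rew, m_unrew)
    return RewardComparison(dff_unrewarded=m_unrew, dff_rewarded=m_rew,
                            paired_t=float(t), paired_p=float(p),
                            degenerate=(len(rew) < 2 or len(unrew) < 2))
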