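"""Task-modulation statistics.

Compares each bouton's activity inside trials (tone onset to stimulus offset)
against the final 2 s of the properly executed quiescent period immediately
before trial onset (a licking-free epoch), classifies boutons as increased /
decreased / unchanged by a paired t-test, computes the task-modulation index
TMI = (within - between) / (within + between), and tests event-triggered
responses (tone, go stimulus, no-go stimulus, reward, airpuff) with a
one-sided paired t-test and Benjamini-Hochberg FDR correction across boutons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .session import FluorescenceSet

log = logging.getLogger(__name__)

EVENT_TYPES = ("tone", "go_stim", "nogo_stim", "reward", "airpuff")


@dataclass
class TrialActivity:
    """Paired per-trial mean activities: within-trial vs preceding quiescence."""

    within: np.ndarray   # (n_boutons, n_valid_trials)
    between: np.ndarray  # same shape
    trial_ids: np.ndarray
    dropped: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return self.within.shape[1]


def trial_period_activity(dff: FluorescenceSet, trials: pd.DataFrame,
                          licks: np.ndarray, between_s: float = 2.0,
                          ) -> TrialActivity:
    """Per-trial within/between mean ΔF/F pairs for every bouton.

    Trials whose pre-tone ``between_s`` window contains a lick (quiescent
    period not properly executed) or is not fully covered by frames are
    dropped and recorded in ``dropped``.
    """
    licks = np.asarray(licks, dtype=float)
    within_cols, between_cols, ids, dropped = [], [], [], []
    for _, tr in trials.iterrows():
        b0, b1 = tr.tone_time - between_s, tr.tone_time
        if np.any((licks >= b0) & (licks < b1)):
            dropped.append((int(tr.trial_id), "lick in quiescent window"))
            continue
        if b0 < dff.frame_times[0] or tr.stim_off > dff.frame_times[-1] + dff.dt:
            dropped.append((int(tr.trial_id), "partial frame coverage"))
            continue
        w = dff.window_mean(tr.tone_time, tr.stim_off)
        b = dff.window_mean(b0, b1)
        if np.any(np.isnan(w)) or np.any(np.isnan(b)):
            dropped.append((int(tr.trial_id), "empty frame window"))
            continue
        within_cols.append(w)
        between_cols.append(b)
        ids.append(int(tr.trial_id))
    if not within_cols:
        raise ValueError("no valid trials for trial-period activity")
    for tid, why in dropped:
        log.info("trial %d dropped: %s", tid, why)
    return TrialActivity(within=np.column_stack(within_cols),
                         between=np.column_stack(between_cols),
                         trial_ids=np.array(ids), dropped=dropped)


@dataclass
class ModulationResult:
    """Per-bouton task-modulation classification and index."""

    class_label: np.ndarray  # 'increased' | 'decreased' | 'ns'
    p_value: np.ndarray
    tmi: np.ndarray
    degenerate: np.ndarray
    tmi_out_of_range: np.ndarray


def classify_trial_modulation(activity: TrialActivity, alpha: float = 0.01,
                              ) -> ModulationResult:
    """Two-sided paired t-test of within vs between activity per bouton.

    TMI is computed from the trial-mean activities; with nonnegative activity
    it lies in [-1, 1] (values outside are reported as-is and flagged, since
    negative ΔF/F can push the ratio out of range).
    """
    if activity.n_trials < 2:
        raise ValueError("need at least 2 paired trials")
    w, b = activity.within, activity.between
    diff = w - b
    degenerate = diff.std(axis=1) == 0
    with np.errstate(all="ignore"):
        t, p = stats.ttest_rel(w, b, axis=1)
    p = np.where(degenerate, np.nan, p)
    mw, mb = w.mean(axis=1), b.mean(axis=1)
    with np.errstate(all="ignore"):
        tmi = (mw - mb) / (mw + mb)
    tmi = np.where(mw == mb, 0.0, tmi)  # exact equality -> 0 even at 0 denom
    label = np.full(w.shape[0], "ns", dtype=object)
    sig = ~degenerate & (p < alpha)
    label[sig & (mw > mb)] = "increased"
    label[sig & (mw < mb)] = "decreased"
    out_of_range = np.isfinite(tmi) & (np.abs(tmi) > 1)
    return ModulationResult(class_label=label.astype(str), p_value=p, tmi=tmi,
                            degenerate=degenerate, tmi_out_of_range=out_of_range)


def events_from_trials(trials: pd.DataFrame) -> dict[str, np.ndarray]:
    """Extract the five task event-time lists from a trial table."""
    go = trials[trials.trial_type == "go"]
    nogo = trials[trials.trial_type == "nogo"]
    return {
        "tone": trials["tone_time"].to_numpy(float),
        "go_stim": go["stim_on"].to_numpy(float),
        "nogo_stim": nogo["stim_on"].to_numpy(float),
        "reward": trials["reward_time"].dropna().to_numpy(float),
        "airpuff": trials["airpuff_time"].dropna().to_numpy(float),
    }


@dataclass
class EventResponse:
    """Per-event-type BH-adjusted one-sided response tests."""

    p_raw: dict[str, np.ndarray]
    p_adjusted: dict[str, np.ndarray]
    responsive: dict[str, np.ndarray]
    omitted: list[str] = field(default_factory=list)


def event_response_test(dff: FluorescenceSet, events: dict[str, np.ndarray],
                        pre_window: float = 0.5, post_window: float = 1.0,
                        alpha: float = 0.05) -> EventResponse:
    """One-sided (increase) paired t-test of post- vs pre-event mean ΔF/F.

    For each event type the pre window is [t - pre_window, t) and the post
    window [t, t + post_window); BH correction runs across boutons within an
    event type.  Types with fewer than two usable events are omitted.
    """
    p_raw: dict[str, np.ndarray] = {}
    p_adj: dict[str, np.ndarray] = {}
    responsive: dict[str, np.ndarray] = {}
    omitted = []
    for etype, times in events.items():
        pre_cols, post_cols = [], []
        for t in np.asarray(times, dtype=float):
            pre = dff.window_mean(t - pre_window, t)
            post = dff.window_mean(t, t + post_window)
            if np.any(np.isnan(pre)) or np.any(np.isnan(post)):
                continue
            pre_cols.append(pre)
            post_cols.append(post)
        if len(pre_cols) < 2:
            omitted.append(etype)
            log.info("event type %s omitted (<2 usable events)", etype)
            continue
        pre_m = np.column_stack(pre_cols)
        post_m = np.column_stack(post_cols)
        with np.errstate(all="ignore"):
            _, p = stats.ttest_rel(post_m, pre_m, axis=1, alternative="greater")
        p = np.where(np.isnan(p), 1.0, p)
        rej, padj, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
        p_raw[etype], p_adj[etype], responsive[etype] = p, padj, rej
    return EventResponse(p_raw=p_raw, p_adjusted=p_adj, responsive=responsive,
                         omitted=omitted)
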