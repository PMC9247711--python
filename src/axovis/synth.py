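"""Synthetic session generator.

Emulates the statistical structure the analysis modules assume: a head-fixed
go/no-go visual discrimination task (auditory start tone, grating stimulus 1 s
later lasting 4 s, reward for licking 2-4 s after go-stimulus onset, airpuff
plus 10 s timeout on false alarms, 2-10 s quiescent periods), an agent that
licks rhythmically when rewarded, slow-indicator bouton traces with known
couplings to behavioral regressors, direction-tuned soma responses, and pupil
landmark tables.  Every simulated quantity is recorded in a ``GroundTruth``
object so that recovery tests can compare estimates against what was injected.

Bouton traces are built as a linear-convolutional model: each behavioral
regressor (lick counts, reward/tone impulses, stimulus/trial boxes) is scaled
by a coupling weight, summed with a Poisson shot-noise background, convolved
with a difference-of-exponentials kernel (rise 0.2 s, decay 1.5 s, a GCaMP6s
stand-in), and topped with white Gaussian noise.  The hemispheric gain
multiplies the reward-coupled component on contralateral-side trials only,
which makes the reward-targeting index analytically (g-1)/(g+1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .session import (FluorescenceSet, ParameterError, SessionRecord,
                      TRIAL_COLUMNS)

REGRESSORS = ("lick_rate", "reward", "tone", "go_stim", "nogo_stim",
              "in_trial", "correctness")


@dataclass
class TaskConfig:
    """Timing and composition of the go/no-go task (defaults: trained task)."""

    tone_duration: float = 0.1
    tone_to_stim: float = 1.0
    stim_duration: float = 4.0
    response_window: tuple[float, float] = (2.0, 4.0)  # s after stim_on
    quiescent_range: tuple[float, float] = (2.0, 10.0)
    timeout_after_fa: float = 10.0
    airpuff_duration: float = 0.5
    n_trials: int = 200
    frac_go: float = 0.5
    sides: tuple[str, ...] = ("monocular",)
    contrasts: tuple[float, ...] = (1.0,)
    frame_rate: float = 10.0

    def validate(self) -> None:
        for name in ("tone_duration", "tone_to_stim", "stim_duration",
                     "timeout_after_fa", "airpuff_duration", "frame_rate"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"TaskConfig.{name} must be > 0")
        rw0, rw1 = self.response_window
        if not (0 <= rw0 < rw1 <= self.stim_duration):
            raise ParameterError("response_window must lie within the stimulus")
        q0, q1 = self.quiescent_range
        if not (0 < q0 <= q1):
            raise ParameterError("quiescent_range must be positive and ordered")
        if self.n_trials < 1:
            raise ParameterError("n_trials must be >= 1")
        if not (0 <= self.frac_go <= 1):
            raise ParameterError("frac_go must be in [0,1]")


@dataclass
class AgentParams:
    """Behavioral agent: outcome probabilities and licking dynamics.

    Rewarded licking is a sustained rhythmic bout (> 6 Hz) starting at the
    response lick; unrewarded licking is sparse and short.  ``accuracy_drift_sd``
    turns on a bounded random walk of the hit/false-alarm rates to mimic slow
    within-session accuracy fluctuation.  Trained animals respond promptly
    after the reward window opens (``response_latency_mean/sd``).
    """

    hit_rate: float = 0.8
    fa_rate: float = 0.2
    reward_lick_freq: float = 7.0
    unrewarded_lick_freq: float = 6.5
    impulsive_lick_prob: float = 0.4
    spontaneous_lick_rate: float = 0.03
    response_latency_mean: float = 0.3
    response_latency_sd: float = 0.15
    reward_bout_range: tuple[float, float] = (1.0, 2.0)
    accuracy_drift_sd: float = 0.0

    def validate(self) -> None:
        for name in ("hit_rate", "fa_rate", "impulsive_lick_prob"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ParameterError(f"AgentParams.{name} must be in [0,1]")
        for name in ("reward_lick_freq", "unrewarded_lick_freq",
                     "spontaneous_lick_rate", "accuracy_drift_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"AgentParams.{name} must be >= 0")


@dataclass
class BoutonSpec:
    """Generative parameters of one simulated bouton.

    ``coupling`` maps regressor names (subset of ``REGRESSORS``) to gains;
    ``baseline_rate`` (events/s) drives the Poisson shot-noise background that
    gives traces GCaMP-like autocorrelation even with zero couplings.
    ``reward_jitter_sd`` is fractional trial-to-trial variability of this
    bouton's reward response (synaptic-variability stand-in).
    """

    coupling: dict[str, float] = field(default_factory=dict)
    hemispheric_gain: float = 1.0
    baseline_rate: float = 0.2
    baseline_amp: float = 1.0
    noise_sd: float = 0.05
    kernel_tau_rise: float = 0.2
    kernel_tau_decay: float = 1.5
    reward_jitter_sd: float = 0.25

    def validate(self) -> None:
        if self.kernel_tau_rise <= 0 or self.kernel_tau_decay <= 0:
            raise ParameterError("kernel taus must be > 0")
        if self.kernel_tau_rise >= self.kernel_tau_decay:
            raise ParameterError("kernel_tau_rise must be < kernel_tau_decay")
        for k, v in self.coupling.items():
            if k not in REGRESSORS:
                raise ParameterError(f"unknown regressor {k!r}")
            if not np.isfinite(v):
                raise ParameterError(f"coupling {k!r} must be finite")
        if self.baseline_rate < 0 or self.noise_sd < 0:
            raise ParameterError("baseline_rate and noise_sd must be >= 0")


@dataclass
class SomaSpec:
    """Double-Gaussian direction tuning of one simulated V1 soma."""

    pref_direction: float = 0.0
    amp_pref: float = 1.0
    amp_null: float = 0.4
    width_sigma: float = 25.0
    offset: float = 0.1
    modulator_interaction: float = 1.0

    def validate(self) -> None:
        if self.amp_pref < 0 or self.amp_null < 0:
            raise ParameterError("tuning amplitudes must be >= 0")
        if self.width_sigma <= 0:
            raise ParameterError("width_sigma must be > 0")


@dataclass
class GroundTruth:
    """Everything the generator injected, for recovery tests."""

    seed: int
    boutons: list[BoutonSpec] = field(default_factory=list)
    somas: list[SomaSpec] = field(default_factory=list)
    trial_hit_rate: np.ndarray | None = None
    trial_fa_rate: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, dict):
                return {k: conv(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [conv(v) for v in x]
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            return x
        return conv({
            "seed": self.seed,
            "boutons": [asdict(b) for b in self.boutons],
            "somas": [asdict(s) for s in self.somas],
            "trial_hit_rate": self.trial_hit_rate,
            "trial_fa_rate": self.trial_fa_rate,
            "extras": self.extras,
        })


def double_exp_kernel(tau_rise: float, tau_decay: float, dt: float) -> np.ndarray:
    """Difference-of-exponentials indicator kernel, normalized to unit peak."""
    t = np.arange(0, 8 * tau_decay, dt)
    k = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    peak = k.max()
    if peak <= 0:
        raise ParameterError("degenerate kernel")
    return k / peak


def tuning_curve(theta, spec: SomaSpec, amp_scale: float = 1.0) -> np.ndarray:
    """Ground-truth double-Gaussian response at direction ``theta`` (deg)."""
    theta = np.asarray(theta, dtype=float)

    def g(delta, sigma):
        d = (delta + 180.0) % 360.0 - 180.0
        return np.exp(-d ** 2 / (2.0 * sigma ** 2))

    return (spec.offset
            + amp_scale * spec.amp_pref * g(theta - spec.pref_direction, spec.width_sigma)
            + spec.amp_null * g(theta - spec.pref_direction - 180.0, spec.width_sigma))


# ---------------------------------------------------------------------------
# Task session
# ---------------------------------------------------------------------------

def _rhythmic_bout(start: float, freq: float, duration: float,
                   rng: np.random.Generator, t_max: float) -> np.ndarray:
    if freq <= 0 or duration <= 0:
        return np.array([start])
    t = start + np.arange(0, duration, 1.0 / freq)
    t = t + rng.normal(0, 0.008, size=t.size)
    t = np.sort(t[(t >= start) & (t < t_max)])
    return t if t.size else np.array([start])


def _simulate_behavior(config: TaskConfig, agent: AgentParams,
                       rng: np.random.Generator):
    rw0, rw1 = config.response_window
    rows, licks = [], []
    p_hit, p_fa = agent.hit_rate, agent.fa_rate
    hit_rates, fa_rates = [], []
    t = rng.uniform(*config.quiescent_range)
    for i in range(config.n_trials):
        if agent.accuracy_drift_sd > 0 and i > 0:
            p_hit = float(np.clip(p_hit + rng.normal(0, agent.accuracy_drift_sd), 0.05, 0.95))
            p_fa = float(np.clip(p_fa + rng.normal(0, agent.accuracy_drift_sd), 0.05, 0.95))
        hit_rates.append(p_hit)
        fa_rates.append(p_fa)
        tone = t
        stim_on = tone + config.tone_to_stim
        stim_off = stim_on + config.stim_duration
        is_go = rng.random() < config.frac_go
        side = str(rng.choice(config.sides))
        contrast = float(rng.choice(config.contrasts))

        reward_time = np.nan
        airpuff_time = np.nan
        licked = False
        gap_extra = 0.0

        if rng.random() < agent.impulsive_lick_prob:
            n_imp = int(rng.integers(2, 5))
            bout = stim_on + rng.uniform(0.0, 0.3) + np.arange(n_imp) / max(
                agent.unrewarded_lick_freq, 1.0)
            licks.extend(bout[bout < stim_on + rw0 - 0.05])

        latency = float(np.clip(
            rng.normal(agent.response_latency_mean, agent.response_latency_sd),
            0.05, rw1 - rw0 - 0.35))
        if is_go:
            if rng.random() < p_hit:
                licked = True
                t_resp = stim_on + rw0 + latency
                reward_time = t_resp
                dur = min(rng.uniform(*agent.reward_bout_range), stim_off - t_resp)
                licks.extend(_rhythmic_bout(t_resp, agent.reward_lick_freq,
                                            dur, rng, stim_off))
        else:
            if rng.random() < p_fa:
                licked = True
                t_fa = stim_on + rw0 + latency
                airpuff_time = t_fa
                licks.extend(t_fa + np.arange(3) / max(agent.unrewarded_lick_freq, 1.0))
                gap_extra = config.timeout_after_fa
        correct = licked if is_go else (not licked)
        rows.append({
            "trial_id": i, "trial_type": "go" if is_go else "nogo",
            "side": side, "contrast": contrast, "tone_time": tone,
            "stim_on": stim_on, "stim_off": stim_off,
            "response": "lick" if licked else "no_lick", "correct": correct,
            "reward_time": reward_time, "airpuff_time": airpuff_time,
        })
        t = stim_off + gap_extra + rng.uniform(*config.quiescent_range)

    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    duration = t + 2.0

    if agent.spontaneous_lick_rate > 0:
        n_sp = rng.poisson(agent.spontaneous_lick_rate * duration)
        cand = np.sort(rng.uniform(0, duration, size=n_sp))
        # the task gates trial starts on quiet quiescent periods, so keep
        # spontaneous licks out of [tone - 2 s, stim_off) of every trial
        keep = np.ones(cand.size, dtype=bool)
        for _, r in trials.iterrows():
            keep &= ~((cand >= r.tone_time - 2.0) & (cand < r.stim_off))
        licks.extend(cand[keep])

    lick_arr = np.sort(np.asarray(licks, dtype=float))
    if lick_arr.size:
        keep = np.concatenate([[True], np.diff(lick_arr) > 0.02])
        lick_arr = lick_arr[keep]
    return trials, lick_arr, duration, np.array(hit_rates), np.array(fa_rates)


def _box(frame_times: np.ndarray, t0: float, t1: float) -> np.ndarray:
    out = np.zeros(frame_times.size)
    i0 = np.searchsorted(frame_times, t0, side="left")
    i1 = np.searchsorted(frame_times, t1, side="left")
    out[i0:i1] = 1.0
    return out


def _impulses(frame_times: np.ndarray, times: np.ndarray,
              amps: np.ndarray | None = None) -> np.ndarray:
    out = np.zeros(frame_times.size)
    if len(times) == 0:
        return out
    idx = np.searchsorted(frame_times, times, side="right") - 1
    idx = np.clip(idx, 0, frame_times.size - 1)
    if amps is None:
        amps = np.ones(len(times))
    np.add.at(out, idx, amps)
    return out


def _build_regressors(frame_times: np.ndarray, trials: pd.DataFrame,
                      licks: np.ndarray) -> dict[str, np.ndarray]:
    n = frame_times.size
    reg = {k: np.zeros(n) for k in REGRESSORS}
    reg["lick_rate"] = _impulses(frame_times, licks)
    reg["tone"] = _impulses(frame_times, trials["tone_time"].to_numpy())
    for _, r in trials.iterrows():
        key = "go_stim" if r.trial_type == "go" else "nogo_stim"
        reg[key] += _box(frame_times, r.stim_on, r.stim_off)
        reg["in_trial"] += _box(frame_times, r.tone_time, r.stim_off)
        if r.correct:
            reg["correctness"] += _box(frame_times, r.tone_time, r.stim_off)
    return reg


def _bouton_signal(spec: BoutonSpec, frame_times: np.ndarray,
                   reg: dict[str, np.ndarray], trials: pd.DataFrame,
                   rng: np.random.Generator, dt: float) -> np.ndarray:
    n = frame_times.size
    drive = np.zeros(n)
    for name, w in spec.coupling.items():
        if name == "reward" or w == 0:
            continue
        drive += w * reg[name]
    w_rew = spec.coupling.get("reward", 0.0)
    if w_rew != 0 and len(trials):
        rewarded = trials[trials["reward_time"].notna()]
        times = rewarded["reward_time"].to_numpy(float)
        gains = np.where(rewarded["side"].to_numpy() == "contra",
                         spec.hemispheric_gain, 1.0)
        jit = np.maximum(0.0, 1.0 + spec.reward_jitter_sd
                         * rng.standard_normal(len(times)))
        drive += w_rew * _impulses(frame_times, times, gains * jit)
    if spec.baseline_rate > 0:
        drive = drive + spec.baseline_amp * rng.poisson(
            spec.baseline_rate * dt, size=n)
    kernel = double_exp_kernel(spec.kernel_tau_rise, spec.kernel_tau_decay, dt)
    sig = fftconvolve(drive, kernel)[:n]
    if spec.noise_sd > 0:
        sig = sig + spec.noise_sd * rng.standard_normal(n)
    return sig


def simulate_session(config: TaskConfig, agent: AgentParams,
                     boutons: list[BoutonSpec], seed: int,
                     trace_kind: str = "raw_F",
                     f0_range: tuple[float, float] = (50.0, 200.0),
                     ) -> tuple[SessionRecord, GroundTruth]:
    """Simulate one go/no-go session; deterministic for a given ``seed``.

    ``trace_kind='raw_F'`` embeds the bouton signal multiplicatively on a
    per-ROI raw-fluorescence offset (so the ΔF/F stage has work to do);
    ``'dff'`` returns the signal directly.
    """
    config.validate()
    agent.validate()
    if not boutons:
        raise ParameterError("need at least one bouton")
    for b in boutons:
        b.validate()
    rng = np.random.default_rng(seed)
    trials, licks, duration, hr, fr = _simulate_behavior(config, agent, rng)

    dt = 1.0 / config.frame_rate
    frame_times = np.arange(int(np.ceil(duration / dt))) * dt
    reg = _build_regressors(frame_times, trials, licks)

    values = np.empty((len(boutons), frame_times.size))
    for i, spec in enumerate(boutons):
        sig = _bouton_signal(spec, frame_times, reg, trials, rng, dt)
        if trace_kind == "raw_F":
            f0 = rng.uniform(*f0_range)
            values[i] = f0 * (1.0 + sig)
        else:
            values[i] = sig
    roi_pixels = rng.integers(4, 40, size=len(boutons))
    fset = FluorescenceSet(values=values, frame_times=frame_times,
                           roi_pixels=roi_pixels, channel="green",
                           kind=trace_kind)
    session = SessionRecord(trials=trials, licks=licks,
                            fluorescence={"green": fset})
    gt = GroundTruth(seed=seed, boutons=list(boutons),
                     trial_hit_rate=hr, trial_fa_rate=fr)
    return session, gt


# ---------------------------------------------------------------------------
# Passive tuning experiment
# ---------------------------------------------------------------------------

def simulate_tuning_experiment(somas: list[SomaSpec],
                               axon_pop_spec: list[BoutonSpec],
                               n_repeats: int, seed: int,
                               n_positions: int = 2,
                               noise_sd: float = 0.05,
                               frame_rate: float = 10.0,
                               stim_duration: float = 1.0,
                               ) -> tuple[SessionRecord, GroundTruth]:
    """Simulate passive drifting-grating presentations (8 directions).

    Soma responses follow the ground-truth double Gaussian during each 1 s
    stimulus window; when a soma's ``modulator_interaction`` differs from 1
    its preferred-direction amplitude is scaled on presentations where the
    concurrent axon-population activity is in the upper half.  Axon traces are
    slow shot-noise fluctuations, so the population activity spread between
    low and high presentations is substantial by construction.
    """
    if not somas:
        raise ParameterError("need at least one soma")
    if n_repeats < 2:
        raise ParameterError("n_repeats must be >= 2")
    for s in somas:
        s.validate()
    rng = np.random.default_rng(seed)
    directions = np.arange(8) * 45.0
    conds = [(d, p) for d in directions for p in range(n_positions)]
    pres = [c for _ in range(n_repeats) for c in conds]
    rng.shuffle(pres)
    n_pres = len(pres)
    start = 5.0
    onsets = start + np.arange(n_pres) * stim_duration
    duration = onsets[-1] + stim_duration + 5.0
    dt = 1.0 / frame_rate
    frame_times = np.arange(int(np.ceil(duration / dt))) * dt

    stimuli = pd.DataFrame({
        "onset": onsets,
        "direction": [d for d, _ in pres],
        "position_index": [p for _, p in pres],
    })

    # concurrent axon population: slow autocorrelated fluctuations
    if axon_pop_spec:
        axon_vals = np.stack([
            _bouton_signal(sp, frame_times, {k: np.zeros(frame_times.size)
                                             for k in REGRESSORS},
                           pd.DataFrame(columns=TRIAL_COLUMNS), rng, dt)
            for sp in axon_pop_spec])
    else:
        axon_vals = np.zeros((1, frame_times.size))
    pop_trace = axon_vals.mean(axis=0)
    pop_per_pres = np.array([
        pop_trace[np.searchsorted(frame_times, t0, "left"):
                  np.searchsorted(frame_times, t0 + stim_duration, "left")].mean()
        for t0 in onsets])
    order = np.argsort(pop_per_pres, kind="stable")
    high = np.zeros(n_pres, dtype=bool)
    high[order[n_pres // 2:]] = True

    soma_vals = np.zeros((len(somas), frame_times.size))
    for j, (t0, (d, _p)) in enumerate(zip(onsets, pres)):
        i0 = np.searchsorted(frame_times, t0, "left")
        i1 = np.searchsorted(frame_times, t0 + stim_duration, "left")
        for i, spec in enumerate(somas):
            scale = spec.modulator_interaction if high[j] else 1.0
            r = float(tuning_curve(d, spec, amp_scale=scale))
            if noise_sd > 0:
                r += noise_sd * rng.standard_normal()
            soma_vals[i, i0:i1] = r

    soma_set = FluorescenceSet(values=soma_vals, frame_times=frame_times,
                               roi_pixels=np.full(len(somas), 100),
                               channel="red", kind="dff")
    axon_set = FluorescenceSet(values=axon_vals, frame_times=frame_times,
                               roi_pixels=np.full(axon_vals.shape[0], 10),
                               channel="green", kind="dff")
    session = SessionRecord(trials=pd.DataFrame(columns=TRIAL_COLUMNS),
                            licks=np.array([]),
                            fluorescence={"red": soma_set, "green": axon_set},
                            stimuli=stimuli)
    gt = GroundTruth(seed=seed, somas=list(somas), boutons=list(axon_pop_spec),
                     extras={"high_presentations": high,
                             "pop_per_presentation": pop_per_pres})
    return session, gt


# ---------------------------------------------------------------------------
# Pupil landmarks
# ---------------------------------------------------------------------------

def simulate_pupil_frames(ellipse_truth: pd.DataFrame,
                          eye_geometry: dict[str, tuple[float, float]],
                          jitter_sd: float = 0.0,
                          outlier_rate: float = 0.0,
                          seed: int = 0,
                          blink_frames: np.ndarray | None = None,
                          frame_rate: float = 30.0,
                          ) -> tuple[pd.DataFrame, dict]:
    """Place 12 landmarks per frame: 4 eyelid corners + 8 pupil octagon points.

    ``ellipse_truth`` needs columns ``cx, cy, a, b, theta_deg`` (one row per
    frame).  Outlier markers and blink frames are displaced well outside the
    eyelid contour so the downstream geometric validation discards them.
    """
    for m in ("eye_medial", "eye_lateral", "eye_superior", "eye_inferior"):
        if m not in eye_geometry:
            raise ParameterError(f"eye_geometry missing marker {m}")
    med = np.asarray(eye_geometry["eye_medial"], float)
    lat = np.asarray(eye_geometry["eye_lateral"], float)
    sup = np.asarray(eye_geometry["eye_superior"], float)
    inf = np.asarray(eye_geometry["eye_inferior"], float)
    if not np.all(np.isfinite([med, lat, sup, inf])) or med[0] >= lat[0]:
        raise ParameterError("degenerate eye geometry")

    rng = np.random.default_rng(seed)
    n_frames = len(ellipse_truth)
    blink = np.zeros(n_frames, dtype=bool)
    if blink_frames is not None:
        blink[np.asarray(blink_frames, int)] = True
    away = 4.0 * (sup - (med + lat) / 2.0)  # displacement well past the upper lid

    phis = np.deg2rad(np.arange(8) * 45.0)
    rows = []
    outlier_mask = np.zeros((n_frames, 8), dtype=bool)
    for fi in range(n_frames):
        e = ellipse_truth.iloc[fi]
        th = np.deg2rad(e["theta_deg"])
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        pts = (rot @ np.stack([e["a"] * np.cos(phis),
                               e["b"] * np.sin(phis)])).T
        pts = pts + np.array([e["cx"], e["cy"]])
        if jitter_sd > 0:
            pts = pts + rng.normal(0, jitter_sd, size=pts.shape)
        if blink[fi]:
            pts = pts + away
        elif outlier_rate > 0:
            out = rng.random(8) < outlier_rate
            outlier_mask[fi] = out
            pts[out] = pts[out] + away
        row = {"frame_time": fi / frame_rate}
        for name, p in zip(("eye_medial", "eye_lateral", "eye_superior",
                            "eye_inferior"), (med, lat, sup, inf)):
            row[f"{name}_x"], row[f"{name}_y"], row[f"{name}_valid"] = p[0], p[1], True
        for k in range(8):
            row[f"pupil_{k + 1}_x"] = pts[k, 0]
            row[f"pupil_{k + 1}_y"] = pts[k, 1]
            row[f"pupil_{k + 1}_valid"] = True
        rows.append(row)
    frames = pd.DataFrame(rows)
    truth = {"ellipse": ellipse_truth, "blink": blink, "outliers": outlier_mask}
    return frames, truth
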