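"""Session data model and on-disk I/O.

A session bundles everything one behavioral imaging experiment produces
downstream of ROI segmentation: a trial event table, the lick raster, one or
more ROI x frame fluorescence matrices, and optionally a passive-stimulus log
and a pupil landmark table.  All times are seconds from session start and all
analysis windows are half-open ``[t0, t1)`` so that an event sitting exactly
on a boundary is counted once.

On disk a session is a directory of plain-text CSV tables plus one HDF5
container for the fluorescence matrices::

    trials.csv   licks.csv   stimuli.csv   pupil.csv   traces.h5

Events are mapped to frames causally ("last frame at or before the event"),
which is the right alignment for a slow calcium indicator.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

TRIAL_COLUMNS = [
    "trial_id", "trial_type", "side", "contrast", "tone_time", "stim_on",
    "stim_off", "response", "correct", "reward_time", "airpuff_time",
]
STIMULUS_COLUMNS = ["onset", "direction", "position_index"]
EYE_MARKERS = ["eye_medial", "eye_lateral", "eye_superior", "eye_inferior"]
PUPIL_MARKERS = [f"pupil_{i}" for i in range(1, 9)]
ALL_MARKERS = EYE_MARKERS + PUPIL_MARKERS

TRIAL_TYPES = {"go", "nogo"}
SIDES = {"contra", "ipsi", "monocular"}
RESPONSES = {"lick", "no_lick"}
CHANNELS = {"green", "red"}
TRACE_KINDS = {"raw_F", "dff"}


class SchemaError(ValueError):
    """A file does not match the documented column/layout schema."""


class SessionValidationError(ValueError):
    """A session violates one or more data-model invariants."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("session invalid:\n  " + "\n  ".join(violations))


class ParameterError(ValueError):
    """Invalid configuration or parameter value."""


@dataclass
class FluorescenceSet:
    """ROI x frame fluorescence matrix with timestamps and ROI sizes.

    ``kind`` distinguishes raw fluorescence (``raw_F``) from baseline-
    normalized ``dff`` traces; ``roi_pixels`` is the pixel count of each ROI
    mask, used as the weight when merging boutons into putative axons.
    """

    values: np.ndarray
    frame_times: np.ndarray
    roi_pixels: np.ndarray
    channel: str = "green"
    kind: str = "raw_F"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.roi_pixels = np.asarray(self.roi_pixels)
        if self.values.ndim != 2:
            raise SchemaError("FluorescenceSet.values must be 2-D (ROI x frame)")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.frame_times)))

    def frame_at(self, t: float) -> int:
        """Index of the last frame whose timestamp is <= ``t`` (causal map)."""
        i = int(np.searchsorted(self.frame_times, t, side="right")) - 1
        if i < 0:
            raise ValueError(f"time {t} precedes first frame")
        return i

    def window_indices(self, t0: float, t1: float) -> slice:
        """Frames with ``t0 <= frame_time < t1`` (half-open window)."""
        i0 = int(np.searchsorted(self.frame_times, t0, side="left"))
        i1 = int(np.searchsorted(self.frame_times, t1, side="left"))
        return slice(i0, i1)

    def window_mean(self, t0: float, t1: float) -> np.ndarray:
        """Per-ROI mean over the half-open window; NaN-shaped if empty."""
        sl = self.window_indices(t0, t1)
        if sl.stop <= sl.start:
            return np.full(self.n_rois, np.nan)
        return self.values[:, sl].mean(axis=1)

    def copy_with(self, **kw) -> "FluorescenceSet":
        d = dataclasses.asdict(self)
        d.update(kw)
        return FluorescenceSet(**d)


@dataclass
class SessionRecord:
    """One experiment: trials, licks, fluorescence sets, optional extras."""

    trials: pd.DataFrame
    licks: np.ndarray
    fluorescence: dict[str, FluorescenceSet] = field(default_factory=dict)
    stimuli: pd.DataFrame | None = None
    pupil: pd.DataFrame | None = None

    def __post_init__(self):
        self.licks = np.asarray(self.licks, dtype=float)

    @property
    def duration(self) -> float:
        ends = [0.0]
        if len(self.trials):
            ends.append(float(self.trials["stim_off"].max()))
        if len(self.licks):
            ends.append(float(self.licks[-1]))
        for fs in self.fluorescence.values():
            if fs.n_frames:
                ends.append(float(fs.frame_times[-1]))
        return max(ends)


def _check_trials(trials: pd.DataFrame, out: list[str]) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        out.append(f"TrialTable: missing columns {missing}")
        return
    for _, row in trials.iterrows():
        tid = row["trial_id"]
        if row["trial_type"] not in TRIAL_TYPES:
            out.append(f"TrialTable: trial {tid} bad trial_type {row['trial_type']!r}")
        if row["side"] not in SIDES:
            out.append(f"TrialTable: trial {tid} bad side {row['side']!r}")
        if row["response"] not in RESPONSES:
            out.append(f"TrialTable: trial {tid} bad response {row['response']!r}")
        if not (0 < row["contrast"] <= 1):
            out.append(f"TrialTable: trial {tid} contrast {row['contrast']} outside (0,1]")
        if not (row["tone_time"] < row["stim_on"] < row["stim_off"]):
            out.append(f"TrialTable: trial {tid} event times not ordered "
                       "(need tone_time < stim_on < stim_off)")
        is_go, correct = row["trial_type"] == "go", bool(row["correct"])
        has_reward = pd.notna(row["reward_time"])
        has_puff = pd.notna(row["airpuff_time"])
        if has_reward != (is_go and correct):
            out.append(f"TrialTable: trial {tid} reward_time present iff go & correct violated")
        if has_puff != ((not is_go) and not correct):
            out.append(f"TrialTable: trial {tid} airpuff_time present iff nogo & incorrect violated")
    tt = trials["tone_time"].to_numpy()
    if np.any(np.diff(tt) <= 0):
        out.append("TrialTable: trials not time-ordered by tone_time")
    else:
        off = trials["stim_off"].to_numpy()
        ids = trials["trial_id"].to_numpy()
        bad = np.nonzero(tt[1:] < off[:-1])[0]
        for i in bad:
            out.append(f"TrialTable: trials {ids[i]} and {ids[i + 1]} overlap")


def _check_fluorescence(name: str, fs: FluorescenceSet, out: list[str]) -> None:
    if fs.channel not in CHANNELS:
        out.append(f"FluorescenceSet {name}: bad channel {fs.channel!r}")
    if fs.kind not in TRACE_KINDS:
        out.append(f"FluorescenceSet {name}: bad kind {fs.kind!r}")
    if fs.frame_times.shape != (fs.n_frames,):
        out.append(f"FluorescenceSet {name}: frame_times length mismatch")
        return
    if fs.roi_pixels.shape != (fs.n_rois,):
        out.append(f"FluorescenceSet {name}: roi_pixels length mismatch")
    elif np.any(fs.roi_pixels < 1):
        out.append(f"FluorescenceSet {name}: roi_pixels must be >= 1")
    dts = np.diff(fs.frame_times)
    if len(dts):
        if np.any(dts <= 0):
            out.append(f"FluorescenceSet {name}: frame_times not strictly increasing")
        else:
            med = np.median(dts)
            if np.any(np.abs(dts - med) > 0.5 * med):
                out.append(f"FluorescenceSet {name}: frame spacing not approximately uniform")


def validate_session(session: SessionRecord) -> list[str]:
    """Return a list of invariant violations (empty when the session is valid)."""
    out: list[str] = []
    _check_trials(session.trials, out)
    licks = session.licks
    if len(licks) > 1 and np.any(np.diff(licks) <= 0):
        out.append("LickRaster: lick_times not strictly increasing")
    for name, fs in session.fluorescence.items():
        _check_fluorescence(name, fs, out)
    if session.stimuli is not None and len(session.stimuli):
        missing = [c for c in STIMULUS_COLUMNS if c not in session.stimuli.columns]
        if missing:
            out.append(f"StimulusLog: missing columns {missing}")
        else:
            on = session.stimuli["onset"].to_numpy()
            if np.any(np.diff(on) < 0):
                out.append("StimulusLog: onsets not sorted")
            d = session.stimuli["direction"].to_numpy()
            if np.any((d < 0) | (d >= 360)):
                out.append("StimulusLog: direction outside [0, 360)")
    return out


def save_session(session: SessionRecord, out_dir: str | Path) -> list[Path]:
    """Write a session to ``out_dir``; returns the paths written.

    CSV tables use empty fields for missing values; the HDF5 container has one
    group per fluorescence set with datasets ``values``, ``frame_times`` and
    ``roi_pixels`` and attributes ``kind`` and ``channel``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    p = out_dir / "trials.csv"
    session.trials.loc[:, TRIAL_COLUMNS].to_csv(p, index=False, na_rep="")
    written.append(p)

    p = out_dir / "licks.csv"
    pd.DataFrame({"lick_time": session.licks}).to_csv(p, index=False)
    written.append(p)

    if session.stimuli is not None:
        p = out_dir / "stimuli.csv"
        session.stimuli.loc[:, STIMULUS_COLUMNS].to_csv(p, index=False)
        written.append(p)

    if session.pupil is not None:
        p = out_dir / "pupil.csv"
        session.pupil.to_csv(p, index=False)
        written.append(p)

    p = out_dir / "traces.h5"
    with h5py.File(p, "w") as h5:
        for name, fs in session.fluorescence.items():
            g = h5.create_group(name)
            g.create_dataset("values", data=fs.values)
            g.create_dataset("frame_times", data=fs.frame_times)
            g.create_dataset("roi_pixels", data=fs.roi_pixels)
            g.attrs["kind"] = fs.kind
            g.attrs["channel"] = fs.channel
    written.append(p)
    return written


def _read_csv(path: Path, required: list[str] | None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if required is not None:
        extra = [c for c in df.columns if c not in required]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"{path.name}: missing column(s) {missing}")
        if extra:
            raise SchemaError(f"{path.name}: unexpected column(s) {extra}")
    return df


def load_session(in_dir: str | Path, validate: bool = True) -> SessionRecord:
    """Load a session directory written by :func:`save_session`.

    Raises :class:`SchemaError` on layout mismatches and
    :class:`SessionValidationError` when invariants are violated (unless
    ``validate=False``).
    """
    in_dir = Path(in_dir)
    trials = _read_csv(in_dir / "trials.csv", TRIAL_COLUMNS)
    trials["correct"] = trials["correct"].astype(bool)
    licks = _read_csv(in_dir / "licks.csv", ["lick_time"])["lick_time"].to_numpy(float)

    stimuli = None
    if (in_dir / "stimuli.csv").exists():
        stimuli = _read_csv(in_dir / "stimuli.csv", STIMULUS_COLUMNS)

    pupil = None
    if (in_dir / "pupil.csv").exists():
        pupil = pd.read_csv(in_dir / "pupil.csv")
        if "frame_time" not in pupil.columns:
            raise SchemaError("pupil.csv: missing column ['frame_time']")

    fluorescence: dict[str, FluorescenceSet] = {}
    h5_path = in_dir / "traces.h5"
    if h5_path.exists():
        with h5py.File(h5_path, "r") as h5:
            for name in h5:
                g = h5[name]
                for ds in ("values", "frame_times", "roi_pixels"):
                    if ds not in g:
                        raise SchemaError(f"traces.h5:/{name} missing dataset {ds}")
                fluorescence[name] = FluorescenceSet(
                    values=g["values"][()],
                    frame_times=g["frame_times"][()],
                    roi_pixels=g["roi_pixels"][()],
                    channel=str(g.attrs.get("channel", name)),
                    kind=str(g.attrs.get("kind", "raw_F")),
                )

    session = SessionRecord(trials=trials, licks=licks,
                            fluorescence=fluorescence, stimuli=stimuli, pupil=pupil)
    if validate:
        violations = validate_session(session)
        if violations:
            raise SessionValidationError(violations)
    return session
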