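import numpy as np
import pandas as pd
import pytest

from axovis.session import TRIAL_COLUMNS, FluorescenceSet, SessionRecord


def make_trials(rows: list[dict]) -> pd.DataFrame:
    """Trial table from partial row dicts (sensible defaults filled in)."""
    out = []
    for r in rows:
        base = {"trial_id": len(out), "trial_type": "go", "side": "monocular",
                "contrast": 1.0, "response": "no_lick", "correct": False,
                "reward_time": np.nan, "airpuff_time": np.nan}
        base.update(r)
        if "stim_on" not in base:
            base["stim_on"] = base["tone_time"] + 1.0
        if "stim_off" not in base:
            base["stim_off"] = base["stim_on"] + 4.0
        out.append(base)
    return pd.DataFrame(out, columns=TRIAL_COLUMNS)


@pytest.fixture
def toy_session() -> SessionRecord:
    """Two-trial session (one rewarded go, one correct-rejection nogo)."""
    trials = make_trials([
        {"tone_time": 5.0, "trial_type": "go", "response": "lick",
         "correct": True, "reward_time": 8.2},
        {"tone_time": 15.0, "trial_type": "nogo", "correct": True},
    ])
    frame_times = np.arange(0, 25, 0.1)
    rng = np.random.default_rng(0)
    values = rng.normal(100.0, 1.0, size=(3, frame_times.size))
    fset = FluorescenceSet(values=values, frame_times=frame_times,
                           roi_pixels=np.array([10, 20, 30]),
                           channel="green", kind="raw_F")
    licks = np.array([8.2, 8.35, 8.5, 8.65])
    return SessionRecord(trials=trials, licks=licks,
                         fluorescence={"green": fset})


def assert_sessions_equal(a: SessionRecord, b: SessionRecord, rtol=1e-9):
    pd.testing.assert_frame_equal(
        a.trials.reset_index(drop=True), b.trials.reset_index(drop=True),
        check_dtype=False)
    np.testing.assert_allclose(a.licks, b.licks, rtol=rtol)
    assert set(a.fluorescence) == set(b.fluorescence)
    for name, fa in a.fluorescence.items():
        fb = b.fluorescence[name]
        np.testing.assert_allclose(fa.values, fb.values, rtol=rtol)
        np.testing.assert_allclose(fa.frame_times, fb.frame_times, rtol=rtol)
        np.testing.assert_array_equal(np.asarray(fa.roi_pixels, float),
                                      np.asarray(fb.roi_pixels, float))
        assert fa.kind == fb.kind and fa.channel == fb.channel
    if a.stimuli is None:
        assert b.stimuli is None or not len(b.stimuli)
    else:
        pd.testing.assert_frame_equal(a.stimuli.reset_index(drop=True),
                                      b.stimuli.reset_index(drop=True),
                                      check_dtype=False)
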