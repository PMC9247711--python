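"""Passive-stimulation tuning analysis.

Each neuron's response to a drifting-grating presentation is the mean ΔF/F
over the 1 s after stimulus onset.  Direction tuning is modeled as a sum of
two Gaussians with a shared width and a common offset, one peaking at the
empirically preferred direction and the other 180° away:

    R(θ) = offset + A1·exp(-Δ(θ, θp)²/2σ²) + A2·exp(-Δ(θ, θp+180°)²/2σ²)

with Δ the wrapped angular distance and A1, A2 >= 0.  From the fitted curve,
OSI = (R_pref - R_ortho)/(R_pref + R_ortho) and DSI = (R_pref_dir -
R_pref_dir+180°)/(R_pref_dir + R_pref_dir+180°).  Visual responsiveness is a
one-way ANOVA across stimulus conditions.  Trials can be split by the median
of the concurrent axon-population activity to ask whether tuning differs
between low- and high-modulator states (Kruskal-Wallis on the per-neuron
index sets, with an r² > 0.3 fit-quality gate in both halves).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

from .session import FluorescenceSet

log = logging.getLogger(__name__)


def build_response_table(dff_somas: FluorescenceSet, stimuli: pd.DataFrame,
                         window_s: float = 1.0) -> pd.DataFrame:
    """Long table of per-presentation responses (mean ΔF/F over 1 s post onset).

    Columns: neuron, presentation, direction, position, repeat, response.
    Presentations not fully covered by frames are dropped (logged).
    """
    rows = []
    rep_counter: dict[tuple[float, int], int] = {}
    for pi, stim in stimuli.iterrows():
        t0 = float(stim.onset)
        m = dff_somas.window_mean(t0, t0 + window_s)
        if np.any(np.isnan(m)):
            log.info("presentation %s dropped: no frame coverage", pi)
            continue
        key = (float(stim.direction), int(stim.position_index))
        rep = rep_counter.get(key, 0)
        rep_counter[key] = rep + 1
        for ni in range(dff_somas.n_rois):
            rows.append((ni, pi, key[0], key[1], rep, m[ni]))
    return pd.DataFrame(rows, columns=["neuron", "presentation", "direction",
                                       "position", "repeat", "response"])


def test_responsive(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """One-way ANOVA across stimulus conditions per neuron (p < alpha)."""
    out = []
    for ni, sub in table.groupby("neuron"):
        groups = [g["response"].to_numpy()
                  for _, g in sub.groupby(["direction", "position"])]
        if len(groups) < 2:
            raise ValueError(f"neuron {ni}: fewer than 2 stimulus conditions")
        degenerate = np.ptp(sub["response"].to_numpy()) == 0
        if degenerate:
            p = np.nan
        elif all(np.ptp(g) == 0 for g in groups):
            p = 0.0  # means differ with zero within-condition variance
        else:
            with np.errstate(all="ignore"):
                _, p = stats.f_oneway(*groups)
        out.append((ni, p, bool(p < alpha) if np.isfinite(p) else False,
                    degenerate))
    return pd.DataFrame(out, columns=["neuron", "p_value", "responsive",
                                      "degenerate"]).set_index("neuron")


@dataclass
class TuningFit:
    """Constrained double-Gaussian direction-tuning fit and derived indices."""

    pref_direction: float
    amp_pref: float
    amp_null: float
    sigma: float
    offset: float
    r_squared: float
    converged: bool
    osi: float = np.nan
    dsi: float = np.nan
    r_pref: float = np.nan
    r_ortho: float = np.nan
    r_pref_dir: float = np.nan
    r_null_dir: float = np.nan


def _wrap(delta):
    return (np.asarray(delta, float) + 180.0) % 360.0 - 180.0


def double_gaussian(theta, a1, a2, sigma, offset, pref):
    d1 = _wrap(theta - pref)
    d2 = _wrap(theta - pref - 180.0)
    return (offset + a1 * np.exp(-d1 ** 2 / (2 * sigma ** 2))
            + a2 * np.exp(-d2 ** 2 / (2 * sigma ** 2)))


def fit_tuning(table: pd.DataFrame, neuron: int,
               min_directions: int = 5) -> TuningFit:
    """Fit the constrained double Gaussian to one neuron's direction means.

    The position dimension is collapsed by keeping the neuron's best position
    (largest overall mean response); the preferred direction is fixed at the
    empirical argmax of the per-direction means.  Bounded nonlinear least
    squares (A1, A2 >= 0, shared sigma); indices are evaluated from the
    fitted curve (R_ortho at 90° from preference).
    """
    sub = table[table["neuron"] == neuron]
    if not len(sub):
        raise ValueError(f"neuron {neuron} not in table")
    by_pos = sub.groupby("position")["response"].mean()
    best_pos = by_pos.idxmax()
    sub = sub[sub["position"] == best_pos]
    means = sub.groupby("direction")["response"].mean()
    if len(means) < min_directions:
        raise ValueError(f"neuron {neuron}: only {len(means)} directions")
    theta = means.index.to_numpy(float)
    y = means.to_numpy(float)
    pref = float(theta[np.argmax(y)])

    y_min, y_max = float(y.min()), float(y.max())
    opp_idx = int(np.argmin(np.abs(_wrap(theta - pref - 180.0))))
    p0 = [max(y_max - y_min, 1e-6), max(y[opp_idx] - y_min, 1e-6), 30.0, y_min]
    try:
        popt, _ = curve_fit(
            lambda th, a1, a2, s, off: double_gaussian(th, a1, a2, s, off, pref),
            theta, y, p0=p0,
            bounds=([0.0, 0.0, 1.0, -np.inf], [np.inf, np.inf, 180.0, np.inf]),
            maxfev=20000)
    except RuntimeError:
        return TuningFit(pref_direction=pref, amp_pref=np.nan, amp_null=np.nan,
                         sigma=np.nan, offset=np.nan, r_squared=np.nan,
                         converged=False)
    a1, a2, sigma, offset = (float(v) for v in popt)
    yhat = double_gaussian(theta, a1, a2, sigma, offset, pref)
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0

    r_pref = float(double_gaussian(pref, a1, a2, sigma, offset, pref))
    r_ortho = float(double_gaussian(pref + 90.0, a1, a2, sigma, offset, pref))
    r_null = float(double_gaussian(pref + 180.0, a1, a2, sigma, offset, pref))
    with np.errstate(all="ignore"):
        osi = (r_pref - r_ortho) / (r_pref + r_ortho)
        dsi = (r_pref - r_null) / (r_pref + r_null)
    return TuningFit(pref_direction=pref, amp_pref=a1, amp_null=a2,
                     sigma=sigma, offset=offset, r_squared=r2, converged=True,
                     osi=float(osi), dsi=float(dsi), r_pref=r_pref,
                     r_ortho=r_ortho, r_pref_dir=r_pref, r_null_dir=r_null)


def fit_all(table: pd.DataFrame, **kw) -> pd.DataFrame:
    rows = {}
    for ni in sorted(table["neuron"].unique()):
        rows[ni] = vars(fit_tuning(table, ni, **kw))
    return pd.DataFrame.from_dict(rows, orient="index")


def axon_population_per_presentation(axons: FluorescenceSet,
                                     stimuli: pd.DataFrame,
                                     window_s: float = 1.0) -> np.ndarray:
    """Mean axon-population ΔF/F during each stimulus presentation."""
    pop = axons.values.mean(axis=0)
    pop_set = FluorescenceSet(values=pop[None, :], frame_times=axons.frame_times,
                              roi_pixels=np.array([1]), channel=axons.channel,
                              kind="dff")
    return np.array([float(pop_set.window_mean(t, t + window_s)[0])
                     for t in stimuli["onset"].to_numpy(float)])


@dataclass
class ActivitySplit:
    """Median split of presentations by concurrent axon-population activity."""

    high: np.ndarray            # boolean per presentation
    fits_low: pd.DataFrame
    fits_high: pd.DataFrame
    retained: np.ndarray        # neuron ids passing responsiveness + r² gates
    osi_kw_stat: float
    osi_kw_p: float
    dsi_kw_stat: float
    dsi_kw_p: float
    delta_pref: pd.Series = field(default=None)


def split_and_compare(table: pd.DataFrame, axon_pop: np.ndarray,
                      r2_gate: float = 0.3, alpha: float = 0.05,
                      ) -> ActivitySplit:
    """Compare tuning between low- and high-modulator halves of the trials.

    Presentations are median-split by ``axon_pop`` (deterministic argsort
    split; half sizes differ by at most one).  Neurons are retained when
    visually responsive and both half fits converge with r² above the gate;
    the retained OSI (and DSI) sets are compared with a Kruskal-Wallis test.
    """
    pres = np.sort(table["presentation"].unique())
    axon_pop = np.asarray(axon_pop, dtype=float)
    if axon_pop.size != pres.size:
        raise ValueError("axon_pop must have one value per presentation")
    order = np.argsort(axon_pop, kind="stable")
    high = np.zeros(pres.size, dtype=bool)
    high[order[pres.size // 2:]] = True
    high_map = dict(zip(pres, high))
    is_high = table["presentation"].map(high_map).to_numpy(bool)

    responsive = test_responsive(table, alpha=alpha)
    fits_low = fit_all(table[~is_high])
    fits_high = fit_all(table[is_high])

    retained = []
    for ni in fits_low.index:
        ok = (bool(responsive.loc[ni, "responsive"])
              and fits_low.loc[ni, "converged"] and fits_high.loc[ni, "converged"]
              and fits_low.loc[ni, "r_squared"] > r2_gate
              and fits_high.loc[ni, "r_squared"] > r2_gate)
        if not ok:
            log.info("neuron %s dropped from split comparison", ni)
            continue
        retained.append(ni)
    retained = np.array(retained)
    if retained.size < 2:
        raise ValueError("fewer than 2 neurons retained for the comparison")
    osi_s, osi_p = stats.kruskal(fits_high.loc[retained, "osi"],
                                 fits_low.loc[retained, "osi"])
    dsi_s, dsi_p = stats.kruskal(fits_high.loc[retained, "dsi"],
                                 fits_low.loc[retained, "dsi"])
    delta = pd.Series(
        _wrap(fits_high.loc[retained, "pref_direction"].to_numpy()
              - fits_low.loc[retained, "pref_direction"].to_numpy()),
        index=retained, name="delta_pref")
    return ActivitySplit(high=high, fits_low=fits_low, fits_high=fits_high,
                         retained=retained, osi_kw_stat=float(osi_s),
                         osi_kw_p=float(osi_p), dsi_kw_stat=float(dsi_s),
                         dsi_kw_p=float(dsi_p), delta_pref=delta)
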