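"""Raw-fluorescence preprocessing.

ΔF/F conversion uses a sliding-percentile baseline: the raw trace is lightly
smoothed (1 s boxcar by default), the 5th percentile of the smoothed trace is
taken within a 20 s window centered on each sample (truncated at the session
edges), and ΔF/F = (F - F0) / F0.  Correlated boutons (Pearson r > 0.7) are
treated as belonging to the same axon and merged by a pixel-count-weighted
average; group membership is the transitive closure of the pairwise relation.
Dual-channel bleed-through is quantified by regressing each green ROI trace on
its red counterpart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .session import FluorescenceSet


def _boxcar_smooth(x: np.ndarray, n: int) -> np.ndarray:
    """Centered boxcar mean of ``n`` samples, truncated at the edges."""
    if n <= 1:
        return x.astype(float, copy=True)
    half = n // 2
    csum = np.concatenate([[0.0], np.cumsum(x, dtype=float)])
    idx = np.arange(x.size)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, x.size)
    return (csum[hi] - csum[lo]) / (hi - lo)


def sliding_percentile(x: np.ndarray, window: int, q: float) -> np.ndarray:
    """Percentile of a centered, edge-truncated window around each sample.

    The window covers samples ``[i - window//2, i + window//2]`` clipped to
    the trace; percentiles use numpy's linear interpolation.
    """
    n = x.size
    half = window // 2
    w = 2 * half + 1
    out = np.empty(n)
    if n >= w:
        interior = np.percentile(sliding_window_view(x, w), q, axis=1)
        out[half:n - half] = interior
    for i in range(min(half, n)):
        out[i] = np.percentile(x[:i + half + 1], q)
    for i in range(max(n - half, 0), n):
        out[i] = np.percentile(x[max(i - half, 0):], q)
    return out


def compute_dff(f: FluorescenceSet, window_s: float = 20.0,
                percentile: float = 5.0, smooth_s: float = 1.0,
                floor_frac: float = 1e-3,
                ) -> tuple[FluorescenceSet, np.ndarray]:
    """Convert raw fluorescence to ΔF/F with a sliding-percentile baseline.

    Returns the converted set and a boolean flag per ROI marking traces whose
    baseline hit the positivity floor (``floor_frac`` x trace median), where
    the division would otherwise blow up.
    """
    if f.kind != "raw_F":
        raise ValueError("compute_dff expects a raw_F FluorescenceSet")
    dt = f.dt
    if f.frame_times[-1] - f.frame_times[0] <= window_s:
        raise ValueError("session shorter than the baseline window")
    if not np.all(np.isfinite(f.values)):
        bad = np.nonzero(~np.isfinite(f.values).all(axis=1))[0]
        raise ValueError(f"non-finite fluorescence in ROI(s) {bad.tolist()}")
    win = max(1, int(round(window_s / dt)))
    smooth_n = max(1, int(round(smooth_s / dt)))
    out = np.empty_like(f.values, dtype=float)
    flagged = np.zeros(f.n_rois, dtype=bool)
    for i in range(f.n_rois):
        row = f.values[i]
        f0 = sliding_percentile(_boxcar_smooth(row, smooth_n), win, percentile)
        floor = floor_frac * np.median(row)
        if floor > 0 and np.any(f0 < floor):
            f0 = np.maximum(f0, floor)
            flagged[i] = True
        out[i] = (row - f0) / f0
    return f.copy_with(values=out, kind="dff"), flagged


@dataclass
class MergeMap:
    """Partition of ROI indices into putative axons (with averaging weights)."""

    groups: list[list[int]]
    weights: list[list[float]]
    zero_variance: list[int] = field(default_factory=list)

    @property
    def n_groups(self) -> int:
        return len(self.groups)


def merge_boutons(dff: FluorescenceSet, threshold: float = 0.7,
                  ) -> tuple[FluorescenceSet, MergeMap]:
    """Merge boutons whose traces correlate above ``threshold`` (strict >).

    Groups are connected components of the thresholded correlation graph;
    each group is replaced by the pixel-weighted average of its members.
    Zero-variance ROIs have undefined correlations and stay singletons.
    """
    n = dff.n_rois
    if n < 1:
        raise ValueError("need at least one ROI")
    if not np.all(np.isfinite(dff.values)):
        raise ValueError("non-finite traces")
    sd = dff.values.std(axis=1)
    zero_var = np.nonzero(sd == 0)[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # corrcoef warns on zero variance
        corr = np.corrcoef(dff.values) if n > 1 else np.ones((1, 1))
    adj = np.nan_to_num(corr, nan=0.0) > threshold
    adj[zero_var, :] = False
    adj[:, zero_var] = False
    np.fill_diagonal(adj, True)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)

    groups = [sorted(np.nonzero(labels == c)[0].tolist()) for c in range(n_comp)]
    groups.sort(key=lambda g: g[0])
    pix = np.asarray(dff.roi_pixels, dtype=float)
    merged = np.empty((len(groups), dff.n_frames))
    new_pix = np.empty(len(groups))
    weights = []
    for gi, g in enumerate(groups):
        w = pix[g]
        merged[gi] = (dff.values[g] * w[:, None]).sum(axis=0) / w.sum()
        new_pix[gi] = w.sum()
        weights.append(w.tolist())
    out = dff.copy_with(values=merged, roi_pixels=new_pix)
    return out, MergeMap(groups=groups, weights=weights,
                         zero_variance=zero_var.tolist())


@dataclass
class BleedthroughReport:
    """Per-ROI green-on-red regression and its population summary."""

    slope: np.ndarray
    r_squared: np.ndarray
    frac_positive_slope: float
    mean_r_squared: float
    excluded: list[int] = field(default_factory=list)


def bleedthrough_qc(green: FluorescenceSet, red: FluorescenceSet,
                    ) -> BleedthroughReport:
    """OLS of each green ROI trace on the matching red ROI trace."""
    if green.values.shape != red.values.shape:
        raise ValueError("green and red sets must have matched ROIs and frames")
    g = green.values - green.values.mean(axis=1, keepdims=True)
    r = red.values - red.values.mean(axis=1, keepdims=True)
    ss_r = (r ** 2).sum(axis=1)
    ss_g = (g ** 2).sum(axis=1)
    excluded = np.nonzero(ss_r == 0)[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (g * r).sum(axis=1) / ss_r
        r2 = np.where(ss_g > 0, (g * r).sum(axis=1) ** 2 / (ss_r * ss_g), 0.0)
    slope[excluded] = np.nan
    r2[excluded] = np.nan
    ok = np.setdiff1d(np.arange(green.n_rois), excluded)
    return BleedthroughReport(
        slope=slope, r_squared=r2,
        frac_positive_slope=float(np.mean(slope[ok] > 0)) if ok.size else np.nan,
        mean_r_squared=float(np.mean(r2[ok])) if ok.size else np.nan,
        excluded=excluded.tolist(),
    )
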