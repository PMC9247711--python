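"""Pupil landmark post-processing.

A landmark detector places 12 points per video frame: the superior, inferior,
medial and lateral corners of the eye, and eight points in an octagon around
the pupil.  The detector always places all eight pupil markers, even during a
blink, so the markers are validated geometrically: a pair of parabolic curves
through (medial, superior, lateral) and (medial, inferior, lateral) defines
the eye shape, any pupil marker outside that shape is discarded, and an
ellipse is least-squares-fitted only when six or more markers remain.  The
parabola abscissa is the medial-to-lateral eye axis (a rotated frame), so the
construction is well-posed for tilted eyes.  The "diameter" is the fitted
major-axis length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import EllipseModel

from .session import ALL_MARKERS, EYE_MARKERS


@dataclass
class EyeContour:
    """Two parabolas in the medial->lateral axis frame bounding the eye."""

    origin: np.ndarray        # medial corner
    axis: np.ndarray          # unit vector medial -> lateral
    length: float             # chord length
    a_upper: float            # h = a * s * (s - length), superior side
    a_lower: float
    upper_sign: float         # sign of h on the superior side
    valid: bool = True
    reason: str = ""

    def to_local(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Project image points to (s, h): along-chord and off-chord coords."""
        points = np.atleast_2d(points).astype(float)
        rel = points - self.origin
        s = rel @ self.axis
        perp = np.array([-self.axis[1], self.axis[0]])
        h = rel @ perp
        return s, h

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Strict interior test (boundary counts as outside)."""
        if not self.valid:
            return np.zeros(len(np.atleast_2d(points)), dtype=bool)
        s, h = self.to_local(points)
        curve_up = self.a_upper * s * (s - self.length)
        curve_lo = self.a_lower * s * (s - self.length)
        lo = np.minimum(curve_up, curve_lo)
        hi = np.maximum(curve_up, curve_lo)
        return (s > 0) & (s < self.length) & (h > lo) & (h < hi)


def eye_contour(eye_markers: dict[str, tuple[float, float]]) -> EyeContour:
    """Build the eyelid contour from the four labeled eye-corner markers.

    Sanity checks follow the validation rules for automatic landmarking: the
    medial marker must be medial (smaller image x) of the lateral one, both
    lid apices must fall strictly between the corners and on opposite sides
    of the medial-lateral chord.  A violated check invalidates the frame (the
    caller then discards all pupil markers).
    """
    med = np.asarray(eye_markers["eye_medial"], float)
    lat = np.asarray(eye_markers["eye_lateral"], float)
    sup = np.asarray(eye_markers["eye_superior"], float)
    inf = np.asarray(eye_markers["eye_inferior"], float)

    def invalid(reason: str) -> EyeContour:
        return EyeContour(origin=med, axis=np.array([1.0, 0.0]), length=0.0,
                          a_upper=0.0, a_lower=0.0, upper_sign=1.0,
                          valid=False, reason=reason)

    if not np.all(np.isfinite(np.concatenate([med, lat, sup, inf]))):
        return invalid("non-finite eye marker")
    if med[0] >= lat[0]:
        return invalid("medial eye marker is lateral to the lateral eye marker")
    chord = lat - med
    length = float(np.linalg.norm(chord))
    if length == 0:
        return invalid("medial and lateral markers coincide")
    axis = chord / length
    contour = EyeContour(origin=med, axis=axis, length=length,
                         a_upper=0.0, a_lower=0.0, upper_sign=1.0)
    (s_sup, s_inf), (h_sup, h_inf) = contour.to_local(np.stack([sup, inf]))
    if not (0 < s_sup < length and 0 < s_inf < length):
        return invalid("lid apex outside the medial-lateral span")
    if h_sup == 0 or h_inf == 0:
        return invalid("degenerate contour: lid apex on the chord")
    if np.sign(h_sup) == np.sign(h_inf):
        return invalid("superior and inferior apices on the same side of the chord")
    contour.a_upper = float(h_sup / (s_sup * (s_sup - length)))
    contour.a_lower = float(h_inf / (s_inf * (s_inf - length)))
    contour.upper_sign = float(np.sign(h_sup))
    return contour


def validate_markers(pupil_markers: np.ndarray, contour: EyeContour,
                     input_valid: np.ndarray | None = None) -> np.ndarray:
    """Boolean mask of pupil markers strictly inside the eye contour."""
    pupil_markers = np.atleast_2d(pupil_markers).astype(float)
    ok = np.all(np.isfinite(pupil_markers), axis=1)
    if input_valid is not None:
        ok &= np.asarray(input_valid, dtype=bool)
    ok &= contour.contains(pupil_markers)
    return ok


@dataclass
class PupilEllipse:
    """Least-squares ellipse through the valid pupil markers."""

    center: np.ndarray
    semi_axes: np.ndarray     # (major, minor)
    rotation: float           # degrees, major-axis angle
    diameter: float           # major-axis length
    n_valid_markers: int
    valid: bool
    reason: str = ""


def fit_pupil_ellipse(valid_markers: np.ndarray) -> PupilEllipse:
    """Algebraic least-squares ellipse fit; abstains below 6 markers."""
    pts = np.atleast_2d(np.asarray(valid_markers, dtype=float))
    n = len(pts)

    def abstain(reason: str) -> PupilEllipse:
        return PupilEllipse(center=np.full(2, np.nan),
                            semi_axes=np.full(2, np.nan), rotation=np.nan,
                            diameter=np.nan, n_valid_markers=n, valid=False,
                            reason=reason)

    if n < 6:
        return abstain("fewer than 6 valid pupil markers")
    model = EllipseModel.from_estimate(pts)
    if not model:
        return abstain("degenerate marker configuration")
    (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    if not np.all(np.isfinite([xc, yc, a, b, theta])) or a <= 0 or b <= 0:
        return abstain("degenerate ellipse")
    if a >= b:
        major, minor, rot = a, b, np.rad2deg(theta)
    else:
        major, minor, rot = b, a, np.rad2deg(theta) + 90.0
    rot = ((rot + 90.0) % 180.0) - 90.0
    return PupilEllipse(center=np.array([xc, yc]),
                        semi_axes=np.array([major, minor]),
                        rotation=float(rot), diameter=float(2 * major),
                        n_valid_markers=n, valid=True)


def _frame_markers(row: pd.Series) -> tuple[dict, np.ndarray, np.ndarray]:
    eye = {m: (row[f"{m}_x"], row[f"{m}_y"]) for m in EYE_MARKERS}
    pup = np.array([[row[f"pupil_{i}_x"], row[f"pupil_{i}_y"]]
                    for i in range(1, 9)], dtype=float)
    flags = np.array([bool(row.get(f"pupil_{i}_valid", True))
                      for i in range(1, 9)])
    return eye, pup, flags


def pupil_timeseries(frames: pd.DataFrame) -> pd.DataFrame:
    """Per-frame pupil diameter and eye-movement velocity.

    Returns a table with ``frame_time, diameter, center_x, center_y,
    n_valid, valid, velocity``.  Velocity is the frame-to-frame displacement
    of the ellipse center divided by the time step; it is missing whenever
    either bounding frame lacks a valid fit.
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    missing = [c for c in ["frame_time"]
               + [f"{m}_{ax}" for m in ALL_MARKERS for ax in "xy"]
               if c not in frames.columns]
    if missing:
        raise ValueError(f"pupil table missing columns {missing}")

    rows = []
    for _, row in frames.iterrows():
        eye, pup, flags = _frame_markers(row)
        contour = eye_contour(eye)
        if contour.valid:
            ok = validate_markers(pup, contour, flags)
            fit = fit_pupil_ellipse(pup[ok])
        else:
            fit = PupilEllipse(center=np.full(2, np.nan),
                               semi_axes=np.full(2, np.nan), rotation=np.nan,
                               diameter=np.nan, n_valid_markers=0,
                               valid=False, reason=contour.reason)
        rows.append({
            "frame_time": row["frame_time"], "diameter": fit.diameter,
            "center_x": fit.center[0], "center_y": fit.center[1],
            "n_valid": fit.n_valid_markers, "valid": fit.valid,
        })
    out = pd.DataFrame(rows)
    vel = np.full(len(out), np.nan)
    cx, cy = out["center_x"].to_numpy(), out["center_y"].to_numpy()
    t = out["frame_time"].to_numpy(float)
    ok = out["valid"].to_numpy(bool)
    for i in range(1, len(out)):
        if ok[i] and ok[i - 1] and t[i] > t[i - 1]:
            vel[i] = np.hypot(cx[i] - cx[i - 1], cy[i] - cy[i - 1]) / (t[i] - t[i - 1])
    out["velocity"] = vel
    if not ok.any():
        warnings.warn("all frames invalid: empty pupil series")
    return out
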