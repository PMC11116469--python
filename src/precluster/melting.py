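"""Apparent melting temperatures from intrinsic-fluorescence ratio
(F350/F330) thermal ramps.

The apparent melting temperature T_m,app is the inflection point of the
sigmoidal transition, located as the extremum of largest magnitude of the
first derivative of the ratio with respect to temperature (a maximum for
increasing transitions, a minimum for decreasing ones), with optional
polynomial smoothing and parabolic sub-grid refinement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .containers import MeltingCurve

__all__ = ["TmResult", "apparent_tm", "replicate_tm"]


@dataclass
class TmResult:
    tm_C: float | None
    derivative: np.ndarray  # dR/dT on the temperature grid (smoothed input)
    raw_derivative: np.ndarray  # derivative of the unsmoothed ratio
    flags: list[str]


def apparent_tm(curve: MeltingCurve, smoothing_window: int = 5, polyorder: int = 2) -> TmResult:
    """Apparent melting temperature from the first-derivative extremum.

    ``smoothing_window`` (points, odd, >= polyorder + 1) controls a
    Savitzky-Golay smoother applied before differentiation; pass 0 or 1 to
    disable. A flat curve (no transition) yields ``tm_C=None`` with the
    ``"no-transition"`` flag.
    """
    temp, ratio = curve.temperature, curve.ratio
    raw_deriv = np.gradient(ratio, temp)

    if smoothing_window and smoothing_window > 1:
        window = min(smoothing_window | 1, ratio.size if ratio.size % 2 else ratio.size - 1)
        window = max(window, polyorder + 1 + ((polyorder + 1) % 2 == 0))
        smooth = savgol_filter(ratio, window, polyorder)
    else:
        smooth = ratio
    deriv = np.gradient(smooth, temp)

    scale = max(np.ptp(ratio), np.abs(ratio).max(), 1e-300)
    span = temp[-1] - temp[0]
    if np.ptp(ratio) < 1e-10 * scale or np.abs(deriv).max() * span < 1e-10 * scale:
        return TmResult(tm_C=None, derivative=deriv, raw_derivative=raw_deriv, flags=["no-transition"])

    # locate the transition on a more heavily smoothed derivative (the
    # locator only picks the peak region, not the reported value)
    loc_window = max(smoothing_window or 0, min(21, (temp.size // 2) * 2 - 1)) | 1
    locator = savgol_filter(deriv, loc_window, polyorder) if temp.size > loc_window > 2 else deriv
    k = int(np.argmax(np.abs(locator)))
    sign = np.sign(locator[k]) or 1.0
    d = deriv * sign
    d_loc = locator * sign

    flags: list[str] = []
    tm = float(temp[k])
    if k in (0, temp.size - 1):
        flags.append("extremum-at-edge")
        return TmResult(tm_C=tm, derivative=deriv, raw_derivative=raw_deriv, flags=flags)

    # sub-grid refinement: intensity-weighted centroid of the contiguous
    # derivative-peak region above 30% of the extremum. For a symmetric
    # transition the centroid is unbiased and averages point noise; it
    # reduces to the 3-point parabola when the region is narrow.
    thr = 0.3 * d_loc[k]
    i0 = k
    while i0 > 0 and d_loc[i0 - 1] >= thr:
        i0 -= 1
    i1 = k
    while i1 < d_loc.size - 1 and d_loc[i1 + 1] >= thr:
        i1 += 1
    tt, dd = temp[i0 : i1 + 1], d[i0 : i1 + 1] - thr
    if tt.size >= 3 and dd.sum() > 0:
        tm = float((tt * dd).sum() / dd.sum())
    else:
        y0, y1, y2 = d[k - 1], d[k], d[k + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom != 0:
            shift = float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))
            tm = float(temp[k] + shift * 0.5 * (temp[k + 1] - temp[k - 1]))
    return TmResult(tm_C=tm, derivative=deriv, raw_derivative=raw_deriv, flags=flags)


def replicate_tm(curves: list[MeltingCurve], smoothing_window: int = 5) -> tuple[float, float, list[float]]:
    """Mean and standard deviation of T_m,app over replicate ramps."""
    tms = []
    for c in curves:
        res = apparent_tm(c, smoothing_window)
        if res.tm_C is None:
            raise ValueError(f"replicate {c.replicate!r}: no transition found")
        tms.append(res.tm_C)
    arr = np.array(tms)
    return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0, tms
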