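"""Peak detection, integration and chromatographic statistics for MRM traces.

Statistics follow the conventions of chromatographic method development:

* resolution  R_s = 2 (t_R2 - t_R1) / (w_B1 + w_B2)  from retention times and
  baseline peak widths;
* tailing factor  T = w_x / (2 f)  where w_x is the peak width at 5% of the
  peak height and f the distance between the peak maximum and the leading
  edge at that level;
* signal-to-noise as peak height over the robust baseline noise.

The baseline peak width is operationalised as the width at the crossing of
max(3 x noise, 0.5% of peak height) on the baseline-subtracted signal;
tangent constructions are deliberately avoided for robustness on noisy
traces.  All level crossings are located by linear interpolation between
samples.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .chromatogram import Chromatogram
from .panel import Panel, TransitionDef


class TraceError(ValueError):
    """Trace unusable for peak processing."""


@dataclass
class Peak:
    """A detected, baseline-corrected chromatographic peak."""

    apex_rt: float          # minutes
    area: float             # counts x min, baseline-subtracted
    height: float           # counts above baseline
    baseline_level: float   # counts
    noise_sd: float         # counts
    w_base: float           # minutes, width at the baseline-crossing level
    w_5pct: float           # minutes, width at 5% of height
    front_5pct: float       # minutes, apex minus leading edge at 5% height
    snr: float
    transition: TransitionDef | None = None


def estimate_baseline(trace: Chromatogram, exclude_rt: float,
                      exclude_halfwidth: float = 0.25) -> tuple[float, float]:
    """Robust baseline level and noise from samples outside the peak region.

    Returns ``(median, 1.4826 x MAD)`` of the intensities with
    ``|t - exclude_rt| <= exclude_halfwidth`` masked out.
    """
    mask = np.abs(trace.times - exclude_rt) > exclude_halfwidth
    if mask.sum() < 10:
        raise TraceError("exclusion zone leaves fewer than 10 baseline samples")
    x = trace.intensities[mask]
    level = float(np.median(x))
    noise = float(1.4826 * np.median(np.abs(x - level)))
    return level, noise


def _cross_left(t, y, i, level):
    """Interpolated time where y crosses ``level`` between samples i-1 and i."""
    if y[i - 1] == y[i]:
        return float(t[i - 1])
    frac = (y[i] - level) / (y[i] - y[i - 1])
    return float(t[i] - frac * (t[i] - t[i - 1]))


def _cross_right(t, y, i, level):
    if y[i + 1] == y[i]:
        return float(t[i + 1])
    frac = (y[i] - level) / (y[i] - y[i + 1])
    return float(t[i] + frac * (t[i + 1] - t[i]))


def _bounds(t, y, apex: int, thr: float, height: float):
    """Integration bounds: walk from the apex until the signal drops below
    ``thr`` (interpolated crossing) or a valley starts rising again."""
    j = apex
    left_t, left_edge = float(t[0]), 0
    while j > 0:
        if y[j - 1] < thr:
            left_t, left_edge = _cross_left(t, y, j, thr), j
            break
        if y[j - 1] > y[j] and y[j] <= 0.5 * height:
            left_t, left_edge = float(t[j]), j  # valley between partly resolved peaks
            break
        j -= 1
    j = apex
    right_t, right_edge = float(t[-1]), len(t) - 1
    while j < len(t) - 1:
        if y[j + 1] < thr:
            right_t, right_edge = _cross_right(t, y, j, thr), j
            break
        if y[j + 1] > y[j] and y[j] <= 0.5 * height:
            right_t, right_edge = float(t[j]), j
            break
        j += 1
    return left_t, left_edge, right_t, right_edge


def _width_at(t, y, apex: int, level: float):
    """Left/right interpolated crossings of ``level`` nearest the apex."""
    j = apex
    left = None
    while j > 0:
        if y[j - 1] < level:
            left = _cross_left(t, y, j, level)
            break
        j -= 1
    j = apex
    right = None
    while j < len(t) - 1:
        if y[j + 1] < level:
            right = _cross_right(t, y, j, level)
            break
        j += 1
    return left, right


def detect_peak(trace: Chromatogram, expected_rt: float,
                search_halfwidth_s: float = 60.0, *,
                min_snr: float = 3.0) -> Peak | None:
    """Detect and integrate the peak nearest ``expected_rt``.

    The apex is the candidate local maximum (above the acceptance threshold
    ``min_snr x noise``) closest to the expected retention time -- co-eluting
    isomers sharing a transition are disambiguated by retention time alone.
    Returns ``None`` if nothing exceeds the threshold.
    """
    half = search_halfwidth_s / 60.0
    if not (trace.covers(expected_rt - half) and trace.covers(expected_rt + half)):
        # scheduled window narrower than the search span: search what we have
        if not trace.covers(expected_rt):
            raise TraceError("trace does not cover the expected retention time")
    baseline, noise = estimate_baseline(trace, expected_rt)
    t = trace.times
    net = trace.intensities - baseline
    thr_height = min_snr * noise if noise > 0 else 0.0
    in_window = np.abs(t - expected_rt) <= half

    # width >= 3 samples rejects single-sample noise excursions that clear
    # the 3 sigma height gate by chance; real peaks span >= 20 samples
    idx, _ = find_peaks(np.where(in_window, net, -np.inf),
                        height=max(thr_height, 1e-12),
                        prominence=max(thr_height, 1e-12),
                        width=3)
    if len(idx) == 0:
        return None
    apex = int(idx[np.argmin(np.abs(t[idx] - expected_rt))])
    height = float(net[apex])
    if noise > 0 and height < min_snr * noise:
        return None

    # apex refinement: 3-point parabola through the top samples
    apex_rt = float(t[apex])
    if 0 < apex < len(t) - 1:
        y0, y1, y2 = net[apex - 1], net[apex], net[apex + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            apex_rt += 0.5 * (y0 - y2) / denom * trace.dt

    thr = max(3.0 * noise, 0.005 * height)
    left_t, le, right_t, re = _bounds(t, net, apex, thr, height)
    seg_t = np.concatenate(([left_t], t[le:re + 1], [right_t]))
    seg_y = np.concatenate(([thr], net[le:re + 1], [thr]))
    area = float(np.trapezoid(seg_y, seg_t))

    lvl5 = 0.05 * height
    left5, right5 = _width_at(t, net, apex, lvl5)
    if left5 is None or right5 is None:
        return None  # peak not resolved down to 5% within the window
    w_5pct = right5 - left5
    front = apex_rt - left5
    snr = height / noise if noise > 0 else math.inf
    return Peak(apex_rt=apex_rt, area=area, height=height,
                baseline_level=baseline, noise_sd=noise,
                w_base=right_t - left_t, w_5pct=w_5pct, front_5pct=front,
                snr=snr, transition=trace.transition)


def integrate_window(trace: Chromatogram, rt: float,
                     halfwidth: float = 0.15) -> float:
    """Forced integration: baseline-subtracted area over ``rt +- halfwidth``.

    No detection threshold and no clipping, so blank traces yield zero-mean
    areas -- this is what low-level calibration regressions (detection-limit
    series) must consume, since the decision limit lies below any sensible
    peak-acceptance threshold.
    """
    baseline, _ = estimate_baseline(trace, rt, exclude_halfwidth=halfwidth + 0.05)
    mask = np.abs(trace.times - rt) <= halfwidth
    if mask.sum() < 3:
        raise TraceError("integration window contains fewer than 3 samples")
    return float(np.trapezoid(trace.intensities[mask] - baseline,
                              trace.times[mask]))


def resolution(p1: Peak, p2: Peak) -> float:
    """Chromatographic resolution of two peaks; symmetric in argument order."""
    if p1.w_base + p2.w_base <= 0:
        raise ValueError("zero total baseline width")
    a, b = sorted((p1, p2), key=lambda p: p.apex_rt)
    return 2.0 * (b.apex_rt - a.apex_rt) / (a.w_base + b.w_base)


def tailing_factor(p: Peak) -> float:
    """Peak asymmetry T = w_5pct / (2 x front_5pct); 1.0 for symmetric peaks."""
    if not p.front_5pct > 0:
        raise ValueError("degenerate peak front distance")
    return p.w_5pct / (2.0 * p.front_5pct)


def signal_to_noise(p: Peak) -> float:
    """Peak height over baseline noise; +inf when the trace is noiseless."""
    if p.noise_sd == 0:
        return math.inf if p.height > 0 else 0.0
    return p.height / p.noise_sd


PEAK_TABLE_COLUMNS = ["injection_id", "analyte_id", "role", "apex_rt", "area",
                      "height", "w_base", "w_5pct", "front_5pct", "snr"]


def measure_batch(batch, panel: Panel, *, min_snr: float = 3.0) -> pd.DataFrame:
    """Detection-based peak table over a whole batch (one row per transition).

    Transitions with no accepted peak yield NaN measurement columns.
    """
    rows = []
    for inj in batch.injections:
        for (aid, role), trace in inj.traces.items():
            p = detect_peak(trace, panel.expected_rt(aid), min_snr=min_snr)
            row = {"injection_id": inj.injection_id, "analyte_id": aid,
                   "role": role}
            if p is None:
                row.update({c: np.nan for c in PEAK_TABLE_COLUMNS[3:]})
            else:
                row.update({"apex_rt": p.apex_rt, "area": p.area,
                            "height": p.height, "w_base": p.w_base,
                            "w_5pct": p.w_5pct, "front_5pct": p.front_5pct,
                            "snr": p.snr})
            rows.append(row)
    return pd.DataFrame(rows, columns=PEAK_TABLE_COLUMNS)


def measure_forced_areas(batch, panel: Panel, *,
                         halfwidth: float = 0.15) -> pd.DataFrame:
    """Forced-window areas over a batch, for calibration-type regressions."""
    rows = []
    for inj in batch.injections:
        for (aid, role), trace in inj.traces.items():
            rows.append({"injection_id": inj.injection_id, "analyte_id": aid,
                         "role": role,
                         "area": integrate_window(trace, panel.expected_rt(aid),
                                                  halfwidth=halfwidth)})
    return pd.DataFrame(rows)
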