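"""Quantification of nystagmus slow-phase velocity from eye-position traces.

The experimental pipeline: detect slow phases by cutting the trace at quick
phases (velocity-threshold crossings) and blinks, fit a least-squares slope
to each surviving segment per component, collect the segment slopes into an
SPV series, summarize the peak response as the mean of the ten highest-|SPV|
points in a window, subtract the Earth-field baseline, apply the
field-direction sign rule (caudocephalic fields reverse the nystagmus), and
normalize for comparison with model output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .traces import EyeTrace

__all__ = [
    "DetectionThresholds",
    "SlowPhaseSegment",
    "PeakSPVSummary",
    "detect_slow_phases",
    "spv_series",
    "peak_spv",
    "baseline_correct",
    "apply_field_direction",
    "group_normalize",
    "model_deviation_percent",
]

COMPONENTS = ("hor", "ver", "tor")


@dataclass(frozen=True)
class DetectionThresholds:
    """Slow-phase segmentation parameters (standard video-nystagmography
    practice; the velocity threshold separates quick phases/saccades from the
    slow drift)."""

    velocity_deg_s: float = 30.0
    debounce_samples: int = 3
    min_duration_s: float = 0.1


@dataclass
class SlowPhaseSegment:
    start: int
    end: int                      # exclusive
    slopes: np.ndarray            # (3,) deg/s
    residual: float               # RMS position residual of the fits (deg)
    t_mid: float

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")


def detect_slow_phases(
    trace: EyeTrace, thresholds: DetectionThresholds = DetectionThresholds()
) -> list[SlowPhaseSegment]:
    """Split the trace at quick phases and blinks; fit slopes per segment."""
    n = len(trace)
    if n == 0:
        raise ValueError("empty trace")
    pos = trace.positions
    t = trace.t
    dt = t[1] - t[0] if n > 1 else 1.0

    vel = np.zeros_like(pos)
    if n > 2:
        vel[1:-1] = (pos[2:] - pos[:-2]) / (2 * dt)
    fast = np.abs(vel).max(axis=1) > thresholds.velocity_deg_s
    cut = fast | ~trace.valid
    # debounce: a cut only ends after `debounce_samples` consecutive quiet
    # samples, merging chattering threshold crossings into one artifact
    if thresholds.debounce_samples > 1 and cut.any():
        idx = np.flatnonzero(cut)
        gaps = np.flatnonzero(np.diff(idx) > 1)
        for g in gaps:
            a, b = idx[g], idx[g + 1]
            if b - a - 1 < thresholds.debounce_samples:
                cut[a:b] = True

    min_len = max(int(round(thresholds.min_duration_s / dt)), 2)
    segments = []
    start = None
    for i in range(n + 1):
        if i < n and not cut[i]:
            if start is None:
                start = i
            continue
        if start is not None and i - start >= min_len:
            sl = np.empty(3)
            res = 0.0
            tt = t[start:i] - t[start]
            for c in range(3):
                coef = np.polyfit(tt, pos[start:i, c], 1)
                sl[c] = coef[0]
                res += float(np.mean((np.polyval(coef, tt) - pos[start:i, c]) ** 2))
            segments.append(
                SlowPhaseSegment(
                    start=start,
                    end=i,
                    slopes=sl,
                    residual=float(np.sqrt(res / 3)),
                    t_mid=float(0.5 * (t[start] + t[i - 1])),
                )
            )
        start = None
    if not segments:
        import warnings

        warnings.warn("no slow phases detected in trace", stacklevel=2)
    return segments


def spv_series(segments: list[SlowPhaseSegment]):
    """(times, values): one SPV triple per slow phase, at the segment midpoint."""
    if not segments:
        raise ValueError("need at least one slow-phase segment")
    times = np.array([s.t_mid for s in segments])
    values = np.array([s.slopes for s in segments])
    return times, values


@dataclass
class PeakSPVSummary:
    """Mean of the ten highest-|SPV| points per component, with a half-range
    error bar derived from the max and min of those ten."""

    mean: np.ndarray              # (3,) deg/s, signed
    error: np.ndarray             # (3,) deg/s
    n_used: np.ndarray            # (3,) int
    insufficient: bool = False
    window_s: tuple | None = None


def peak_spv(times, values, window=None, n_peaks: int = 10) -> PeakSPVSummary:
    """Summarize the peak response within a time window.

    Selects the ``n_peaks`` largest-|value| SPV points per component, averages
    them (signed) and reports error = (max - min)/2 of the selected points.
    With fewer than ``n_peaks`` points, all are used and the summary is
    flagged insufficient.
    """
    times = np.asarray(times, float)
    values = np.atleast_2d(np.asarray(values, float))
    if window is not None:
        sel = (times >= window[0]) & (times <= window[1])
        if not sel.any():
            raise ValueError("no SPV points inside the requested window")
        values = values[sel]
    if len(values) == 0:
        raise ValueError("empty SPV series")
    mean = np.empty(3)
    err = np.empty(3)
    nu = np.empty(3, dtype=int)
    for c in range(3):
        col = values[:, c]
        k = min(n_peaks, len(col))
        top = col[np.argsort(-np.abs(col))[:k]]
        mean[c] = top.mean()
        err[c] = (top.max() - top.min()) / 2.0
        nu[c] = k
    return PeakSPVSummary(
        mean=mean,
        error=err,
        n_used=nu,
        insufficient=bool((nu < n_peaks).any()),
        window_s=tuple(window) if window is not None else None,
    )


def baseline_correct(peak: PeakSPVSummary, baseline: PeakSPVSummary) -> PeakSPVSummary:
    """Subtract the Earth-field baseline; errors propagate in quadrature."""
    return PeakSPVSummary(
        mean=peak.mean - baseline.mean,
        error=np.sqrt(peak.error**2 + baseline.error**2),
        n_used=peak.n_used.copy(),
        insufficient=peak.insufficient or baseline.insufficient,
        window_s=peak.window_s,
    )


def apply_field_direction(peak: PeakSPVSummary, B_axis_sign: str) -> PeakSPVSummary:
    """Sign rule for pooling recordings across scanners.

    A caudocephalic (feet_to_head) static field reverses the nystagmus, so
    those recordings are sign-inverted before being combined with
    head_to_feet data.
    """
    if B_axis_sign == "head_to_feet":
        return replace(peak, mean=peak.mean.copy(), error=peak.error.copy())
    if B_axis_sign == "feet_to_head":
        return replace(peak, mean=-peak.mean, error=peak.error.copy())
    raise ValueError(f"unknown B axis sign {B_axis_sign!r}")


def group_normalize(peaks: list[PeakSPVSummary]):
    """Group mean peak SPV across subjects, normalized per the comparison rule.

    Returns (normalized mean (3,), normalized propagated error (3,)).  The
    horizontal and torsional components are normalized by their own group
    peak |mean|; the vertical one by the horizontal peak.  Errors combine in
    quadrature over subjects and scale with the same factors.
    """
    if not peaks:
        raise ValueError("need at least one subject")
    means = np.array([p.mean for p in peaks])
    errs = np.array([p.error for p in peaks])
    gmean = means.mean(axis=0)
    gerr = np.sqrt(np.sum(errs**2, axis=0)) / len(peaks)
    hpk = np.abs(gmean[0])
    tpk = np.abs(gmean[2])
    scale = np.array(
        [1.0 / hpk if hpk > 0 else 0.0, 1.0 / hpk if hpk > 0 else 0.0, 1.0 / tpk if tpk > 0 else 0.0]
    )
    return gmean * scale, gerr * scale


def model_deviation_percent(model_norm, exp_norm) -> float:
    """Mean absolute difference of normalized SPV points, as a percentage."""
    model_norm = np.asarray(model_norm, float)
    exp_norm = np.asarray(exp_norm, float)
    return float(np.mean(np.abs(model_norm - exp_norm)) * 100.0)
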