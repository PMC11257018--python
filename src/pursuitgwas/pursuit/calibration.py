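"""Spatial calibration of the oculographic signal.

Each calibration block fixates a seven-point horizontal grid (±15, ±10,
±5, 0 degrees).  Gain and offset come from ordinary least squares of the
mean signal per fixation against the target values; calibrated position
is (signal - offset) / gain, applied to all data recorded after the
calibration until the next one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .trace import EyeTrace, RawCalibration

__all__ = ["CalibrationFit", "fit_calibration", "apply_calibration"]

MIN_ABS_GAIN = 1e-3
# central portion of each fixation used for the mean (settling margin)
FIXATION_TRIM_MS = (200, 950)


@dataclass
class CalibrationFit:
    target_positions_deg: np.ndarray
    mean_signal_per_target: np.ndarray
    fit_gain: float
    fit_offset: float
    r_squared: float
    before_trial: int = 0


def fit_calibration(segment: RawCalibration) -> CalibrationFit:
    """OLS of mean fixation signal on target position.

    Requires at least two distinct targets with valid samples; a fitted
    |gain| below 1e-3 is rejected as degenerate.
    """
    targets = np.unique(segment.target_deg)
    if len(targets) < 2:
        raise ValueError("calibration needs >= 2 distinct fixation targets")
    fs = 1000.0 / float(np.median(np.diff(segment.time_ms))) \
        if len(segment.time_ms) > 1 else 1000.0
    means = []
    for tgt in targets:
        idx = np.flatnonzero(segment.target_deg == tgt)
        # trim the first/last part of each contiguous fixation
        lo = idx[0] + int(FIXATION_TRIM_MS[0] * fs / 1000.0)
        hi = idx[0] + int(FIXATION_TRIM_MS[1] * fs / 1000.0)
        sel = idx[(idx >= lo) & (idx < hi)]
        if sel.size == 0:
            sel = idx
        means.append(float(np.mean(segment.signal[sel])))
    means = np.asarray(means)
    res = stats.linregress(targets, means)
    if abs(res.slope) < MIN_ABS_GAIN:
        raise ValueError(f"degenerate calibration: |gain| = {abs(res.slope):.2e}")
    return CalibrationFit(target_positions_deg=targets, mean_signal_per_target=means,
                          fit_gain=float(res.slope), fit_offset=float(res.intercept),
                          r_squared=float(res.rvalue**2),
                          before_trial=segment.before_trial)


def apply_calibration(trace: EyeTrace, fit: CalibrationFit) -> EyeTrace:
    """Calibrated position = (signal - offset) / gain."""
    pos = (trace.position_deg - fit.fit_offset) / fit.fit_gain
    return EyeTrace(time_ms=trace.time_ms, position_deg=pos, valid=trace.valid,
                    sample_rate_hz=trace.sample_rate_hz, calibrated=True)
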