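"""Session-level pursuit phenotypes: RMSE, gain, saccade rates.

RMSE uses the complete pursuit signal of each trial (saccades included)
excluding blink-masked samples; pursuit gain averages the ratio of eye
to target velocity over valid, non-saccadic samples away from direction
reversals (|target eccentricity| <= 10 degrees); saccade rates are total
class counts divided by total valid tracking time.  The session value of
RMSE and gain is by default the unweighted mean of per-trial values
across all trials at all speeds (a pooled-sample alternative exists for
RMSE).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from typing import TYPE_CHECKING

from .calibration import fit_calibration, apply_calibration, CalibrationFit
from .preprocess import detect_blinks, apply_blink_mask, velocity
from .saccades import Saccade, compute_saccade_threshold, detect_and_classify_saccades
from .trace import EyeTrace, RawCalibration, SessionTrial

if TYPE_CHECKING:  # pragma: no cover
    from ..sim.targets import TargetTrajectory

__all__ = ["SessionPhenotypes", "compute_rmse", "compute_gain", "summarize_session"]

GAIN_ECCENTRICITY_MAX_DEG = 10.0
MIN_VALID_FRACTION = 0.5  # trials with less valid data are dropped


@dataclass
class SessionPhenotypes:
    rmse_deg: float
    gain: float
    catchup_per_s: float
    anticipatory_per_s: float
    n_trials_used: int

    def __post_init__(self) -> None:
        if self.rmse_deg < 0 or self.catchup_per_s < 0 or self.anticipatory_per_s < 0:
            raise ValueError("rmse and rates must be nonnegative")


def compute_rmse(trace: EyeTrace, target: TargetTrajectory) -> float:
    """Root mean square eye-target error over valid samples, in degrees."""
    keep = trace.valid
    if not keep.any():
        raise ValueError("no valid samples in trial")
    err = trace.position_deg[keep] - target.position_deg[keep]
    return float(np.sqrt(np.mean(err**2)))


def _saccade_mask(n: int, fs: int, saccades: list[Saccade], pad_ms: float = 5.0) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    pad = int(pad_ms * fs / 1000.0)
    for sac in saccades:
        s = int(sac.onset_ms * fs / 1000.0) - pad
        e = int(sac.offset_ms * fs / 1000.0) + pad
        mask[max(0, s) : min(n, e)] = True
    return mask


def compute_gain(trace: EyeTrace, target: TargetTrajectory,
                 saccades: list[Saccade]) -> float:
    """Mean signed eye/target velocity ratio over retained samples.

    Retained: valid, outside saccades, target moving, |target| <= 10 deg.
    """
    fs = trace.sample_rate_hz
    eye_vel = velocity(trace.position_deg, fs)
    tgt_vel = target.velocity_deg_s()
    keep = (trace.valid
            & ~_saccade_mask(len(trace), fs, saccades)
            & (np.abs(target.position_deg) <= GAIN_ECCENTRICITY_MAX_DEG)
            & (np.abs(tgt_vel) > 0.5))
    if not keep.any():
        raise ValueError("no retained samples for gain")
    return float(np.mean(eye_vel[keep] / tgt_vel[keep]))


def summarize_session(trials: list[SessionTrial], calibrations: list[RawCalibration],
                      aggregate: str = "mean", return_events: bool = False):
    """Calibrate, mask blinks, detect saccades and assemble the phenotypes.

    Each trial uses the most recent preceding calibration.  Trials with
    fewer than 50% valid samples (after blink masking) are dropped; a
    session with zero usable trials raises.  With ``return_events`` the
    per-saccade event table (trial, onset/offset ms, amplitude, class) is
    returned alongside the phenotypes.
    """
    if aggregate not in ("mean", "pooled"):
        raise ValueError("aggregate must be 'mean' or 'pooled'")
    if not trials:
        raise ValueError("no trials supplied")
    if not calibrations:
        raise ValueError("no calibration blocks supplied")
    fits: list[CalibrationFit] = sorted((fit_calibration(c) for c in calibrations),
                                        key=lambda f: f.before_trial)

    def fit_for(trial_index: int) -> CalibrationFit:
        chosen = fits[0]
        for f in fits:
            if f.before_trial <= trial_index:
                chosen = f
        return chosen

    # calibrate and blink-mask every trial
    prepared: list[tuple[EyeTrace, TargetTrajectory]] = []
    for trial in trials:
        cal = apply_calibration(trial.eye, fit_for(trial.index))
        blinks = detect_blinks(cal)
        cal = apply_blink_mask(cal, blinks)
        prepared.append((cal, trial.target))

    threshold = compute_saccade_threshold([tr for tr, _ in prepared])

    rmses, gains = [], []
    sq_sum, n_sq = 0.0, 0
    n_catch = n_antic = 0
    valid_motion_s = 0.0
    n_used = 0
    events: list[dict] = []
    for trial_no, (tr, target) in enumerate(prepared):
        if tr.valid_fraction < MIN_VALID_FRACTION:
            continue
        saccades = detect_and_classify_saccades(tr, target, threshold)
        try:
            rmse = compute_rmse(tr, target)
            gain = compute_gain(tr, target, saccades)
        except ValueError:
            continue
        n_used += 1
        rmses.append(rmse)
        gains.append(gain)
        err = tr.position_deg[tr.valid] - target.position_deg[tr.valid]
        sq_sum += float(np.sum(err**2))
        n_sq += int(tr.valid.sum())
        n_catch += sum(1 for s in saccades if s.klass == "catchup")
        n_antic += sum(1 for s in saccades if s.klass == "anticipatory")
        events.extend({"trial": trials[trial_no].index, "onset_ms": s.onset_ms,
                       "offset_ms": s.offset_ms, "amplitude_deg": s.amplitude_deg,
                       "klass": s.klass} for s in saccades)
        valid_motion_s += float(np.sum(tr.valid & target.motion_mask)) / tr.sample_rate_hz
    if n_used == 0:
        raise ValueError("no usable trials in session")

    rmse_session = float(np.mean(rmses)) if aggregate == "mean" \
        else float(np.sqrt(sq_sum / n_sq))
    phenotypes = SessionPhenotypes(
        rmse_deg=rmse_session,
        gain=float(np.mean(gains)),
        catchup_per_s=n_catch / valid_motion_s if valid_motion_s > 0 else 0.0,
        anticipatory_per_s=n_antic / valid_motion_s if valid_motion_s > 0 else 0.0,
        n_trials_used=n_used,
    )
    if return_events:
        import pandas as pd
        columns = ["trial", "onset_ms", "offset_ms", "amplitude_deg", "klass"]
        return phenotypes, pd.DataFrame(events, columns=columns)
    return phenotypes
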