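"""Saccade detection by a participant-relative acceleration threshold.

The threshold is six times the median, across trials, of the standard
deviation of the acceleration signal during the first 80 ms of each
trial (the initial fixation, so it measures the participant's noise
floor).  Candidate events are runs where |acceleration| exceeds the
threshold; candidates closer than a 20 ms refractory gap are merged,
event bounds extend to where |acceleration| falls back below 20% of
threshold, and events shorter than 10 ms are discarded.

Classification uses the position error (eye - target) just outside the
event (onset - 5 ms, offset + 5 ms), measured on the smoothed position;
candidates whose smoothed position change is below 0.3 degrees are
discarded (velocity reversals of smooth pursuit produce acceleration
transients with no position jump); a saccade in the direction of
pursuit that decreases |error| is a catch-up saccade; one in the pursuit
direction that increases |error| and exceeds 1.5 degrees in amplitude is
anticipatory; everything else is "other".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from typing import TYPE_CHECKING

from .preprocess import acceleration, smooth_position
from .trace import EyeTrace

if TYPE_CHECKING:  # pragma: no cover
    from ..sim.targets import TargetTrajectory

__all__ = ["Saccade", "initial_acceleration_sd", "threshold_from_sds",
           "compute_saccade_threshold", "detect_and_classify_saccades"]

THRESHOLD_MULTIPLIER = 6.0
INITIAL_WINDOW_MS = 80
REFRACTORY_MS = 20
MIN_DURATION_MS = 10
BOUND_FRACTION = 0.2
ERROR_MARGIN_MS = 5
ANTICIPATORY_MIN_AMP_DEG = 1.5
MIN_AMPLITUDE_DEG = 0.3   # rejects pursuit-reversal transients with no position jump


@dataclass
class Saccade:
    onset_ms: float
    offset_ms: float
    amplitude_deg: float    # signed position change onset -> offset
    direction: int
    klass: str              # "catchup" | "anticipatory" | "other"

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


def initial_acceleration_sd(trace: EyeTrace) -> float | None:
    """SD of the acceleration signal over the first 80 ms of a trial.

    None when the initial window is too short or contains invalid samples.
    """
    fs = trace.sample_rate_hz
    n0 = int(INITIAL_WINDOW_MS * fs / 1000.0)
    if len(trace) < max(n0, 25) or not trace.valid[:n0].all():
        return None
    acc = acceleration(trace.position_deg, fs)[:n0]
    return float(np.std(acc))


def threshold_from_sds(sds: list[float]) -> float:
    """The participant-relative rule: 6 x median of per-trial acceleration SDs."""
    if not sds:
        raise ValueError("no trial has a valid initial 80 ms window")
    return THRESHOLD_MULTIPLIER * float(np.median(sds))


def compute_saccade_threshold(trials: list[EyeTrace]) -> float:
    """Acceleration threshold for one participant's session."""
    sds = [sd for sd in (initial_acceleration_sd(t) for t in trials) if sd is not None]
    return threshold_from_sds(sds)


def _candidate_events(acc: np.ndarray, threshold: float, fs: int) -> list[tuple[int, int]]:
    above = np.abs(acc) > threshold
    if not above.any():
        return []
    starts = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    ends = np.flatnonzero(above[:-1] & ~above[1:]) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [len(acc)]])
    gap = int(REFRACTORY_MS * fs / 1000.0)
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] <= gap:
            merged[-1][1] = e
        else:
            merged.append([int(s), int(e)])
    # extend bounds to the 20%-of-threshold re-crossing
    low = BOUND_FRACTION * threshold
    out = []
    n = len(acc)
    for s, e in merged:
        while s > 0 and abs(acc[s - 1]) > low:
            s -= 1
        while e < n and abs(acc[e]) > low:
            e += 1
        out.append((s, e))
    # extending bounds may make neighbours touch; merge again
    final: list[tuple[int, int]] = []
    for s, e in out:
        if final and s <= final[-1][1]:
            final[-1] = (final[-1][0], max(final[-1][1], e))
        else:
            final.append((s, e))
    return final


def detect_and_classify_saccades(trace: EyeTrace, target: TargetTrajectory,
                                 threshold: float) -> list[Saccade]:
    """Detect saccades on a calibrated, blink-masked trace and classify them.

    Candidates containing invalid (blink) samples are discarded.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    fs = trace.sample_rate_hz
    acc = acceleration(trace.position_deg, fs)
    acc = np.where(trace.valid, acc, 0.0)  # keep artifacts from seeding candidates
    vel_target = target.velocity_deg_s()
    # amplitudes and classification errors are read off the smoothed position:
    # raw endpoints carry the full sensor noise and would misgrade small events
    pos = smooth_position(trace.position_deg, fs)
    n = len(pos)
    margin = int(ERROR_MARGIN_MS * fs / 1000.0)
    min_dur = int(MIN_DURATION_MS * fs / 1000.0)

    saccades: list[Saccade] = []
    for s, e in _candidate_events(acc, threshold, fs):
        if e - s < min_dur:
            continue
        if not trace.valid[s:e].all():
            continue
        i0 = max(0, s - margin)
        i1 = min(n - 1, e - 1 + margin)
        amplitude = float(pos[i1] - pos[i0])
        if abs(amplitude) < MIN_AMPLITUDE_DEG:
            continue
        direction = int(np.sign(amplitude))
        mid = (s + e) // 2
        pursuit_dir = int(np.sign(vel_target[mid]))
        err_before = abs(pos[i0] - target.position_deg[i0])
        err_after = abs(pos[i1] - target.position_deg[i1])
        klass = "other"
        if pursuit_dir != 0 and direction == pursuit_dir:
            if err_after < err_before:
                klass = "catchup"
            elif err_after > err_before and abs(amplitude) > ANTICIPATORY_MIN_AMP_DEG:
                klass = "anticipatory"
        saccades.append(Saccade(onset_ms=float(trace.time_ms[s]),
                                offset_ms=float(trace.time_ms[min(e, n - 1)]),
                                amplitude_deg=amplitude, direction=direction,
                                klass=klass))
    return saccades
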