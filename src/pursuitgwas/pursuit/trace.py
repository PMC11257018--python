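"""Core recording containers shared by the simulator and the phenotyping code."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

__all__ = ["EyeTrace", "RawCalibration", "SessionTrial"]


@dataclass
class EyeTrace:
    """A horizontal eye-position series sampled at a fixed rate.

    position_deg holds either raw oculographic signal (before calibration)
    or calibrated position in degrees; ``calibrated`` records which.
    ``valid`` is False inside blinks / signal dropout.
    """

    time_ms: np.ndarray
    position_deg: np.ndarray
    valid: np.ndarray
    sample_rate_hz: int = 1000
    calibrated: bool = False

    def __post_init__(self) -> None:
        n = len(self.time_ms)
        if len(self.position_deg) != n or len(self.valid) != n:
            raise ValueError("time, position and valid series must have equal length")
        if n > 1 and np.any(np.diff(self.time_ms) <= 0):
            raise ValueError("time_ms must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time_ms)

    @property
    def valid_fraction(self) -> float:
        return float(np.mean(self.valid)) if len(self) else 0.0


@dataclass
class RawCalibration:
    """One uncalibrated calibration block: fixations on a horizontal grid."""

    time_ms: np.ndarray
    signal: np.ndarray
    target_deg: np.ndarray
    before_trial: int


@dataclass
class SessionTrial:
    """One trial: raw (uncalibrated) eye trace paired with its target."""

    eye: EyeTrace
    target: Any   # TargetTrajectory; duck-typed to avoid a simulator dependency
    index: int
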