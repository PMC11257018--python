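"""Deterministic triangular-waveform pursuit targets.

A trial begins with the target at the central fixation point for a
duration drawn uniformly from a configurable range, after which the
target moves horizontally at constant speed between ``-amplitude`` and
``+amplitude`` degrees, tracing a triangular waveform for a fixed number
of cycles (one cycle = out, back through centre to the opposite side,
and back to centre: period ``4 * amplitude / speed`` seconds).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TargetSpec", "TargetTrajectory", "generate_target_waveform"]


@dataclass(frozen=True)
class TargetSpec:
    """Parameters of one pursuit trial's target motion.

    speed_deg_s : constant target speed in deg/s (study set: 10, 20, 30).
    amplitude_deg : horizontal excursion, degrees (default 15).
    n_cycles : number of triangular cycles (default 5.5).
    initial_fixation_ms : (lo, hi) range the initial central fixation
        duration is drawn from, uniformly, in ms.
    sample_rate_hz : sampling rate of the emitted trajectory.
    start_direction : "left" or "right", direction of the first ramp.
    """

    speed_deg_s: float = 20.0
    amplitude_deg: float = 15.0
    n_cycles: float = 5.5
    initial_fixation_ms: tuple[int, int] = (500, 1500)
    sample_rate_hz: int = 1000
    start_direction: str = "right"

    def __post_init__(self) -> None:
        if self.speed_deg_s <= 0:
            raise ValueError("speed_deg_s must be positive")
        if self.amplitude_deg <= 0:
            raise ValueError("amplitude_deg must be positive")
        if self.n_cycles <= 0:
            raise ValueError("n_cycles must be positive")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        lo, hi = self.initial_fixation_ms
        if lo < 0 or hi < lo:
            raise ValueError("initial_fixation_ms must satisfy 0 <= lo <= hi")
        if self.start_direction not in ("left", "right"):
            raise ValueError("start_direction must be 'left' or 'right'")

    @property
    def motion_duration_s(self) -> float:
        """Duration of the moving part: n_cycles * 4A / v."""
        return self.n_cycles * 4.0 * self.amplitude_deg / self.speed_deg_s


@dataclass
class TargetTrajectory:
    """Sampled target position series for one trial."""

    time_ms: np.ndarray
    position_deg: np.ndarray
    sample_rate_hz: int
    fixation_ms: int
    spec: TargetSpec = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.time_ms)

    def velocity_deg_s(self) -> np.ndarray:
        """Signed target velocity (piecewise constant, 0 during fixation)."""
        return np.gradient(self.position_deg) * self.sample_rate_hz

    @property
    def motion_mask(self) -> np.ndarray:
        return self.time_ms >= self.fixation_ms


def _triangle(t_s: np.ndarray, amplitude: float, speed: float, sign: float) -> np.ndarray:
    """Triangular wave starting at 0 moving with velocity sign*speed."""
    period = 4.0 * amplitude / speed
    phase = np.mod(t_s, period) / period  # in [0,1)
    # quarter ramps: 0->A, A->-A, -A->0
    pos = np.where(
        phase < 0.25,
        4.0 * amplitude * phase,
        np.where(phase < 0.75, amplitude * (2.0 - 4.0 * phase), 4.0 * amplitude * (phase - 1.0)),
    )
    return sign * pos


def generate_target_waveform(spec: TargetSpec, seed: int | np.random.Generator = 0) -> TargetTrajectory:
    """Sample the target position series for one trial.

    The initial fixation duration is drawn uniformly (integer ms) from
    ``spec.initial_fixation_ms`` using ``seed`` (an int or a Generator,
    so a session simulator can pass its own stream through).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = spec.initial_fixation_ms
    fix_ms = int(rng.integers(lo, hi + 1))

    dt_ms = 1000.0 / spec.sample_rate_hz
    n_fix = int(round(fix_ms / dt_ms))
    n_mot = int(round(spec.motion_duration_s * spec.sample_rate_hz))
    n = n_fix + n_mot
    time_ms = np.arange(n) * dt_ms
    sign = 1.0 if spec.start_direction == "right" else -1.0

    pos = np.zeros(n)
    t_mot = np.arange(n_mot) * (1.0 / spec.sample_rate_hz)
    pos[n_fix:] = _triangle(t_mot, spec.amplitude_deg, spec.speed_deg_s, sign)
    return TargetTrajectory(time_ms=time_ms, position_deg=pos,
                            sample_rate_hz=spec.sample_rate_hz, fixation_ms=fix_ms, spec=spec)
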