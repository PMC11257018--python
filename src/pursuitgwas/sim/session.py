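"""Simulate annotated smooth-pursuit recording sessions.

The simulated eye follows the target through a first-order pursuit
model: smooth eye position ``u`` obeys

    du = gain * dT_lag + (T_lag - u - s) * dt / tau

where ``T_lag`` is the target delayed by the pursuit latency, ``s`` is
the cumulative displacement contributed by injected saccades and ``tau``
is a slow position-error feedback constant.  With gain 1 and no events
the recursion is exact: the eye equals the latency-shifted target.
With gain < 1 the eye accumulates a lag that the feedback term bounds,
producing the persistent position errors that catch-up saccades correct.

Catch-up and anticipatory saccades are scheduled as Poisson processes
over the motion period; each scheduled event is shifted forward to the
first sample at which its defining geometry holds (catch-up: error in
the pursuit direction and large enough; anticipatory: a saccade of the
configured amplitude in the pursuit direction would increase the error).
Saccades follow a minimum-jerk position profile.  Blinks clamp the
recorded signal to an off-scale constant with 50 ms tapered edges.

The recorded signal is an affine distortion of true position:
``signal = cal_gain * position + cal_offset``; interleaved calibration
fixation blocks carry the same distortion so downstream calibration can
undo it.  Everything injected is logged in :class:`SessionTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from ..pursuit.trace import EyeTrace, RawCalibration, SessionTrial
from .targets import TargetSpec, TargetTrajectory, generate_target_waveform

__all__ = [
    "SimTraceConfig",
    "RawCalibration",
    "SimTrial",
    "TruthSaccade",
    "SessionTruth",
    "simulate_session",
    "default_spec_set",
]

CAL_TARGETS_DEG = (15.0, 10.0, 5.0, 0.0, -5.0, -10.0, -15.0)
CAL_FIXATION_MS = 1000
BLINK_TAPER_MS = 50
BLINK_CLAMP_SIGNAL = -45.0


@dataclass(frozen=True)
class SimTraceConfig:
    """Knobs of the simulated oculomotor plant and recording chain."""

    pursuit_gain_true: float = 0.9
    pursuit_latency_ms: float = 100.0
    catchup_rate_per_s: float = 0.5
    anticipatory_rate_per_s: float = 0.2
    anticipatory_amp_deg: float = 2.5
    blink_rate_per_s: float = 0.1
    blink_duration_ms: float = 250.0
    noise_sd_deg: float = 0.1          # sensor noise, ~six arcmin
    cal_gain: float = 1.0
    cal_offset_deg: float = 0.0
    seed: int = 0
    # plumbing beyond the recording chain
    error_feedback_tau_s: float = 0.7
    catchup_min_error_deg: float = 0.5
    catchup_fraction: float = 0.9
    trials_per_speed: int = 8
    cal_interval_trials: int = 6
    shuffle_trials: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.pursuit_gain_true <= 1.2):
            raise ValueError("pursuit_gain_true must be in (0, 1.2]")
        if self.noise_sd_deg < 0:
            raise ValueError("noise_sd_deg must be >= 0")
        for name in ("catchup_rate_per_s", "anticipatory_rate_per_s",
                     "blink_rate_per_s", "pursuit_latency_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.anticipatory_amp_deg <= 1.5:
            raise ValueError("anticipatory_amp_deg must exceed 1.5 deg to be "
                             "classifiable as anticipatory")
        if self.blink_duration_ms <= 2 * BLINK_TAPER_MS:
            raise ValueError("blink_duration_ms must exceed the two 50 ms tapers")
        if abs(self.cal_gain) < 1e-6:
            raise ValueError("cal_gain must be nonzero")


SimTrial = SessionTrial


@dataclass
class TruthSaccade:
    trial: int
    onset_ms: float
    offset_ms: float
    amplitude_deg: float
    klass: str              # "catchup" | "anticipatory"


@dataclass
class SessionTruth:
    saccade_events: list[TruthSaccade] = field(default_factory=list)
    blink_intervals: list[tuple[int, float, float]] = field(default_factory=list)
    pursuit_gain_true: float = 1.0


def default_spec_set(speeds=(10.0, 20.0, 30.0), **kwargs) -> list[TargetSpec]:
    """One TargetSpec per target speed of the standard protocol."""
    return [TargetSpec(speed_deg_s=s, **kwargs) for s in speeds]


def _min_jerk(n: int) -> np.ndarray:
    tau = np.arange(1, n + 1) / n
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _saccade_duration_ms(amplitude_deg: float) -> float:
    # main-sequence-like: larger saccades last longer, clipped to 30-80 ms
    return float(np.clip(30.0 + 8.0 * abs(amplitude_deg), 30.0, 80.0))


def _smooth_eye(t_lag: np.ndarray, s: np.ndarray, gain: float, a_fb: float) -> np.ndarray:
    """Integrate the first-order pursuit recursion (vectorised via lfilter).

    u[i+1] = u[i] + gain*(t_lag[i+1]-t_lag[i]) + a_fb*(t_lag[i] - u[i] - s[i])
    """
    drive = np.empty_like(t_lag)
    drive[0] = 0.0
    drive[1:] = gain * np.diff(t_lag) + a_fb * (t_lag[:-1] - s[:-1])
    # u[i] = (1 - a_fb) u[i-1] + drive[i]
    return lfilter([1.0], [1.0, -(1.0 - a_fb)], drive)


def _simulate_trial(target: TargetTrajectory, config: SimTraceConfig,
                    rng: np.random.Generator, trial_index: int,
                    truth: SessionTruth) -> EyeTrace:
    fs = target.sample_rate_hz
    dt = 1.0 / fs
    n = len(target)
    pos = target.position_deg
    n_lag = int(round(config.pursuit_latency_ms * fs / 1000.0))
    t_lag = np.concatenate([np.full(n_lag, pos[0]), pos[: n - n_lag]]) if n_lag else pos.copy()
    a_fb = dt / config.error_feedback_tau_s
    g = config.pursuit_gain_true

    motion_start = int(target.fixation_ms * fs / 1000.0)
    motion_dur_s = (n - motion_start) * dt
    vel = target.velocity_deg_s()

    # --- blinks ---------------------------------------------------------
    blink_mask = np.zeros(n, dtype=bool)
    n_blinks = rng.poisson(config.blink_rate_per_s * n * dt)
    blink_len = int(round(config.blink_duration_ms * fs / 1000.0))
    for _ in range(n_blinks):
        b0 = int(rng.integers(0, max(1, n - blink_len)))
        blink_mask[b0 : b0 + blink_len] = True
        truth.blink_intervals.append(
            (trial_index, b0 * dt * 1000.0, (b0 + blink_len) * dt * 1000.0))

    # --- schedule saccadic events --------------------------------------
    events: list[tuple[int, str]] = []
    for klass, rate in (("catchup", config.catchup_rate_per_s),
                        ("anticipatory", config.anticipatory_rate_per_s)):
        k = rng.poisson(rate * motion_dur_s)
        for idx in rng.integers(motion_start, n, size=k):
            events.append((int(idx), klass))
    events.sort()

    s = np.zeros(n)  # cumulative saccadic displacement
    occupied = blink_mask.copy()  # samples already taken by blinks/saccades

    # keep events clear of target reversals: the latency-lagged smooth eye
    # still moves with the old direction there, which corrupts the class
    # geometry of an injected saccade
    sgn = np.sign(vel)
    flip = np.flatnonzero(sgn[1:] != sgn[:-1]) + 1
    near_reversal = np.zeros(n, dtype=bool)
    back = n_lag + int(0.02 * fs)
    ahead = int(0.12 * fs)
    for f in flip:
        near_reversal[max(0, f - ahead) : min(n, f + back)] = True

    for sched_idx, klass in events:
        u = _smooth_eye(t_lag, s, g, a_fb)
        eye_pre = u + s
        err = pos - eye_pre  # signed real position error
        d = np.sign(vel)
        if klass == "catchup":
            valid = (np.sign(err) == d) & (np.abs(err) >= config.catchup_min_error_deg)
        else:
            a_sign = config.anticipatory_amp_deg * d
            # saccade of amplitude a in pursuit direction must increase |error|
            valid = (d != 0) & (np.abs(err - a_sign) > np.abs(err) + 0.1)
        valid &= ~occupied & ~near_reversal
        valid[:motion_start] = False
        cand = np.flatnonzero(valid[sched_idx:])
        if cand.size == 0:
            continue  # event dropped: no valid geometry before trial end
        i0 = sched_idx + int(cand[0])
        if klass == "catchup":
            amp = config.catchup_fraction * err[i0]
        else:
            amp = config.anticipatory_amp_deg * d[i0]
        dur = int(round(_saccade_duration_ms(amp) * fs / 1000.0))
        if i0 + dur >= n or occupied[i0 : i0 + dur].any():
            continue
        s[i0 : i0 + dur] += amp * _min_jerk(dur)
        s[i0 + dur :] += amp
        occupied[max(0, i0 - int(0.02 * fs)) : i0 + dur + int(0.02 * fs)] = True
        truth.saccade_events.append(TruthSaccade(
            trial=trial_index, onset_ms=i0 * dt * 1000.0,
            offset_ms=(i0 + dur) * dt * 1000.0, amplitude_deg=float(amp), klass=klass))

    u = _smooth_eye(t_lag, s, g, a_fb)
    eye_true = u + s
    if config.noise_sd_deg > 0:
        eye_true = eye_true + rng.normal(0.0, config.noise_sd_deg, n)
    signal = config.cal_gain * eye_true + config.cal_offset_deg

    # blink artifact: clamp with tapered edges
    if blink_mask.any():
        taper = int(BLINK_TAPER_MS * fs / 1000.0)
        starts = np.flatnonzero(blink_mask[1:] & ~blink_mask[:-1]) + 1
        if blink_mask[0]:
            starts = np.concatenate([[0], starts])
        ends = np.flatnonzero(blink_mask[:-1] & ~blink_mask[1:]) + 1
        if blink_mask[-1]:
            ends = np.concatenate([ends, [n]])
        for b0, b1 in zip(starts, ends):
            lo = min(b0 + taper, b1)
            hi = max(b1 - taper, lo)
            signal[lo:hi] = BLINK_CLAMP_SIGNAL
            w_in = np.linspace(0.0, 1.0, lo - b0)
            signal[b0:lo] += w_in * (BLINK_CLAMP_SIGNAL - signal[b0:lo])
            w_out = np.linspace(1.0, 0.0, b1 - hi)
            signal[hi:b1] = signal[hi:b1] + w_out * (BLINK_CLAMP_SIGNAL - signal[hi:b1])

    return EyeTrace(time_ms=target.time_ms.copy(), position_deg=signal,
                    valid=~blink_mask, sample_rate_hz=fs, calibrated=False)


def _make_calibration(config: SimTraceConfig, rng: np.random.Generator,
                      before_trial: int, fs: int) -> RawCalibration:
    n_fix = int(CAL_FIXATION_MS * fs / 1000.0)
    tgt = np.repeat(CAL_TARGETS_DEG, n_fix)
    n = len(tgt)
    noise = rng.normal(0.0, config.noise_sd_deg, n) if config.noise_sd_deg > 0 else 0.0
    sig = config.cal_gain * (tgt + noise) + config.cal_offset_deg
    return RawCalibration(time_ms=np.arange(n) * (1000.0 / fs), signal=sig,
                          target_deg=tgt.astype(float), before_trial=before_trial)


def simulate_session(
    spec_set: list[TargetSpec] | None,
    config: SimTraceConfig,
) -> tuple[list[SimTrial], list[RawCalibration], SessionTruth]:
    """Simulate one participant's full recording session.

    Returns the raw (uncalibrated) trial traces paired with their target
    trajectories, the interleaved calibration blocks, and the truth log
    of everything injected.  Identical config (including seed) gives
    byte-identical output.
    """
    if spec_set is None:
        spec_set = default_spec_set()
    rng = np.random.default_rng(config.seed)
    truth = SessionTruth(pursuit_gain_true=config.pursuit_gain_true)

    trial_specs: list[TargetSpec] = []
    for spec in spec_set:
        half = config.trials_per_speed // 2
        dirs = ["right"] * half + ["left"] * (config.trials_per_speed - half)
        for d in dirs:
            trial_specs.append(TargetSpec(
                speed_deg_s=spec.speed_deg_s, amplitude_deg=spec.amplitude_deg,
                n_cycles=spec.n_cycles, initial_fixation_ms=spec.initial_fixation_ms,
                sample_rate_hz=spec.sample_rate_hz, start_direction=d))
    if config.shuffle_trials:
        order = rng.permutation(len(trial_specs))
        trial_specs = [trial_specs[i] for i in order]

    fs = trial_specs[0].sample_rate_hz
    trials: list[SimTrial] = []
    calibrations: list[RawCalibration] = []
    for i, spec in enumerate(trial_specs):
        if i % config.cal_interval_trials == 0:
            calibrations.append(_make_calibration(config, rng, before_trial=i, fs=fs))
        target = generate_target_waveform(spec, rng)
        eye = _simulate_trial(target, config, rng, i, truth)
        trials.append(SimTrial(eye=eye, target=target, index=i))
    return trials, calibrations, truth
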