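"""Shared fixtures: small simulated sessions and cohorts, reused across tests."""

import numpy as np
import pytest

from pursuitgwas.pursuit import (apply_blink_mask, apply_calibration,
                                 detect_blinks, fit_calibration)
from pursuitgwas.sim import SimCohortConfig, SimTraceConfig, simulate_cohort, simulate_session


@pytest.fixture(scope="session")
def standard_session():
    """One full 24-trial session at gain 0.85 with events and blinks."""
    config = SimTraceConfig(pursuit_gain_true=0.85, catchup_rate_per_s=0.5,
                            anticipatory_rate_per_s=0.2, blink_rate_per_s=0.05,
                            seed=42)
    trials, calibrations, truth = simulate_session(None, config)
    return trials, calibrations, truth


@pytest.fixture(scope="session")
def prepared_session(standard_session):
    """Calibrated, blink-masked traces of the standard session."""
    trials, calibrations, truth = standard_session
    fits = sorted((fit_calibration(c) for c in calibrations),
                  key=lambda f: f.before_trial)

    def fit_for(index):
        chosen = fits[0]
        for f in fits:
            if f.before_trial <= index:
                chosen = f
        return chosen

    prepared = {}
    for trial in trials:
        cal = apply_calibration(trial.eye, fit_for(trial.index))
        cal = apply_blink_mask(cal, detect_blinks(cal))
        prepared[trial.index] = (cal, trial.target)
    return prepared, truth


@pytest.fixture(scope="session")
def small_cohort():
    """980 x 200 cohort at the default causal operating point."""
    config = SimCohortConfig(n_individuals=980, n_snps=200, seed=7)
    return simulate_cohort(config)


def match_events(detected, truth_events, trial, slack_ms=10.0):
    """Pair detected saccades with truth events of one trial by overlap."""
    pairs = []
    for ev in truth_events:
        if ev.trial != trial:
            continue
        hit = None
        for s in detected:
            if s.onset_ms <= ev.offset_ms + slack_ms and s.offset_ms >= ev.onset_ms - slack_ms:
                hit = s
                break
        pairs.append((ev, hit))
    return pairs
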