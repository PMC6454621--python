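"""Shared fixtures: synthetic sessions are expensive, so decode-grade
sessions are built once per test run and shared."""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pytest

from mngpipe.protocols import make_protocol
from mngpipe.synthesis import (default_templates, generate_ground_truth_trains,
                               synthesize_session)
from mngpipe.preprocess import sort_session, envelope
from mngpipe.decode import make_trials

FORCE_LEVELS = [1.0, 2.0, 4.0, 6.0]       # kPa
VELOCITY_LEVELS = [17.0, 26.0, 47.0]      # deg/s
N_UNITS_DECODE = 10
NOISE_SD = 0.08


@lru_cache(maxsize=24)
def build_session(task: str, seed: int, n_units: int = N_UNITS_DECODE,
                  reps: int = 3, noise_sd: float = NOISE_SD):
    """One ground-truthed session under the study conditions."""
    levels = FORCE_LEVELS if task == "isotonic" else VELOCITY_LEVELS
    law = "saturating_isotonic" if task == "isotonic" else "ramp_isokinetic"
    proto = make_protocol(task, levels, reps)
    trains = generate_ground_truth_trains(proto, n_units, law, seed=seed)
    sess = synthesize_session(proto, trains,
                              default_templates(n_units, cycle=True),
                              noise_sd=noise_sd, seed=seed)
    return sess, trains


@lru_cache(maxsize=24)
def build_processed(task: str, seed: int, n_units: int = N_UNITS_DECODE):
    """Session plus sorted units, filtered trace and decoding trials."""
    sess, trains = build_session(task, seed, n_units)
    units, filtered = sort_session(sess)
    trials = make_trials(sess, units, mng_env=envelope(filtered))
    return sess, trains, units, filtered, trials


@pytest.fixture(scope="session")
def force_scenario():
    return build_processed("isotonic", 1)


@pytest.fixture(scope="session")
def velocity_scenario():
    return build_processed("isokinetic", 1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
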