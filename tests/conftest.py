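"""Shared fixtures: compound list, config, and a simulated campaign.

The expensive pieces — a 60-run in-control history processed through the
full raw-signal pipeline, and one 25-injection batch per fault scenario —
are session-scoped and shared by the scenario, store and acceptance tests.
"""

from __future__ import annotations

import copy
from datetime import timedelta

import pytest
from hypothesis import settings

from hrmsqc import (
    PipelineState,
    QCConfig,
    default_internal_standards,
    process_run,
)
from hrmsqc.synthetic import SCENARIOS, ScenarioConfig, simulate_batch

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")

HISTORY_SEED = 7
HISTORY_N = 60
SCENARIO_SEED = 11


@pytest.fixture(scope="session")
def standards():
    return default_internal_standards()


@pytest.fixture(scope="session")
def cfg():
    return QCConfig()


@pytest.fixture(scope="session")
def nominal_state(standards, cfg):
    """(pipeline state, last timestamp, outcomes) after a 60-run in-control
    history processed end to end from raw spectra."""
    state = PipelineState()
    sc = ScenarioConfig(name="nominal", seed=HISTORY_SEED, n_injections=HISTORY_N)
    runs, _labels = simulate_batch(sc, standards)
    outcomes = [process_run(r, standards, cfg, state) for r in runs]
    return state, runs[-1].acquired_at, outcomes


@pytest.fixture(scope="session")
def scenario_outcomes(nominal_state, standards, cfg):
    """Per scenario: (sample-run outcomes, labels) for a 25-injection batch
    appended to an independent copy of the nominal history."""
    state, t_end, _ = nominal_state
    results = {}
    for name in SCENARIOS:
        st = copy.deepcopy(state)
        sc = ScenarioConfig(
            name=name,
            seed=SCENARIO_SEED,
            n_injections=25,
            start_time=t_end + timedelta(hours=1),
        )
        runs, labels = simulate_batch(sc, standards)
        outcomes = [process_run(r, standards, cfg, st) for r in runs]
        results[name] = (outcomes, labels)
    return results
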