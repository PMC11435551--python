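"""Shared fixtures: simulated recordings reused across the suite.

Simulation fixtures are session-scoped; trial lengths are kept short enough
for a quick suite while still holding >50 gait cycles where a test needs
statistics.
"""

from __future__ import annotations

import numpy as np
import pytest

from insolegait.pipeline import PipelineConfig, analyze_condition
from insolegait.simulate import VarianceComponents, condition_preset, simulate_condition

ZERO_NOISE = dict(
    within_trial_sd=VarianceComponents(0.0, 0.0, 0.0),
    between_trial_sd=VarianceComponents(0.0, 0.0, 0.0),
    cell_noise_sd=0.0,
    drift_ms=0.0,
)


@pytest.fixture(scope="session")
def zero_noise_sym_trials():
    """Three noiseless symmetric-treadmill trials, ~63 cycles each."""
    cfg = condition_preset("TDM6-SYM-MGAIT", seed=11, trial_duration_s=75.0, **ZERO_NOISE)
    return cfg, simulate_condition(cfg)


@pytest.fixture(scope="session")
def noisy_sym_trials():
    """Three symmetric-treadmill trials with the default noise model."""
    cfg = condition_preset("TDM6-SYM-MGAIT", seed=12, trial_duration_s=75.0)
    return cfg, simulate_condition(cfg)


@pytest.fixture(scope="session")
def pipeline_config():
    return PipelineConfig(trial_duration_s=40.0, seed=5)


@pytest.fixture(scope="session")
def full_run(pipeline_config):
    """All eight conditions analysed end to end (short trials)."""
    datasets = {}
    for name in pipeline_config.conditions:
        dataset, _, _ = analyze_condition(name, pipeline_config)
        datasets[name] = dataset
    return datasets


def match_to_truth(detected_times: np.ndarray, truth_times: np.ndarray) -> np.ndarray:
    """Absolute error (s) of each truth event against its nearest detection."""
    detected_times = np.asarray(detected_times)
    return np.array([np.min(np.abs(detected_times - t)) for t in truth_times])
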