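"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from msconn.config import GeneratorConfig, PreprocessConfig
from msconn.preprocess import preprocess_participant
from msconn import synthetic


@pytest.fixture(scope="session")
def tiny_config() -> GeneratorConfig:
    """A cohort small enough for end-to-end tests: 16 channels, 4+4
    participants, 4 trials per condition, 1.4 s epochs."""
    return GeneratorConfig(
        n_channels=16,
        n_participants_music=4,
        n_participants_control=4,
        n_trials_per_condition=4,
        epoch_window=(-200.0, 1200.0),
        segment_duration_range=(150.0, 400.0),
        snr=5.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    cohort, truths, templates = synthetic.simulate_cohort(tiny_config)
    return cohort, truths, templates


@pytest.fixture(scope="session")
def tiny_erps(tiny_config, tiny_cohort):
    cohort, _, _ = tiny_cohort
    pp = PreprocessConfig(epoch_window=tiny_config.epoch_window)
    erps = {}
    for epochs in cohort:
        e, _, _ = preprocess_participant(epochs, pp)
        erps[epochs.participant_id] = e
    return erps


@pytest.fixture(scope="session")
def noiseless_epochs():
    """Single-participant noiseless epochs from 4 known templates."""
    cfg = GeneratorConfig(
        n_channels=32,
        n_trials_per_condition=3,
        epoch_window=(-200.0, 2000.0),
        segment_duration_range=(150.0, 400.0),
        snr=np.inf,
        seed=3,
    )
    templates = synthetic.make_template_set(cfg.n_channels, 4, seed=11)
    schedule = synthetic.make_trial_schedule(cfg, seed=5)
    epochs, truth = synthetic.simulate_erp(templates, schedule, cfg, seed=5)
    return epochs, truth, templates
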