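"""Shared fixtures: synthetic records and one trained scaled-down model.

The expensive artefacts (the preprocessed 2-class dataset and the trained
reduced-width model) are session-scoped so the network, featurization and
acceptance tests share a single training run.
"""

import numpy as np
import pytest

from mlecg import (MLCNNBiLSTM, ModelConfig, SynthConfig, generate_dataset,
                   generate_record, run_pipeline)

TWO_CLASS_SEED = 11

#: 2-class definitions: distinct heart rate AND R amplitude, separable by
#: construction (rate 60 vs 150 bpm, R wave 1.0 vs 0.5 mV).
TWO_CLASS_DEFS = [
    {"heart_rate": 60.0},
    {"heart_rate": 150.0,
     "wave_params": {**SynthConfig().wave_params, "R": (0.5, 0.0, 0.015)}},
]


def two_class_config():
    return SynthConfig(noise_emg_amp=0.05, noise_baseline_amp=0.1,
                       noise_powerline_amp=0.02, seed=TWO_CLASS_SEED)


@pytest.fixture(scope="session")
def clean_record():
    """Noise-free 60 bpm record with zero RR jitter (500 Hz, 10 s)."""
    cfg = SynthConfig(hr_jitter=0.0, seed=3)
    rec, truth, clean = generate_record(cfg, return_clean=True)
    return rec, truth, clean


@pytest.fixture(scope="session")
def two_class_dataset():
    return generate_dataset(two_class_config(), 20, TWO_CLASS_DEFS)


@pytest.fixture(scope="session")
def two_class_arrays(two_class_dataset):
    x12, x2 = run_pipeline(two_class_dataset.records)
    return x12, x2, two_class_dataset.labels


@pytest.fixture(scope="session")
def trained_small(two_class_arrays):
    """Reduced-width model trained 30 epochs on the 2-class set."""
    x12, x2, labels = two_class_arrays
    model = MLCNNBiLSTM(x12, x2, labels, ModelConfig.small(seed=5))
    results = model.fit()
    return model, results
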