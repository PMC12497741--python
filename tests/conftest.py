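import numpy as np
import pandas as pd
import pytest

from actionfx import synthetic_data as sd
from actionfx.epochs_core import ChannelLayout, EpochSet


@pytest.fixture(scope="session")
def layout60():
    return ChannelLayout.standard_60()


@pytest.fixture(scope="session")
def small_dataset():
    """Four subjects, 12 trials/cell, 100 Hz, full default injections."""
    cfg = sd.default_config(seed=11, n_subjects=4, n_trials_per_cell=12,
                            sampling_rate=100.0)
    epochs_list, tables, truth = sd.generate_dataset(cfg)
    return cfg, epochs_list, tables, truth


@pytest.fixture()
def toy_epochs(layout60):
    """Deterministic 6-trial epoch set with a balanced mini trial table."""
    rng = np.random.default_rng(42)
    times = -200.0 + 10.0 * np.arange(100)   # 100 Hz, -200..790 ms
    data = rng.normal(0, 5, size=(6, 60, 100))
    epochs = EpochSet(data, times, layout60, subject_id="S00")
    table = pd.DataFrame({
        "subject": ["S00"] * 6,
        "congruency": ["congruent"] * 3 + ["incongruent"] * 3,
        "action": ["action", "no_action"] * 3,
        "validity": ["valid", "invalid"] * 3,
        "target_hemifield": ["left", "right"] * 3,
        "target_orientation": ["left", "left", "right", "right", "left", "right"],
        "rt": [500.0, 520.0, 480.0, 600.0, 550.0, 510.0],
        "correct": [True] * 6,
        "kept": [True] * 6,
    })
    return epochs, table
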