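import numpy as np
import pandas as pd
import pytest

import thiolkinetics as tk
from thiolkinetics.dataset import COLUMNS, StudyDataset


@pytest.fixture(scope="session")
def table2_models():
    return tk.table2_models()


@pytest.fixture(scope="session")
def noiseless_study(table2_models):
    """Full 28-cell factorial study with zero measurement noise."""
    return tk.simulate_study(table2_models, tk.paper_design(noise_sd=0.0, seed=1))


@pytest.fixture(scope="session")
def noisy_study_small():
    """Four-treatment factorial study at the default 2% noise level."""
    models = [
        m for m in tk.table2_models()
        if m.treatment in ("control", "basil", "garlic", "caraway")
    ]
    return tk.simulate_study(models, tk.paper_design(noise_sd=2.0, seed=7))


def make_dataset(rows, unit="percent"):
    """Build a StudyDataset from (treatment, heat, temp, time, rep, sh) tuples."""
    return StudyDataset(pd.DataFrame(rows, columns=list(COLUMNS)), unit=unit)


@pytest.fixture
def tiny_raw_dataset():
    """One group, raw units: day-0 triplicate {48, 50, 52} then a day-3 value."""
    return make_dataset(
        [
            ("control", "raw", 4.0, 0.0, 1, 48.0),
            ("control", "raw", 4.0, 0.0, 2, 50.0),
            ("control", "raw", 4.0, 0.0, 3, 52.0),
            ("control", "raw", 4.0, 3.0, 1, 40.0),
        ],
        unit="raw_units",
    )


def exact_line_series(k=5.0, intercept=100.0, times=range(6), temperature_c=4.0):
    rows = [
        ("control", "raw", temperature_c, float(t), 1, intercept - k * t)
        for t in times
    ]
    return make_dataset(rows)
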