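import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from mpus.data_model import (
    LABEL_BENIGN,
    LABEL_MALIGNANT,
    ZONE_PZ,
    ZONE_TZ,
    FeatureTable,
    RunConfig,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture
def speckle_frame(rng):
    """Smooth speckle-like texture used as a registration target."""
    img = ndimage.gaussian_filter(rng.standard_normal((72, 96)), 1.5)
    return img - img.min()


def make_feature_table(rng, n_patients=13, rows_per_patient=220, n_features=6,
                       effect=0.8, seed_labels=True):
    """Random labeled feature table with a controllable class effect."""
    n = n_patients * rows_per_patient
    df = pd.DataFrame({
        "patient_id": np.repeat([f"P{i:02d}" for i in range(n_patients)],
                                rows_per_patient),
        "plane_id": "mid",
        "row": rng.integers(0, 64, n),
        "col": rng.integers(0, 64, n),
        "zone": rng.choice([ZONE_PZ, ZONE_TZ], n),
        "label": rng.choice([LABEL_BENIGN, LABEL_MALIGNANT], n),
        "calcified": rng.random(n) < 0.02,
    })
    names = [f"f{j}" for j in range(n_features)]
    for j, name in enumerate(names):
        signal = effect * (df["label"] == LABEL_MALIGNANT) if seed_labels else 0.0
        df[name] = rng.normal(size=n) + signal
    return FeatureTable(df, names)


@pytest.fixture
def feature_table(rng):
    return make_feature_table(rng)
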