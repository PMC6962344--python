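import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from modfuse.panel_io import CONTROL, PATIENT, FeatureTable, ModalityPanel, build_panel

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_table(name, values, subjects=None, features=None):
    values = np.asarray(values, dtype=float)
    subjects = subjects or [f"s{i:03d}" for i in range(values.shape[0])]
    features = features or [f"{name}_f{j}" for j in range(values.shape[1])]
    return FeatureTable(name, pd.DataFrame(values, index=subjects, columns=features))


def make_labels(subjects, patients):
    patients = set(patients)
    return pd.Series({s: PATIENT if s in patients else CONTROL for s in subjects}).sort_index()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_class_data(rng):
    """Linearly shifted Gaussian two-class problem: (X, y) with y in ±1."""
    n = 60
    y = np.array([-1.0] * (n // 2) + [1.0] * (n // 2))
    X = rng.standard_normal((n, 8))
    X[y > 0, :3] += 1.2
    return X, y


@pytest.fixture
def small_panel(rng):
    """Tiny 2-modality panel (16 subjects) for fast end-to-end runs."""
    subjects = [f"s{i:03d}" for i in range(16)]
    labels = make_labels(subjects, subjects[8:])
    y = np.array([-1.0] * 8 + [1.0] * 8)
    tables = {}
    for m, nf, shift in (("a", 6, 1.5), ("b", 4, 0.8)):
        X = rng.standard_normal((16, nf))
        X[y > 0, : nf // 2] += shift
        tables[m] = make_table(m, X, subjects=subjects)
    return build_panel(tables, labels)


def xor_data(rng, n_per=15, noise=0.15):
    """Replicated XOR pattern: not separable by any linear rule."""
    corners = np.array([[1, 1], [-1, -1], [1, -1], [-1, 1]], dtype=float)
    labels = np.array([-1.0, -1.0, 1.0, 1.0])
    X = np.repeat(corners, n_per, axis=0) + noise * rng.standard_normal((4 * n_per, 2))
    y = np.repeat(labels, n_per)
    return X, y
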