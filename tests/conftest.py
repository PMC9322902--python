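import warnings

import numpy as np
import pytest

import ftirclass as fc

SEED = 11


@pytest.fixture(autouse=True)
def _quiet_numeric_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture(scope="session")
def easy_train():
    """Easy fixture training set: 100/class, low noise, seed fixed."""
    train, _ = fc.make_fixture("easy", seed=SEED)
    return train


@pytest.fixture(scope="session")
def easy_vf_split(easy_train):
    """vector_first-pretreated easy data with its Kennard-Stone split."""
    t = fc.apply_recipe("vector_first", easy_train)
    sp = fc.kennard_stone(t, fraction=0.8, stratified=True)
    lab = t.label_array().astype(str)
    return {
        "set": t,
        "split": sp,
        "Xcal": t.values[sp.calibration_idx],
        "ycal": lab[sp.calibration_idx],
        "Xval": t.values[sp.validation_idx],
        "yval": lab[sp.validation_idx],
    }


@pytest.fixture(scope="session")
def small_train():
    """Smaller easy-style set (25/class) for fast pipeline-level tests."""
    train, _ = fc.make_fixture("easy", seed=SEED, n_per_class=25)
    return train


def toy_set(rows, grid=None, mode=fc.ABSORBANCE, labels=None):
    """Tiny SpectrumSet helper for arithmetic-oracle tests."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    if grid is None:
        n = rows.shape[1]
        grid = np.arange(float(n), 0.0, -1.0)
    ids = [f"s{i}" for i in range(rows.shape[0])]
    return fc.SpectrumSet(np.asarray(grid, float), rows, mode, ids, labels)
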