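import numpy as np
import pandas as pd
import pytest

from hteforest.datagen import DGPConfig, calibrate_dgp, generate_trial
from hteforest.dataset import FeatureMeta, TrialDataset


@pytest.fixture(scope="session")
def calibrated_dgp() -> DGPConfig:
    """DGP calibrated to control survival 0.725 and subgroup RDs +0.069/-0.257."""
    return calibrate_dgp()


@pytest.fixture(scope="session")
def null_dgp() -> DGPConfig:
    """Homogeneous-effect DGP: both subgroups share one risk difference."""
    return calibrate_dgp(control_survival=0.725, rd_low=0.05, rd_high=0.05)


@pytest.fixture()
def small_trial(calibrated_dgp) -> TrialDataset:
    from dataclasses import replace
    return generate_trial(replace(calibrated_dgp, n_participants=400, seed=42))


def make_dataset(X: dict, y=None, w=None, kinds=None, seed=0) -> TrialDataset:
    """Hand-rolled TrialDataset from plain columns (for unit fixtures)."""
    frame = pd.DataFrame(X)
    n = len(frame)
    rng = np.random.default_rng(seed)
    if y is None:
        y = rng.integers(0, 2, n).astype(float)
    if w is None:
        w = rng.integers(0, 2, n).astype(float)
    meta = {}
    kinds = kinds or {}
    for name in frame.columns:
        kind = kinds.get(name)
        if kind is None:
            if frame[name].dtype == object:
                kind = "categorical"
            else:
                vals = set(frame[name].dropna().unique())
                kind = "binary" if vals <= {0, 1, 0.0, 1.0} else "continuous"
        meta[name] = FeatureMeta(
            name=name, kind=kind,
            missing_fraction=float(frame[name].isna().mean()),
        )
    return TrialDataset(y=np.asarray(y, float), w=np.asarray(w, float),
                        X=frame, meta=meta)
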