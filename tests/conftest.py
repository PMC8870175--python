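import numpy as np
import pandas as pd
import pytest

from ramelan import SpectralDataset, WavenumberAxis
from ramelan.preprocess import preprocess_dataset
from ramelan.synthetic import SyntheticConfig, make_dataset


@pytest.fixture
def small_axis() -> WavenumberAxis:
    return WavenumberAxis(np.arange(1200.0, 1501.0))


def make_toy_dataset(axis: WavenumberAxis, rows, sample_ids=None, classes=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    n = rows.shape[0]
    meta = pd.DataFrame(
        {
            "spectrum_id": [f"s{i:03d}" for i in range(n)],
            "sample_id": sample_ids if sample_ids is not None else ["a"] * n,
        }
    )
    if classes is not None:
        meta["class_label"] = classes
    return SpectralDataset(axis, rows, meta)


@pytest.fixture(scope="session")
def default_campaign():
    """One default synthetic campaign (seed 1): raw, truth and conditioned."""
    config = SyntheticConfig(seed=1)
    dataset, truth = make_dataset(config)
    conditioned = preprocess_dataset(dataset)
    return {
        "config": config,
        "dataset": dataset,
        "truth": truth,
        "conditioned": conditioned,
    }
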