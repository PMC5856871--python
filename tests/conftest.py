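import numpy as np
import pandas as pd
import pytest

from metaproc import FeatureMatrix, SampleRecord, SampleType


def make_matrix(values, sample_ids=None, feature_ids=None) -> FeatureMatrix:
    """Build a FeatureMatrix from a nested list / array (NaN = missing)."""
    arr = np.asarray(values, dtype=float)
    sample_ids = sample_ids or [f"S{i+1}" for i in range(arr.shape[0])]
    feature_ids = feature_ids or [f"F{j+1}" for j in range(arr.shape[1])]
    return FeatureMatrix(pd.DataFrame(arr, index=sample_ids, columns=feature_ids))


def make_samples(types, batches=None, orders=None) -> list[SampleRecord]:
    """Sample metadata from a compact list of type codes ('s','q','b')."""
    code = {"s": SampleType.STUDY, "q": SampleType.QC, "b": SampleType.BLANK}
    batches = batches or ["1"] * len(types)
    orders = orders or list(range(1, len(types) + 1))
    return [
        SampleRecord(
            sample_id=f"S{i+1}", sample_type=code[t], batch=str(b), injection_order=o
        )
        for i, (t, b, o) in enumerate(zip(types, batches, orders))
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_matrix_with_missing(rng, n_samples, n_features, missing_rate=0.15):
    vals = rng.lognormal(5, 1, size=(n_samples, n_features))
    mask = rng.random((n_samples, n_features)) < missing_rate
    vals[mask] = np.nan
    return vals
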