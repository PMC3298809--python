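import numpy as np
import pandas as pd
import pytest

from metabodelta import ClinicalTable, FeatureMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_clinical(baseline, followup, elapsed, gender=None):
    """Minimal clinical table from glucose/elapsed vectors."""
    n = len(baseline)
    idx = pd.Index([f"S{i+1}" for i in range(n)], name="subject_id")
    return ClinicalTable(
        pd.DataFrame(
            {
                "gender": gender if gender is not None else ["female"] * n,
                "waist_cm": np.full(n, 90.0),
                "bmi": np.full(n, 28.0),
                "age_years": np.full(n, 55.0),
                "glucose_baseline": np.asarray(baseline, dtype=float),
                "glucose_followup": np.asarray(followup, dtype=float),
                "elapsed_years": np.asarray(elapsed, dtype=float),
            },
            index=idx,
        )
    )


def make_matrix(arr, stage="raw", feature_ids=None):
    arr = np.asarray(arr, dtype=float)
    n, p = arr.shape
    cols = feature_ids or [f"M{j+1:03d}" for j in range(p)]
    idx = pd.Index([f"S{i+1}" for i in range(n)], name="subject_id")
    return FeatureMatrix(pd.DataFrame(arr, index=idx, columns=cols), stage=stage)


@pytest.fixture
def tiny_clinical():
    return make_clinical([100, 90, 100], [100, 100, 90], [5, 5, 4])
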