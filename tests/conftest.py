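import numpy as np
import pytest

from igri.core_model import (
    ExamRecord,
    ReferenceDataset,
    default_index_model,
    default_normalization_spec,
)
from igri.normalization import transform_record
from igri.synthetic_cohort import CohortConfig, build_reference, generate_cohort


@pytest.fixture(scope="session")
def spec():
    return default_normalization_spec()


@pytest.fixture(scope="session")
def model():
    return default_index_model()


@pytest.fixture
def glaucoma_record():
    return ExamRecord(9.54, -7.84, 56, 54, 48, 11, label=1)


@pytest.fixture
def normal_record():
    return ExamRecord(1.43, -1.49, 125, 140, 63, 13, label=0)


@pytest.fixture
def border_record():
    return ExamRecord(2.29, -6.99, 94, 89, 77, 12)


@pytest.fixture
def tight_reference(spec, glaucoma_record):
    """Reference whose 5 nearest rows to the glaucoma record are glaucoma."""
    center = transform_record(glaucoma_record, spec)
    rng = np.random.default_rng(7)
    near = np.clip(center + rng.normal(0, 0.01, size=(6, 6)), 0, 1)
    far = np.clip(rng.uniform(0, 0.15, size=(6, 6)), 0, 1)
    matrix = np.vstack([near, far])
    labels = np.array([1] * 6 + [0] * 6)
    return ReferenceDataset(matrix=matrix, labels=labels, provenance="synthetic")


@pytest.fixture(scope="session")
def small_cohort():
    config = CohortConfig(n_normal=120, n_glaucoma=160, seed=11)
    return generate_cohort(config)


@pytest.fixture(scope="session")
def small_reference(small_cohort, spec):
    return build_reference(small_cohort, spec)


def brute_force_nni(query, reference, k, exclude_row=None, metric="euclidean"):
    """Independent oracle: all-pairs distances, full sort, count labels."""
    rows = []
    for i, (row, label) in enumerate(zip(reference.matrix, reference.labels)):
        if exclude_row is not None and i == exclude_row:
            continue
        diff = np.asarray(query, float) - row
        if metric == "euclidean":
            d = float(np.sqrt((diff**2).sum()))
        else:
            d = float(np.abs(diff).sum())
        rows.append((d, tuple(row.tolist()), int(label)))
    rows.sort()
    return sum(label for _, _, label in rows[:k]) / k
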