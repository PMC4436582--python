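import numpy as np
import pandas as pd
import pytest

from cram.core_model import Dataset, MemoryRecord, SubjectRecord
from cram.synthetic_cohort import CohortConfig, ContaminantRates


@pytest.fixture
def hand_dataset() -> Dataset:
    """Two subjects, three memories (one unscored), built by hand."""
    subjects = [
        SubjectRecord("s1", 30, "female", True, "full", "internet"),
        SubjectRecord("s2", 60, "male", False, "in_person", "in_person"),
    ]
    memories = [
        MemoryRecord(
            "m1", "s1", (5,),
            {"things": 3, "feelings": 2, "people": 4, "places": 5,
             "times": 1, "episodes": 0, "contexts": 2, "details": 4},
        ),
        MemoryRecord("m2", "s1", (7, 8), None),
        MemoryRecord(
            "m3", "s2", (10,),
            {"things": 1, "feelings": 1, "people": 1, "places": 1,
             "times": 1, "episodes": 1, "contexts": 1, "details": 1},
        ),
    ]
    return Dataset.from_records(subjects, memories)


@pytest.fixture
def small_config() -> CohortConfig:
    """A small but fully structured cohort for fast tests."""
    return CohortConfig(n_subjects=300)


@pytest.fixture
def contaminated_config() -> CohortConfig:
    return CohortConfig(
        n_subjects=400,
        contaminants=ContaminantRates(
            uniform_memory=0.01, pattern_subject=0.02, outlier=0.01
        ),
    )


def make_scored_frame(vectors, subject_ids=None) -> pd.DataFrame:
    """Memories table from a list of 8-count vectors (helper for tests)."""
    from cram.core_model import FEATURES

    n = len(vectors)
    df = pd.DataFrame(
        {
            "memory_id": [f"m{i}" for i in range(n)],
            "subject_id": subject_ids or ["s0"] * n,
            "bins": [(1,)] * n,
            "scored": [True] * n,
        }
    )
    arr = np.asarray(vectors, dtype=float)
    for j, f in enumerate(FEATURES):
        df[f] = arr[:, j]
    return df
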