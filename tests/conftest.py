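import numpy as np
import pytest

from ruminate.cohort import CohortDesign, FeatureTable
from ruminate.simulate import SyntheticCohortConfig, simulate_cohort

import pandas as pd


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-subject single-habitat cohort with truth, reused across tests."""
    cfg = SyntheticCohortConfig(n_subjects=30, habitats=("rumen",), seed=42)
    table, design, tree, pathways, truth = simulate_cohort(cfg)
    return {"config": cfg, "table": table, "design": design, "tree": tree,
            "pathways": pathways, "truth": truth}


@pytest.fixture
def tiny_table():
    """3 samples x 4 taxa with simple hand-checkable counts."""
    counts = np.array([[10, 0, 5, 5], [5, 5, 5, 5], [0, 7, 3, 10]])
    return FeatureTable(["s1", "s2", "s3"], ["a", "b", "c", "d"], counts)


@pytest.fixture
def tiny_design():
    frame = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3"],
            "subject_id": ["cowA", "cowA", "cowB"],
            "day": [-21, 1, -21],
            "habitat": ["rumen"] * 3,
        }
    )
    return CohortDesign(frame)
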