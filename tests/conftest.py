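import numpy as np
import pytest
from hypothesis import settings

import ceam

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def planted():
    """Planted two-cohort purified-cell fixture: 400 CpGs, 20 donors/cohort."""
    rng = np.random.default_rng(5)
    truth = ceam.make_planted_truth(400, rng, within_sd=0.03)
    cohorts = ceam.synth_purified_cohorts(20, truth, seed=9)
    return truth, cohorts


@pytest.fixture(scope="session")
def built_panels(planted):
    """Full high/medium/low panel build on the planted fixture."""
    _, ((betas_a, meta_a), (betas_b, meta_b)) = planted
    return ceam.build_panels(betas_a, meta_a, betas_b, meta_b)


@pytest.fixture(scope="session")
def purified_meta():
    """Small one-cohort metadata: 20 donors x 4 cell types."""
    import pandas as pd

    rows = []
    for d in range(20):
        for cell in ceam.CELL_TYPES:
            rows.append(
                (f"D{d}_{cell}", f"D{d}", cell, 80.0 + d % 10,
                 "F" if d % 2 else "M", "A")
            )
    return pd.DataFrame(
        rows, columns=["sample_id", "donor_id", "cell_type", "age", "sex", "cohort"]
    )
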