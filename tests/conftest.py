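import numpy as np
import pandas as pd
import pytest

from medpheno import CohortSpec, generate_cohort, preprocess_records


def _mar_frame(rows):
    """Build a MAR record frame from (patient, admission, med, action, ts) tuples."""
    return pd.DataFrame(
        rows, columns=["patient_id", "admission_index", "medication_name", "action", "timestamp"]
    )


@pytest.fixture
def mar_frame():
    return _mar_frame


@pytest.fixture(scope="session")
def planted_cohort():
    """Small cohort with strong planted structure (0.9/0.05 contrast)."""
    usage = np.full((4, 4), 0.05)
    np.fill_diagonal(usage, 0.9)
    spec = CohortSpec(
        n_patients=120,
        n_medications=40,
        n_blocks=4,
        n_archetypes=4,
        block_size=10,
        block_usage=usage,
        background_rate=0.0,
        seed=11,
    )
    records, outcomes, truth = generate_cohort(spec)
    return spec, records, outcomes, truth


@pytest.fixture(scope="session")
def planted_matrix(planted_cohort):
    _, records, _, _ = planted_cohort
    _, matrix = preprocess_records(records)
    return matrix
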