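import datetime as dt

import numpy as np
import pytest

from fedvar.cohorts import CohortConfig, SiloSpec, generate_cohort
from fedvar.features import build_feature_matrix, fit_standardizer


@pytest.fixture(scope="session")
def small_iid_cohort():
    """2-silo IID coding-SNV cohort, moderately separable, session-cached."""
    cfg = CohortConfig(
        "coding_snv",
        (SiloSpec("a", 150), SiloSpec("b", 150)),
        split_date=dt.date(2020, 1, 1),
        test1_n=200,
        test2_n=200,
        seed=42,
        class_separation=1.5,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_iid_matrices(small_iid_cohort):
    """Standardized (train, test1) matrices for the small IID cohort."""
    tr = build_feature_matrix(small_iid_cohort.train_records)
    t1 = build_feature_matrix(small_iid_cohort.test1)
    mean, scale = fit_standardizer(tr.X)
    tr.X = (tr.X - mean) / scale
    t1.X = (t1.X - mean) / scale
    return tr, t1


@pytest.fixture(scope="session")
def small_clients(small_iid_matrices):
    tr, _ = small_iid_matrices
    return {
        str(s): (tr.X[tr.silo_id == s], tr.y[tr.silo_id == s])
        for s in np.unique(tr.silo_id)
    }
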