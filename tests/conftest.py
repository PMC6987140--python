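import numpy as np
import pandas as pd
import pytest

from threec import Cohort, GeneratorConfig, VariableCatalog, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A complete 300-subject cohort with 3 well-separated planted clusters."""
    cfg = GeneratorConfig(n_subjects=300, k_true=3, n_cm_info=5,
                          n_cm_noise=20, n_pbm_signal=5, n_pbm_null=20,
                          effect_size=4.0, seed=7)
    cohort, truth = generate_cohort(cfg)
    return cohort, truth, cfg


@pytest.fixture
def tiny_cohort():
    """Hand-built 4x3 cohort with a specific missingness pattern."""
    data = pd.DataFrame(
        {"DX": ["CN", "AD", "CN", "AD"],
         "A": [np.nan, np.nan, 1.0, 2.0],
         "B": [1.0, 2.0, np.nan, 3.0]},
        index=pd.Index(["s1", "s2", "s3", "s4"], name="subject_id"))
    catalog = VariableCatalog.from_records([
        {"variable": "DX", "category": "DX", "vartype": "categorical",
         "direction": "none", "domain": ""},
        {"variable": "A", "category": "CM", "vartype": "continuous",
         "direction": "higher_worse", "domain": ""},
        {"variable": "B", "category": "CM", "vartype": "continuous",
         "direction": "higher_worse", "domain": ""},
    ])
    return Cohort(data, catalog)
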