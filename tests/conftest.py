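import numpy as np
import pandas as pd
import pytest

from dbstdm.reference import trough_cohort
from dbstdm.synthetic import SyntheticConfig, generate_cohort, generate_paired, paired_records


@pytest.fixture
def reference_trough() -> pd.DataFrame:
    """The nine-patient published trough cohort."""
    return trough_cohort()


@pytest.fixture
def noise_free_records():
    """Noise-free paired records for 40 subjects (K parent 1.57, metabolite 0)."""
    cfg = SyntheticConfig(seed=11, n_subjects=40, meas_cv=0.0)
    cohort = generate_cohort(cfg)
    return paired_records(generate_paired(cohort, cfg)), cfg


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
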