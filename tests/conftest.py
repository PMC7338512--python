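import numpy as np
import pandas as pd
import pytest

import ctshapes as cs


@pytest.fixture(scope="session")
def paperlike_spec():
    return cs.make_spec("paper-like", n_rois=40, centers=4)


@pytest.fixture(scope="session")
def small_dataset():
    """A modest paper-like dataset shared across read-only tests."""
    spec = cs.make_spec("paper-like", n_rois=20, centers=3)
    cohort = cs.generate_cohort(90, 90, [60, 60, 60], seed=11)
    ct = cs.generate_ct(cohort, spec, seed=12)
    cohort = cs.generate_ados(cohort, spec, seed=13)
    return spec, cohort, ct


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def make_flat_cohort(n=60, center="A", group="TD", seed=0, age_lo=6.0, age_hi=30.0):
    """Single-center, single-group cohort helper for trajectory-level tests."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "subject_id": [f"X{i:04d}" for i in range(n)],
            "group": group,
            "age": rng.uniform(age_lo, age_hi, n),
            "sex": "M",
            "center": center,
            "ados_comm": np.nan,
            "ados_social": np.nan,
            "ados_stereo": np.nan,
            "severity": rng.standard_normal(n),
        }
    )
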