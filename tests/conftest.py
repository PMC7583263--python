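import numpy as np
import pandas as pd
import pytest

from cinrisk import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One medium default-parameter cohort shared across read-only tests."""
    return generate_cohort(SimConfig(n_patients=1200, seed=101))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_record(histotype="EEC", grade=1, stage_sub="IA", age=55,
                pole=0, ctnnb1=0, **extra) -> pd.Series:
    base = {
        "histotype": histotype, "grade": grade, "stage_sub": stage_sub,
        "age": age, "pole_mut": pole, "ctnnb1_mut": ctnnb1,
        "other_malignancy": 0, "positive_margins": 0,
        "dfs_time": 60.0, "dfs_event": 0, "os_time": 120.0, "os_event": 0,
    }
    base.update(extra)
    return pd.Series(base, name=extra.get("patient_id", "P1"))
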