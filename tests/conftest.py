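import logging

import numpy as np
import pandas as pd
import pytest

from gxeforge import (
    GenotypeMatrix,
    RecordFrame,
    SimConfig,
    grm_vanraden,
    simulate_dataset,
)

logging.getLogger("gxeforge").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_dataset():
    """A study-design-like synthetic dataset, scaled down for unit tests."""
    return simulate_dataset(SimConfig(n_lines=60, n_variants=800, seed=5))


@pytest.fixture(scope="session")
def small_grm(small_dataset):
    return grm_vanraden(small_dataset.genotypes)


@pytest.fixture
def toy_genotypes():
    """3 lines x 2 variants with hand-computable VanRaden GRM."""
    return GenotypeMatrix(
        line_ids=np.array(["a", "b", "c"], dtype=object),
        variant_ids=np.array(["v1", "v2"], dtype=object),
        dosages=np.array([[0.0, 2.0], [2.0, 0.0], [2.0, 2.0]]),
    )


def make_records(n_lines=4, envs=(("E1", 0.0, 18.0), ("E2", 1.0, 25.0)), phen=None, seed=0):
    """Complete-grid RecordFrame with (sex, temperature) covariates."""
    rng = np.random.default_rng(seed)
    rows = []
    k = 0
    for i in range(n_lines):
        for env_id, sex, temp in envs:
            y = phen[k] if phen is not None else rng.normal()
            rows.append(
                {"line_id": f"L{i:03d}", "env_id": env_id, "phenotype": y,
                 "sex": sex, "temperature": temp}
            )
            k += 1
    return RecordFrame(pd.DataFrame(rows), ["sex", "temperature"])


SIX_ENVS = (
    ("F_18", 0.0, 18.0), ("F_25", 0.0, 25.0), ("F_28", 0.0, 28.0),
    ("M_18", 1.0, 18.0), ("M_25", 1.0, 25.0), ("M_28", 1.0, 28.0),
)


@pytest.fixture
def records_factory():
    return make_records
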