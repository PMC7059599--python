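import numpy as np
import pytest

from cdcat.engine import StudyConfig, run_full_study
from cdcat.study_design import POOL_SPECS, PoolSpec, generate_item_pool


@pytest.fixture(scope="session")
def toy_bank():
    """Small K=3 bank (14 items = 2 replicates of the 7 nonzero patterns)."""
    spec = PoolSpec(label="toy", J=14, K=3, r_range=(0.1, 0.4))
    return generate_item_pool(spec, np.random.default_rng(7))


@pytest.fixture(scope="session")
def hd_bank():
    """One seeded draw of the high-discrimination 775-item pool."""
    return generate_item_pool(POOL_SPECS["HD"], np.random.default_rng(101))


@pytest.fixture(scope="session")
def ld_bank():
    """One seeded draw of the low-discrimination 775-item pool."""
    return generate_item_pool(POOL_SPECS["LD"], np.random.default_rng(102))


@pytest.fixture(scope="session")
def pwkl_grid():
    """Full-scale PWKL sweep: 3 pools x 3 populations x 3 constraint levels,
    N=3,200 examinees, 10-item tests.  Shared by the acceptance checks."""
    study = StudyConfig(methods=("PWKL",), seed=0)
    _, frame = run_full_study(study)
    return frame
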