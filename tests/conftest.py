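import numpy as np
import pytest

import covpower as cp


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture(scope="session")
def toy_cohort():
    """Two-group cohort small enough for exact, fast checks."""
    cfg = cp.SimulationConfig(
        populations=(
            cp.PopulationConfig("EUR1", "EUR", 30, 30, 2e-5, 0.003),
            cp.PopulationConfig("AFR1", "AFR", 30, 120, 2e-5, 0.003),
        ),
        n_variants=400,
        chrom_length=400_000,
        sfs_shape=0.2,
        seed=7,
    )
    return cp.build_cohort(cfg)


@pytest.fixture(scope="session")
def toy_imputed(toy_cohort):
    """Leave-batch-out imputation of the toy cohort on a 25%-density array."""
    from covpower.pipeline import impute_all_batches

    array = cp.design_array(toy_cohort, 100, seed=3)
    batches = cp.assign_batches(toy_cohort, 5, 11)
    imputed = impute_all_batches(toy_cohort, array, batches, cp.HmmParams())
    return array, imputed
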