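import numpy as np
import pytest
from hypothesis import settings

import cropgs as cg

settings.register_profile("repro", derandomize=True, deadline=None,
                          database=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def hwe_panel():
    """300 HWE diploid samples x 3000 loci, with known frequencies."""
    rng = np.random.default_rng(0)
    p = rng.uniform(0.05, 0.95, 3000)
    X = rng.binomial(2, p, size=(300, 3000)).astype(float)
    return X, p


@pytest.fixture(scope="session")
def small_vm():
    """Tiny deterministic matrix with one missing call."""
    dosage = np.array([
        [0, 1, 2, 0],
        [2, 1, 0, 1],
        [0, np.nan, 2, 2],
        [2, 0, 0, 1],
    ], dtype=float)
    return cg.VariantMatrix(
        sample_ids=["s1", "s2", "s3", "s4"],
        dosage=dosage,
        chrom=np.array(["1"] * 4, dtype=object),
        pos=np.array([100, 200, 300, 400]),
        ref=np.array(list("ACGT"), dtype=object),
        alt=np.array(list("GTAC"), dtype=object),
    )


@pytest.fixture(scope="session")
def parent_panel():
    """60 inbred parents (30 B, 30 R) x 400 loci."""
    return cg.simulate_parent_panel(cg.SimTruth(seed=7), n_parents=60,
                                    n_loci=400, n_b=30)


@pytest.fixture(scope="session")
def wild_cult():
    """Two-population panel at F_ST 0.1 used by PCA/NJ/F_ST checks."""
    return cg.simulate_populations(cg.SimTruth(seed=9, fst_target=0.1),
                                   n_wild=100, n_cult=100, n_loci=5000)
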