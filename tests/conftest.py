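import numpy as np
import pandas as pd
import pytest

from twinvar import cohortsim as cs
from twinvar.dataio import ExpressionTable, GenotypeTable, TwinCohort


@pytest.fixture(scope="session")
def small_cohort():
    """3 MZ pairs, 4 DZ pairs, 5 singletons (n=19)."""
    return cs.simulate_cohort(3, 4, 5, seed=11)


@pytest.fixture(scope="session")
def twin_cohort():
    """Discovery-scale cohort: 134 MZ + 192 DZ pairs + 113 singletons."""
    return cs.simulate_cohort(134, 192, 113, seed=5)


@pytest.fixture(scope="session")
def twin_genotypes(twin_cohort):
    cohort, ibd = twin_cohort
    return cs.simulate_genotypes(
        cohort, ibd, 40, seed=6, maf_range=(0.2, 0.5), ld_rho=0.8
    )


@pytest.fixture()
def toy_genotable():
    """Hand-built 3-variant x 4-sample table with exact GP triplets."""
    variants = pd.DataFrame(
        {
            "variant_id": ["v1", "v2", "v3"],
            "chrom": ["1", "1", "2"],
            "pos": [100, 2_100_000, 500],
            "ref": ["A", "C", "G"],
            "alt": ["G", "T", "A"],
            "maf": [0.25, 0.375, 0.5],
            "info": [0.95, 0.85, np.nan],
        }
    )
    gp = np.zeros((3, 4, 3))
    geno = np.array([[0, 1, 0, 1], [2, 1, 0, 0], [1, 1, 1, 1]])
    for i in range(3):
        for j in range(4):
            gp[i, j, geno[i, j]] = 1.0
    return GenotypeTable(
        variants=variants,
        dosage=geno.astype(float),
        gp=gp,
        samples=["s1", "s2", "s3", "s4"],
    )
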