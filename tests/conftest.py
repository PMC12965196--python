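import numpy as np
import pandas as pd
import pytest

from landgen.genotypes import GenotypeMatrix
from landgen.simulate import SimParams, simulate_dataset


def make_genotypes(dosage, ids=None) -> GenotypeMatrix:
    dosage = np.asarray(dosage, dtype=np.int8)
    n, L = dosage.shape
    ids = ids or [f"i{k}" for k in range(n)]
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, L + 1),
            "id": [f"v{j}" for j in range(L)],
            "ref": "A",
            "alt": "T",
        }
    )
    return GenotypeMatrix(dosage, ids, variants)


@pytest.fixture(scope="session")
def toy_G() -> GenotypeMatrix:
    """4 samples x 6 SNPs with heterozygotes and one missing call."""
    return make_genotypes(
        [
            [0, 1, 2, 0, 1, 2],
            [0, 1, 2, 0, 1, 2],
            [2, 1, 0, 1, 0, 2],
            [2, 2, 0, -1, 0, 1],
        ]
    )


@pytest.fixture(scope="session")
def sim():
    """Mid-sized simulated dataset reused by the slower analysis tests."""
    return simulate_dataset(
        SimParams(n_samples=60, n_snps=300, seed=7, n_rows=20, n_cols=25)
    )
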