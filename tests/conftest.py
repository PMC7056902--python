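import numpy as np
import pandas as pd
import pytest

from pmsblup.data import MISSING, GenotypeMatrix


def make_genotypes(dosages, ids=None, chrom=None, positions=None):
    """Build a GenotypeMatrix from a plain dosage array (rows = individuals)."""
    dosages = np.asarray(dosages, dtype=np.int16)
    n, m = dosages.shape
    ids = ids or [f"ind{i + 1}" for i in range(n)]
    markers = pd.DataFrame(
        {
            "marker_id": [f"snp{j + 1}" for j in range(m)],
            "chromosome": chrom or ["1"] * m,
            "position": positions if positions is not None else np.arange(1, m + 1),
            "allele1": "A",
            "allele2": "B",
        }
    )
    return GenotypeMatrix(ids, markers, dosages)


def random_genotypes(rng, n, m, maf_low=0.05, maf_high=0.5):
    """Hardy-Weinberg dosages at frequencies drawn uniform in [maf_low, maf_high]."""
    p = rng.uniform(maf_low, maf_high, m)
    return make_genotypes(rng.binomial(2, p, size=(n, m)))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def toy_qc_panel():
    """4 individuals x 3 markers where exactly one marker passes both QC filters.

    snp1: call rate 2/4 = 0.5 (fails call rate; MAF 0.5 passes).
    snp2: call rate 1.0 but monomorphic-ish MAF 0/8 = 0 (fails MAF).
    snp3: call rate 1.0, MAF 3/8 = 0.375 (passes both).
    """
    d = [
        [0, 0, 1],
        [MISSING, 0, 0],
        [2, 0, 2],
        [MISSING, 0, 0],
    ]
    return make_genotypes(d)


def yc_frame(ids, values):
    return pd.DataFrame({"id": ids, "yc": np.asarray(values, dtype=float)})
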