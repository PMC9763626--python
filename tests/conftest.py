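import numpy as np
import pandas as pd
import pytest

from qkmgwas.genotype import GenotypeMatrix
from qkmgwas.simulate import SimConfig, simulate_genotypes


def make_genotype(dosages, chrom="chr1H", spacing=1000) -> GenotypeMatrix:
    """GenotypeMatrix from a raw dosage array with evenly spaced positions."""
    dosages = np.asarray(dosages, dtype=float)
    m = dosages.shape[1]
    variants = pd.DataFrame({
        "chrom": [chrom] * m,
        "pos": np.arange(1, m + 1) * spacing,
        "ref": ["A"] * m,
        "alt": ["G"] * m,
    })
    return GenotypeMatrix(dosages, variants)


@pytest.fixture(scope="session")
def small_cohort():
    """Structured 246-accession cohort reused by read-only tests."""
    cfg = SimConfig(n_snps=500, n_metabolites=40, seed=42,
                    planted_qtls=[(25, 0, 0.15)])
    G, labels = simulate_genotypes(cfg)
    return cfg, G, labels
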