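import numpy as np
import pandas as pd
import pytest

from popqtl.io_core import GenotypeMatrix, SampleTable, VariantRecord
from popqtl.synthetic_data import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Five-group cohort, 120 samples, 10 genes, with full truth."""
    cfg = SimConfig(
        n_groups=5, pops_per_group=2, pop_size_range=(12, 12),
        n_genes=10, variants_per_gene=40, n_clusters=12,
        seed=1234,
    )
    genotypes, samples, expression, splicing, truth = simulate_cohort(cfg)
    return {
        "config": cfg, "genotypes": genotypes, "samples": samples,
        "expression": expression, "splicing": splicing, "truth": truth,
    }


@pytest.fixture()
def toy_genotypes():
    """3 variants x 4 samples with one missing genotype."""
    variants = [
        VariantRecord("chr1", 100, "v1", "A", "G"),
        VariantRecord("chr1", 250, "v2", "C", "T"),
        VariantRecord("chr1", 900, "v3", "G", "A"),
    ]
    dosage = np.array(
        [[0, 1, 2, 1], [2, 0, 0, np.nan], [1, 1, 0, 2]], dtype=float
    )
    return GenotypeMatrix(variants, ["s1", "s2", "s3", "s4"], dosage)


@pytest.fixture()
def toy_samples():
    return SampleTable(
        pd.DataFrame(
            {
                "sample": ["s1", "s2", "s3", "s4"],
                "population": ["AFR01", "AFR01", "EUR01", "EUR01"],
                "group": ["AFR", "AFR", "EUR", "EUR"],
                "sex": ["F", "M", "F", "M"],
                "batch": ["b1", "b2", "b1", "b2"],
            }
        )
    )
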