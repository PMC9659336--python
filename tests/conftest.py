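import numpy as np
import pandas as pd
import pytest

import lowcovpop as lcp


@pytest.fixture(scope="session")
def divergent_truth():
    """1,000 strongly divergent SNPs (inversion-like contrast)."""
    return lcp.simulate_divergent_populations(
        1_000, ("uniform", 0.9, 1.0), seed=11, labels=("atlantic", "baltic")
    )


@pytest.fixture(scope="session")
def divergent_panel(divergent_truth):
    ref = lcp.sample_genotypes(divergent_truth, 200, seed=12, prefix="ref")
    return lcp.select_divergent_snps(ref, min_abs_delta_p=0.5, contrast="inversion")


@pytest.fixture()
def tiny_panel():
    """Three-SNP hand-written panel."""
    table = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr2"],
            "pos": [100, 200, 50],
            "allele_a": ["A", "C", "G"],
            "allele_b": ["T", "G", "A"],
            "p_group1": [1.0, 0.9, 0.8],
            "p_group2": [0.0, 0.1, 0.2],
        }
    )
    return lcp.import_panel(table, ("north", "south"), contrast="toy")
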