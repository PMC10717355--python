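import numpy as np
import pandas as pd
import pytest

from sgaburden import GeneTypeCountMatrix, VariantType, collapse_counts, filter_rare
from sgaburden.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort with one strongly planted PTV gene and one SYN-confounded gene."""
    cfg = SimulationConfig(
        n_case=80,
        n_control=160,
        n_genes=40,
        seed=11,
        planted_genes=[
            {"gene_id": 0, "variant_type": "PTV", "odds_ratio": 8.0},
            {"gene_id": 30, "variant_type": "SYN", "odds_ratio": 8.0},
        ],
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    rare = filter_rare(small_cohort.variants)
    genes = [f"G{i:04d}" for i in range(40)]
    return collapse_counts(rare, list(small_cohort.samples["sample_id"]), genes)


@pytest.fixture
def tiny_matrix():
    """Hand-built 3-gene, 6-sample matrix with known counts."""
    counts = {vt: np.zeros((3, 6), dtype=np.int32) for vt in VariantType}
    counts[VariantType.PTV][0] = [2, 1, 0, 0, 0, 0]
    counts[VariantType.MIS][1] = [0, 1, 1, 0, 1, 0]
    counts[VariantType.SYN][2] = [1, 0, 0, 0, 0, 1]
    return GeneTypeCountMatrix(
        genes=["GA", "GB", "GC"],
        samples=[f"S{i}" for i in range(6)],
        counts=counts,
    )


@pytest.fixture
def variant_frame():
    return pd.DataFrame(
        {
            "sample_id": ["S1", "S1", "S2", "S3"],
            "gene": ["GA", "GA", "GB", "GA"],
            "consequence": [
                "stop_gained",
                "stop_gained",
                "missense_variant",
                "synonymous_variant",
            ],
            "allele_frequency": [0.001, np.nan, 0.005, 0.002],
        }
    )
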