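import numpy as np
import pandas as pd
import pytest

from melanotx.genesets import GeneSet, packaged_gene_sets
from melanotx.preprocess import CountMatrix, estimate_size_factors, filter_low_expression
from melanotx.simulate import SimulationConfig, generate_counts

PLANTED_SET = "PLANTED50"
PLANTED_GENES = tuple(f"SYN{i:04d}" for i in range(1, 51))


def make_counts(data: dict[str, list[int]], classes: list[str] | None = None) -> CountMatrix:
    """Tiny CountMatrix helper: data maps sample id -> per-gene counts."""
    df = pd.DataFrame(data)
    df.index = [f"G{i}" for i in range(1, len(df) + 1)]
    n = df.shape[1]
    samples = pd.DataFrame(
        {"class": classes or ["c"] * n, "replicate": list(range(1, n + 1))},
        index=df.columns,
    )
    return CountMatrix(df, samples)


@pytest.fixture(scope="session")
def registry_with_planted():
    reg = packaged_gene_sets()
    reg[PLANTED_SET] = GeneSet(PLANTED_SET, PLANTED_GENES)
    return reg


@pytest.fixture(scope="session")
def planted_dataset(registry_with_planted):
    """Study-scale synthetic dataset: 2000 genes, 5 classes x 3 replicates,
    a 50-gene set planted at log2FC = -2 in the degrader class."""
    cfg = SimulationConfig(
        seed=11,
        n_genes=2000,
        planted_effects=((PLANTED_SET, "PROTAC", -2.0),),
    )
    return generate_counts(cfg, registry_with_planted)


@pytest.fixture(scope="session")
def planted_norm(planted_dataset):
    filt = filter_low_expression(planted_dataset.counts)
    return filt, estimate_size_factors(filt)
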