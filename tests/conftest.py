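import numpy as np
import pandas as pd
import pytest

from metastrat import CohortConfig, ExpressionMatrix, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """60-tumor, 3-cluster cohort shared by read-only tests."""
    return generate_cohort(
        CohortConfig(n_tumor_samples=60, n_normal_samples=6, k_true=3, master_seed=42)
    )


@pytest.fixture(scope="session")
def default_cohort():
    """Default-condition cohort (4 clusters, 200 tumors) shared by read-only tests."""
    return generate_cohort(CohortConfig(master_seed=42))


def random_expression(rng, n_genes=20, n_samples=5, prefix="G"):
    genes = [f"{prefix}{i:03d}" for i in range(n_genes)]
    samples = [f"S{i:03d}" for i in range(n_samples)]
    vals = rng.uniform(0, 100, size=(n_genes, n_samples))
    return ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=samples))
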