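import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from varex.io import CountsMatrix, GenotypeMatrix, PhenotypeTable, VariantRecord

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def small_genotypes() -> GenotypeMatrix:
    """7 samples x 3 variants with one missing call."""
    variants = [VariantRecord("1", 100, "rsA", "C", "T"),
                VariantRecord("1", 200, "rsB", "G", "A"),
                VariantRecord("1", 300, "rsC", "T", "C")]
    dosage = np.array([
        [0, 1, 2],
        [1, 1, 0],
        [2, 0, 1],
        [0, 0, 0],
        [1, 2, -1],
        [0, 1, 1],
        [2, 2, 0],
    ], dtype=np.int16)
    return GenotypeMatrix([f"s{i}" for i in range(7)], variants, dosage)


@pytest.fixture
def small_phenotype() -> PhenotypeTable:
    return PhenotypeTable(pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(7)],
        "status": ["case", "case", "case", "case", "control", "control", "control"],
        "dataset": ["d1"] * 7,
    }))


@pytest.fixture
def small_counts() -> CountsMatrix:
    rng = np.random.default_rng(42)
    counts = rng.poisson(200, size=(5, 6))
    return CountsMatrix([f"g{i}" for i in range(5)],
                        [f"s{j}" for j in range(6)], counts)
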