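import numpy as np
import pandas as pd
import pytest

from gsas import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    SimulationConfig,
    generate_benchmark,
    score_collection,
    screen_collection,
)

# Small-scale benchmark shared by the module tests (the acceptance tests
# build their own at the default scale).
SMALL_CONFIG = SimulationConfig(
    n_genes=600,
    n_samples=100,
    program_size=30,
    n_sets=50,
    n_program_sets=10,
    set_size_range=(15, 50),
    seed=2024,
)
SMALL_N_PERM = 30


@pytest.fixture(scope="session")
def small_benchmark():
    return generate_benchmark(SMALL_CONFIG, n_cohorts=2)


@pytest.fixture(scope="session")
def small_scored(small_benchmark):
    """GSAS matrices + survival screens for the small benchmark."""
    out = []
    for i, (expr, clinical, truth) in enumerate(small_benchmark.cohorts):
        gsas = score_collection(
            expr, small_benchmark.collection, n_perm=SMALL_N_PERM, seed=77 + i
        )
        screen = screen_collection(gsas, clinical, dataset=f"cohort{i}")
        out.append((gsas, screen))
    return out


@pytest.fixture
def tiny_expr():
    rng = np.random.default_rng(7)
    genes = [f"g{i:02d}" for i in range(50)]
    samples = [f"s{j}" for j in range(5)]
    return ExpressionMatrix(genes, samples, rng.normal(size=(50, 5)))


@pytest.fixture
def tiny_collection(tiny_expr):
    rng = np.random.default_rng(8)
    sets = {
        f"T{i}": list(rng.choice(tiny_expr.gene_ids, size=rng.integers(4, 20), replace=False))
        for i in range(10)
    }
    return GeneSetCollection.from_lists(sets)


@pytest.fixture
def simple_clinical():
    rng = np.random.default_rng(11)
    n = 40
    samples = [f"s{j}" for j in range(n)]
    return ClinicalTable(
        pd.DataFrame(
            {
                "time": rng.uniform(1, 100, n).round(2),
                "event": (rng.random(n) < 0.7).astype(float),
                "age": rng.normal(60, 10, n),
                "grade": rng.choice([1.0, 2.0, 3.0], n),
            },
            index=pd.Index(samples, name="sample"),
        )
    )
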