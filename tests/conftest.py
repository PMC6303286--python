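import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from trnascape import (
    CountMatrix,
    SimConfig,
    normalize_counts,
    simulate_annotation,
    simulate_paired_counts,
)


@pytest.fixture(scope="session")
def annotation60():
    return simulate_annotation(60, seed=1)


@pytest.fixture(scope="session")
def cohort(annotation60):
    """Paired cohort with one planted tRNA-level effect (FC=3)."""
    planted = annotation60["gene_id"].iloc[5]
    cfg = SimConfig(
        n_trna_genes=60,
        n_pairs=12,
        planted_effects=[(planted, "trna", 3.0)],
        dispersion=0.1,
        seed=11,
    )
    cm, meta, truth = simulate_paired_counts(cfg, annotation60)
    return {"cm": cm, "meta": meta, "truth": truth, "planted": planted}


@pytest.fixture(scope="session")
def expr(cohort):
    return normalize_counts(cohort["cm"])


def random_count_matrix(seed, n_features=50, n_samples=6, mean=200.0, phi=0.2):
    """Random NB count matrix used across tests."""
    rng = np.random.default_rng(seed)
    mu = rng.lognormal(np.log(mean), 1.0, size=(n_features, 1)) * rng.uniform(
        0.5, 2.0, size=(1, n_samples)
    )
    size = 1.0 / phi
    counts = rng.negative_binomial(size, size / (size + mu))
    counts[0] += 1  # guarantee every sample has a nonzero count
    df = pd.DataFrame(
        counts,
        index=[f"g{i}" for i in range(n_features)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    lib = pd.Series(counts.sum(axis=0) * 10 + 1000, index=df.columns)
    return CountMatrix(counts=df, lib_sizes=lib)
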