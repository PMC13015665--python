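import numpy as np
import pandas as pd
import pytest

from cftme.normalize import NormalizedMatrix, log2_cpm, normalize_counts
from cftme.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def cohort_with_ln_effect():
    """Small two-cohort simulation with a log2FC = 1 LN-analog effect."""
    config = SimulationConfig(
        n_genes=400,
        n_samples_per_cohort=[20, 20],
        responder_fraction=0.5,
        marker_gene_sets={"LN": tuple(range(20)), "FMAC": tuple(range(20, 40)), "TEX": tuple(range(40, 60))},
        effect_log2fc={"LN": 1.0, "FMAC": 0.0, "TEX": 0.0},
        seed=11,
    )
    counts, meta = simulate_cohort(config)
    return config, counts, meta


@pytest.fixture(scope="session")
def norm_with_ln_effect(cohort_with_ln_effect):
    _, counts, _ = cohort_with_ln_effect
    return normalize_counts(counts)


@pytest.fixture()
def toy_norm():
    """Deterministic 10-gene x 6-sample normalized matrix (no TMM)."""
    rng = np.random.default_rng(42)
    counts = pd.DataFrame(
        rng.integers(1, 500, size=(10, 6)),
        index=[f"g{i}" for i in range(10)],
        columns=[f"s{j}" for j in range(6)],
    )
    return log2_cpm(counts)


def make_norm(values: np.ndarray, genes=None, samples=None) -> NormalizedMatrix:
    """Wrap an explicit log2-CPM matrix for tests that need exact entries."""
    n_genes, n_samples = values.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    samples = samples or [f"s{j}" for j in range(n_samples)]
    logcpm = pd.DataFrame(values, index=genes, columns=samples, dtype=float)
    return NormalizedMatrix(
        logcpm=logcpm,
        factors=pd.Series(1.0, index=logcpm.columns),
        lib_sizes=pd.Series(1_000_000.0, index=logcpm.columns),
        pseudocount=0.5,
    )
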