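"""Synthetic cohort generator.

Emulates the statistical structure of a multi-cohort plasma cfRNA study so
every downstream stage is testable without external data:

* negative-binomial gene counts (mean/dispersion parameterization,
  variance mu + phi * mu^2) with gamma-distributed per-gene base abundance
  and log-normal per-sample library-size variation;
* three cohorts with binary responder labels and a configurable
  multiplicative (log2) effect on designated archetype-analog marker genes
  in responders;
* exponential progression times whose hazard depends on a group indicator
  or score, right-censored at a fixed horizon;
* Poisson single-cell counts with sample and cluster labels for pseudobulk
  tests; and
* QC-failing samples injected by overwriting metric fields only (the QC
  filters operate on summary metrics, never on counts).

One integer seed drives a single root random stream; each operation derives
its own deterministic substream, so outputs are byte-identical under a
fixed configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import METADATA_COLUMNS, SingleCellMatrix


def _default_marker_sets(n_genes: int) -> dict[str, tuple[int, ...]]:
    """Three disjoint archetype-analog sets: 20 genes each when the matrix
    allows, otherwise a third of the genes each."""
    size = min(20, n_genes // 3)
    return {
        "LN": tuple(range(0, size)),
        "FMAC": tuple(range(size, 2 * size)),
        "TEX": tuple(range(2 * size, 3 * size)),
    }


def _default_effects() -> dict[str, float]:
    return {"LN": 0.0, "FMAC": 0.0, "TEX": 0.0}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the study design: three cohorts of 28/28/35 samples,
    negative-binomial counts with dispersion 0.3, per-gene base abundance
    Gamma(0.4, rate 0.004) (mean 100 counts/gene, heavy right tail), mild
    log-normal library-size variation, and exponential progression times
    (baseline hazard 0.05 per month, censoring at 24 months) in which
    responders progress at a log hazard ratio of -0.7.
    """

    n_genes: int = 2000
    n_samples_per_cohort: list[int] = field(default_factory=lambda: [28, 28, 35])
    responder_fraction: float = 0.5
    marker_gene_sets: dict[str, tuple[int, ...]] | None = None
    effect_log2fc: dict[str, float] = field(default_factory=_default_effects)
    nb_dispersion: float = 0.3
    libsize_log_mean: float = 0.0
    libsize_log_sd: float = 0.4
    baseline_gene_mean_shape: float = 0.4
    baseline_gene_mean_rate: float = 0.004
    survival_baseline_hazard: float = 0.05
    survival_log_hr: float = -0.7
    censor_time: float = 24.0
    qc_fail_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.marker_gene_sets is None:
            self.marker_gene_sets = _default_marker_sets(self.n_genes)
        if any(n <= 0 for n in self.n_samples_per_cohort):
            raise ValueError("cohort sizes must be positive")
        if not 0 < self.responder_fraction < 1:
            raise ValueError("responder_fraction must be in (0, 1)")
        if not 0 <= self.qc_fail_fraction < 1:
            raise ValueError("qc_fail_fraction must be in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.baseline_gene_mean_shape <= 0 or self.baseline_gene_mean_rate <= 0:
            raise ValueError("gamma parameters must be positive")
        seen: set[int] = set()
        for name, idx in self.marker_gene_sets.items():
            idx_set = set(idx)
            if any(i < 0 or i >= self.n_genes for i in idx_set):
                raise ValueError(f"marker set {name!r} has gene index out of range")
            if seen & idx_set:
                raise ValueError(f"marker set {name!r} overlaps another marker set")
            seen |= idx_set

    def gene_ids(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_genes)]

    def marker_gene_names(self, name: str) -> list[str]:
        ids = self.gene_ids()
        return [ids[i] for i in self.marker_gene_sets[name]]


def _substream(config_seed: int, label: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config_seed, label]))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mean + dispersion * mean^2."""
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a count matrix and metadata table.

    Counts for gene g in sample j are negative binomial with mean
    ``lib_j * q_g * 2**(beta_g * r_j)``, where ``q_g`` is the gamma base
    abundance, ``lib_j`` the log-normal library factor, ``r_j`` the
    responder indicator, and ``beta_g`` the configured log2 effect on
    marker genes (0 elsewhere).
    """
    genes = config.gene_ids()
    rng_genes = _substream(config.seed, 0)
    rng_samples = _substream(config.seed, 1)
    rng_counts = _substream(config.seed, 2)
    rng_qc = _substream(config.seed, 3)
    rng_surv = _substream(config.seed, 4)

    q = rng_genes.gamma(
        config.baseline_gene_mean_shape, 1.0 / config.baseline_gene_mean_rate, size=config.n_genes
    )
    q = np.maximum(q, 1e-3)

    beta = np.zeros(config.n_genes)
    for name, idx in config.marker_gene_sets.items():
        beta[list(idx)] = config.effect_log2fc.get(name, 0.0)

    sample_ids: list[str] = []
    cohorts: list[str] = []
    timepoints: list[str] = []
    responders: list[bool] = []
    libs: list[float] = []
    for c, n in enumerate(config.n_samples_per_cohort, start=1):
        r = rng_samples.random(n) < config.responder_fraction
        lib = np.exp(rng_samples.normal(config.libsize_log_mean, config.libsize_log_sd, size=n))
        for j in range(n):
            sample_ids.append(f"C{c}_S{j + 1:03d}")
            cohorts.append(f"cohort{c}")
            timepoints.append("leukapheresis" if j % 2 == 0 else "pre-lymphodepletion")
            responders.append(bool(r[j]))
            libs.append(float(lib[j]))
    n_total = len(sample_ids)
    r_vec = np.array(responders, dtype=float)
    mean = np.outer(q, np.array(libs)) * np.power(2.0, np.outer(beta, r_vec))
    counts = _nb_draw(rng_counts, mean, config.nb_dispersion)
    counts_df = pd.DataFrame(counts, index=genes, columns=sample_ids)

    surv = simulate_survival(r_vec, config, rng=rng_surv)

    intron_exon = rng_qc.gamma(20.0, 1.0 / 20.0, size=n_total)  # mean 1, well below 3
    bias = rng_qc.normal(1.0, 0.1, size=n_total)
    total_counts = counts.sum(axis=0)

    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cohort": cohorts,
            "timepoint": timepoints,
            "response": ["responder" if r else "non-responder" for r in responders],
            "pfs_time": surv["time"].to_numpy(),
            "pfs_event": surv["event"].to_numpy(),
            "intron_exon_ratio": intron_exon,
            "five_three_bias": bias,
            "total_counts": total_counts,
        }
    )[list(METADATA_COLUMNS)]

    n_fail = int(round(config.qc_fail_fraction * n_total))
    if n_fail:
        fail_idx = rng_qc.choice(n_total, size=n_fail, replace=False)
        for k, i in enumerate(sorted(fail_idx)):
            mode = k % 3
            if mode == 0:
                meta.loc[i, "intron_exon_ratio"] = 5.0
            elif mode == 1:
                meta.loc[i, "five_three_bias"] = 5.0  # far above mean + 3 SD
            else:
                meta.loc[i, "total_counts"] = 50_000
    return counts_df, meta


def simulate_survival(
    x,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Exponential event times with hazard h0 * exp(log_hr * x), censored at
    ``censor_time``.  ``x`` may be a binary group indicator or a score."""
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("covariate values must be finite")
    if config.survival_baseline_hazard <= 0:
        raise ValueError("survival_baseline_hazard must be positive")
    if config.censor_time < 0:
        raise ValueError("censor_time must be non-negative")
    rng = rng if rng is not None else _substream(config.seed, 4)
    hazard = config.survival_baseline_hazard * np.exp(config.survival_log_hr * x)
    raw = rng.exponential(1.0 / hazard)
    event = raw <= config.censor_time
    time = np.minimum(raw, config.censor_time)
    return pd.DataFrame({"time": time, "event": event.astype(int)})


def simulate_single_cell(
    n_samples: int,
    n_clusters: int,
    cells_per_cluster,
    config: SimulationConfig,
    mean_cell_depth: float = 1000.0,
) -> SingleCellMatrix:
    """Poisson single-cell counts with sample and cluster labels.

    ``cells_per_cluster`` is either a single integer (every sample x cluster
    cell count) or an (n_samples, n_clusters) integer array, which lets
    tests plant clusters that are deficient in chosen samples.
    """
    if n_samples <= 0 or n_clusters <= 0:
        raise ValueError("dimensions must be positive")
    layout = np.asarray(cells_per_cluster)
    if layout.ndim == 0:
        layout = np.full((n_samples, n_clusters), int(layout))
    if layout.shape != (n_samples, n_clusters):
        raise ValueError("cells_per_cluster must be scalar or (n_samples, n_clusters)")
    if (layout < 0).any():
        raise ValueError("cell counts must be non-negative")
    rng = _substream(config.seed, 5)
    q = rng.gamma(
        config.baseline_gene_mean_shape, 1.0 / config.baseline_gene_mean_rate, size=config.n_genes
    )
    rate = q / q.sum() * mean_cell_depth
    counts_rows: list[np.ndarray] = []
    cell_ids: list[str] = []
    sample_labels: list[str] = []
    cluster_labels: list[str] = []
    for s in range(n_samples):
        for c in range(n_clusters):
            n_cells = int(layout[s, c])
            if n_cells == 0:
                continue
            counts_rows.append(rng.poisson(rate, size=(n_cells, config.n_genes)))
            for k in range(n_cells):
                cell_ids.append(f"S{s + 1}_K{c + 1}_cell{k + 1}")
                sample_labels.append(f"S{s + 1}")
                cluster_labels.append(f"K{c + 1}")
    counts = np.vstack(counts_rows) if counts_rows else np.zeros((0, config.n_genes), dtype=int)
    return SingleCellMatrix(
        counts=counts,
        genes=config.gene_ids(),
        cell_ids=cell_ids,
        sample_labels=np.array(sample_labels, dtype=object),
        cluster_labels=np.array(cluster_labels, dtype=object),
    )
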