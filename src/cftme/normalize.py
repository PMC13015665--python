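"""Between-sample normalization and expression diagnostics.

Implements trimmed-mean-of-M-values (TMM) scaling factors, log2 counts per
million on the effective library size, pseudobulk aggregation of single-cell
counts, and the variable-gene PCA used as a batch/timepoint diagnostic.

TMM follows the original definition: per-gene log ratios M and average
abundances A against a reference sample, doubly trimmed (30% of M, 5% of A,
by rank), then averaged with weights equal to the inverse asymptotic
binomial variance of M.  Factors are rescaled to geometric mean 1 so they
are a pure between-sample adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import SingleCellMatrix

PSEUDOBULK_DELIMITER = "|"


@dataclass(frozen=True)
class NormalizationConfig:
    """Tuning constants for TMM and log2-CPM.

    m_trim, a_trim
        Fractions of the most extreme M (log-ratio) and A (abundance) values
        discarded from each tail before averaging.
    pseudocount
        Added to counts before the log; keeps zeros finite.
    reference_rule
        ``"upper_quartile"`` picks as reference the sample whose 75th
        percentile count fraction is closest to the mean across samples;
        ``reference_sample`` pins an explicit column instead.
    """

    m_trim: float = 0.30
    a_trim: float = 0.05
    pseudocount: float = 0.5
    reference_rule: str = "upper_quartile"
    reference_sample: str | None = None

    def __post_init__(self) -> None:
        for name, trim in (("m_trim", self.m_trim), ("a_trim", self.a_trim)):
            if not 0 <= trim < 0.5:
                raise ValueError(f"{name} must be in [0, 0.5)")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


@dataclass
class NormalizedMatrix:
    """log2-CPM matrix plus the quantities needed to invert it."""

    logcpm: pd.DataFrame  # genes x samples
    factors: pd.Series  # TMM factor per sample
    lib_sizes: pd.Series  # raw library size per sample
    pseudocount: float

    @property
    def genes(self) -> pd.Index:
        return self.logcpm.index

    @property
    def samples(self) -> pd.Index:
        return self.logcpm.columns

    def detection_mask(self) -> pd.DataFrame:
        """Boolean genes-x-samples mask of entries with a non-zero raw count.

        The zero-count log2-CPM value is sample-specific and known exactly
        (``log2(p * 1e6 / (N_j f_j))``), so detection is recovered without
        the raw counts.
        """
        zero_val = np.log2(self.pseudocount * 1e6 / (self.lib_sizes * self.factors))
        return self.logcpm.gt(zero_val + 1e-9, axis=1)


def filter_expressed(counts: pd.DataFrame) -> pd.DataFrame:
    """Drop genes with zero counts in every sample (no information, break M/A)."""
    return counts.loc[counts.sum(axis=1) > 0]


def _pick_reference(counts: np.ndarray, lib_sizes: np.ndarray, config: NormalizationConfig, columns) -> int:
    if config.reference_sample is not None:
        return list(columns).index(config.reference_sample)
    f75 = np.quantile(counts, 0.75, axis=0) / lib_sizes
    return int(np.argmin(np.abs(f75 - f75.mean())))


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    m_trim: float,
    a_trim: float,
) -> float:
    """Log2 TMM factor of one sample against the reference."""
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        raise ValueError("sample shares no positive genes with the reference")
    o = obs[pos] / n_obs
    r = ref[pos] / n_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    # asymptotic variance of M under binomial sampling
    var = (n_obs - obs[pos]) / (n_obs * obs[pos]) + (n_ref - ref[pos]) / (n_ref * ref[pos])
    n = m.size
    lo_m = np.floor(n * m_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * a_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    return float(np.sum(m[keep] / var[keep]) / np.sum(1.0 / var[keep]))


def tmm_factors(counts: pd.DataFrame, config: NormalizationConfig | None = None) -> pd.Series:
    """TMM scaling factor per sample, geometric mean 1.

    Raises if any sample has an empty library or shares no expressed gene
    with the reference sample.
    """
    config = config or NormalizationConfig()
    mat = counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if (lib <= 0).any():
        bad = counts.columns[lib <= 0][0]
        raise ValueError(f"sample {bad!r} has non-positive library size")
    ref_idx = _pick_reference(mat, lib, config, counts.columns)
    log_factors = np.zeros(mat.shape[1])
    for j in range(mat.shape[1]):
        if j == ref_idx:
            continue
        try:
            log_factors[j] = _tmm_pair(mat[:, j], mat[:, ref_idx], lib[j], lib[ref_idx], config.m_trim, config.a_trim)
        except ValueError as exc:
            raise ValueError(f"sample {counts.columns[j]!r}: {exc}") from exc
    log_factors -= log_factors.mean()  # geometric mean 1
    return pd.Series(2.0 ** log_factors, index=counts.columns, name="tmm_factor")


def log2_cpm(
    counts: pd.DataFrame,
    factors: pd.Series | None = None,
    config: NormalizationConfig | None = None,
) -> NormalizedMatrix:
    """log2 counts per million on the effective library size N_j * f_j.

    entry = log2((c + p) / (N_j f_j) * 1e6); strictly increasing in counts
    and invariant to jointly rescaling (c + p) and the effective library.
    """
    config = config or NormalizationConfig()
    lib = counts.sum(axis=0).astype(float)
    if factors is None:
        factors = pd.Series(1.0, index=counts.columns, name="tmm_factor")
    factors = factors.reindex(counts.columns)
    eff = lib * factors
    if (eff <= 0).any() or eff.isna().any():
        bad = counts.columns[(eff <= 0) | eff.isna()][0]
        raise ValueError(f"sample {bad!r} has zero effective library size")
    logcpm = np.log2((counts + config.pseudocount).div(eff, axis=1) * 1e6)
    return NormalizedMatrix(
        logcpm=logcpm,
        factors=factors,
        lib_sizes=lib.rename("lib_size"),
        pseudocount=config.pseudocount,
    )


def normalize_counts(counts: pd.DataFrame, config: NormalizationConfig | None = None) -> NormalizedMatrix:
    """Convenience: drop never-expressed genes, compute TMM, return log2-CPM."""
    counts = filter_expressed(counts)
    factors = tmm_factors(counts, config)
    return log2_cpm(counts, factors, config)


def _escape_label(label: str) -> str:
    return str(label).replace(PSEUDOBULK_DELIMITER, PSEUDOBULK_DELIMITER * 2)


@dataclass
class PseudobulkResult:
    counts: pd.DataFrame  # genes x (sample|cluster) columns
    cluster_report: pd.DataFrame  # cluster, n_deficient_samples, excluded
    excluded_clusters: list[str] = field(default_factory=list)


def pseudobulk(
    sc: SingleCellMatrix,
    min_cells: int = 10,
    max_deficient_samples: int = 3,
) -> PseudobulkResult:
    """Sum single-cell counts within each sample x cluster.

    A cluster is flagged excluded for cell-type-specific analyses when the
    number of samples holding fewer than ``min_cells`` of its cells exceeds
    ``max_deficient_samples`` (strictly).  Excluded clusters stay in the
    matrix; exclusion is reported, not silently applied.
    """
    samples = pd.unique(sc.sample_labels)
    clusters = pd.unique(sc.cluster_labels)
    columns: dict[str, np.ndarray] = {}
    cell_tally = pd.DataFrame(0, index=samples, columns=clusters)
    for s in samples:
        in_s = sc.sample_labels == s
        for c in clusters:
            mask = in_s & (sc.cluster_labels == c)
            n = int(mask.sum())
            cell_tally.loc[s, c] = n
            if n:
                key = f"{_escape_label(s)}{PSEUDOBULK_DELIMITER}{_escape_label(c)}"
                columns[key] = sc.counts[mask].sum(axis=0)
    out = pd.DataFrame(columns, index=sc.genes, dtype=np.int64)
    deficient = (cell_tally < min_cells).sum(axis=0)
    report = pd.DataFrame(
        {
            "cluster": clusters,
            "n_deficient_samples": [int(deficient[c]) for c in clusters],
            "excluded": [bool(deficient[c] > max_deficient_samples) for c in clusters],
        }
    )
    excluded = [str(c) for c in clusters if deficient[c] > max_deficient_samples]
    return PseudobulkResult(counts=out, cluster_report=report, excluded_clusters=excluded)


def select_variable_genes(norm: NormalizedMatrix, n: int = 500) -> list[str]:
    """Top ``n`` genes by variance of log2-CPM across samples.

    Deterministic: ties broken by gene identifier.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n > len(norm.genes):
        raise ValueError(f"requested {n} genes but matrix has {len(norm.genes)}")
    var = norm.logcpm.var(axis=1, ddof=1)
    order = sorted(norm.genes, key=lambda g: (-var[g], g))
    return order[:n]


def pca_embed(
    norm: NormalizedMatrix,
    genes: list[str] | None = None,
    n_components: int = 2,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on (a subset of) genes via SVD of the centered matrix.

    Returns the sample embedding (samples x components) and the
    explained-variance fractions.  Sign convention: within each component,
    the gene loading with the largest magnitude is made positive.
    """
    sub = norm.logcpm if genes is None else norm.logcpm.loc[list(genes)]
    x = sub.to_numpy(dtype=float).T  # samples x genes
    if n_components > min(x.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    centered = x - x.mean(axis=0, keepdims=True)
    total_var = (centered**2).sum()
    if total_var == 0:
        raise ValueError("all-constant input has no principal components")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    for k in range(n_components):
        pivot = np.argmax(np.abs(vt[k]))
        if vt[k, pivot] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    embedding = u[:, :n_components] * s[:n_components]
    evr = s[:n_components] ** 2 / total_var
    emb = pd.DataFrame(
        embedding,
        index=sub.columns,
        columns=[f"PC{k + 1}" for k in range(n_components)],
    )
    return emb, evr
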