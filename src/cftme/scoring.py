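"""Expression-level-controlled gene-set module scores.

For each target gene set the per-sample score is the mean log2-CPM over the
target genes minus the mean over a background control multiset drawn to
match the targets' expression-level distribution: genes are ranked by mean
log2-CPM and cut into equal-frequency bins, and each target gene contributes
``controls_per_gene`` genes drawn uniformly from its own bin.  Raw scores
are then min-max rescaled to the unit interval.

The control draw is seed-controlled and shared across samples (one manifest
per target set), so scores are exactly reproducible and auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GeneSet
from .normalize import NormalizedMatrix


@dataclass(frozen=True)
class ScoringConfig:
    n_bins: int = 25
    controls_per_gene: int = 100
    seed: int = 0
    rescale: bool = True

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.controls_per_gene < 1:
            raise ValueError("controls_per_gene must be >= 1")


@dataclass
class ModuleScoreTable:
    """Per-sample raw and rescaled scores plus the control-gene audit trail."""

    table: pd.DataFrame  # sample_id index; <set>_raw and <set>_scaled columns
    manifests: dict[str, dict] = field(default_factory=dict)


def bin_genes_by_expression(norm: NormalizedMatrix, n_bins: int = 25) -> pd.Series:
    """Assign every gene to one of ``n_bins`` equal-frequency expression bins.

    Genes are ranked by mean log2-CPM across samples (ties broken by gene
    identifier) and cut into bins of near-equal occupancy; bin 0 holds the
    lowest-expressed genes.
    """
    genes = list(norm.genes)
    if len(genes) < n_bins:
        raise ValueError(f"{len(genes)} genes cannot fill {n_bins} bins")
    means = norm.logcpm.mean(axis=1)
    ranked = sorted(genes, key=lambda g: (means[g], g))
    assignment = pd.Series(0, index=pd.Index(ranked), dtype=int)
    for b, chunk in enumerate(np.array_split(np.arange(len(ranked)), n_bins)):
        assignment.iloc[chunk] = b
    return assignment.reindex(norm.genes)


def sample_control_genes(
    target_set: GeneSet,
    bins: pd.Series,
    controls_per_gene: int = 100,
    seed: int = 0,
) -> list[str]:
    """Draw the expression-matched control multiset for one target set.

    For each target gene, ``controls_per_gene`` genes are drawn uniformly
    from that gene's expression bin — without replacement when the bin is
    large enough, with replacement otherwise.  Target genes themselves stay
    eligible as controls.  Fully determined by ``seed``.
    """
    missing = [g for g in target_set.members if g not in bins.index]
    if missing:
        raise KeyError(f"target genes absent from bin map: {missing}")
    rng = np.random.default_rng(seed)
    by_bin: dict[int, np.ndarray] = {
        b: np.array(sorted(idx)) for b, idx in bins.groupby(bins).groups.items()
    }
    controls: list[str] = []
    for gene in target_set.members:
        pool = by_bin[int(bins[gene])]
        replace = len(pool) < controls_per_gene
        controls.extend(rng.choice(pool, size=controls_per_gene, replace=replace).tolist())
    return controls


def module_score(
    norm: NormalizedMatrix,
    target_genes: list[str],
    controls: list[str],
) -> pd.Series:
    """Raw per-sample score: mean target log2-CPM minus mean control log2-CPM."""
    if not target_genes:
        raise ValueError("empty effective target set")
    target_mean = norm.logcpm.loc[list(target_genes)].mean(axis=0)
    control_mean = norm.logcpm.loc[list(controls)].mean(axis=0)
    return (target_mean - control_mean).rename("raw_score")


def rescale_unit(raw: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Min-max rescale to [0, 1]; a constant vector maps to 0.5 with a warning."""
    values = np.asarray(raw, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("non-finite values cannot be rescaled")
    lo, hi = values.min(), values.max()
    if hi == lo:
        warnings.warn("constant scores: min-max rescale is degenerate, mapping all to 0.5")
        out = np.full_like(values, 0.5)
    else:
        out = (values - lo) / (hi - lo)
    if isinstance(raw, pd.Series):
        return pd.Series(out, index=raw.index, name=raw.name)
    return out


def score_archetypes(
    norm: NormalizedMatrix,
    gene_sets: list[GeneSet],
    config: ScoringConfig | None = None,
) -> ModuleScoreTable:
    """Score every gene set against the matrix: bin once, then draw controls
    and score per set.

    Target genes missing from the matrix are dropped with a warning and
    recorded in the per-set manifest; an entirely absent set is an error.
    Per-set control draws derive their seed from ``(config.seed, set index)``
    so adding or reordering sets does not perturb other sets' draws beyond
    their index.
    """
    config = config or ScoringConfig()
    bins = bin_genes_by_expression(norm, config.n_bins)
    table = pd.DataFrame(index=norm.samples)
    table.index.name = "sample_id"
    manifests: dict[str, dict] = {}
    for i, gs in enumerate(gene_sets):
        present = [g for g in gs.members if g in norm.genes]
        absent = [g for g in gs.members if g not in norm.genes]
        if absent:
            warnings.warn(f"gene set {gs.name!r}: {len(absent)} target genes absent from matrix")
        if not present:
            raise ValueError(f"gene set {gs.name!r} has no genes in the matrix")
        effective = GeneSet(name=gs.name, members=tuple(present), description=gs.description)
        set_seed = int(np.random.SeedSequence([config.seed, i]).generate_state(1)[0] % (2**31))
        controls = sample_control_genes(effective, bins, config.controls_per_gene, set_seed)
        raw = module_score(norm, present, controls)
        table[f"{gs.name}_raw"] = raw
        if config.rescale:
            table[f"{gs.name}_scaled"] = rescale_unit(raw)
        manifests[gs.name] = {
            "targets_used": present,
            "targets_missing": absent,
            "controls": controls,
            "seed": set_seed,
        }
    return ModuleScoreTable(table=table, manifests=manifests)
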