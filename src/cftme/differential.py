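"""Per-gene differential abundance and cross-cohort concordance.

Log2 fold changes are differences of group means on the log2-CPM scale
(responders minus non-responders); the per-gene test is a two-sided
Mann-Whitney U on log2-CPM, corrected for multiplicity with
Benjamini-Hochberg.  This is a deliberately simple independent-transcript
model: it preserves the discovery/validation design (two cohorts discover,
one validates) while avoiding a negative-binomial GLM, and its estimator is
exactly testable against brute-force group means.

Cross-cohort concordance is the Pearson correlation between the discovery
log2 fold changes of BH-significant genes and the fold changes of the same
genes estimated independently in the validation cohort.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .normalize import NormalizedMatrix
from .survival import mann_whitney_u


def log2_fold_change(norm: NormalizedMatrix, labels) -> pd.Series:
    """Per-gene mean log2-CPM difference: group True minus group False."""
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both groups must be non-empty")
    pos = norm.logcpm.loc[:, labels].mean(axis=1)
    neg = norm.logcpm.loc[:, ~labels].mean(axis=1)
    return (pos - neg).rename("log2_fold_change")


def per_gene_test(norm: NormalizedMatrix, labels) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per gene on log2-CPM.

    Genes whose values are all tied across both groups get p = 1 and a
    ``degenerate`` flag.  Requires >= 3 samples per group.
    """
    labels = np.asarray(labels).astype(bool)
    if labels.sum() < 3 or (~labels).sum() < 3:
        raise ValueError("per-gene test needs >= 3 samples per group")
    mat = norm.logcpm.to_numpy(dtype=float)
    pvals = np.ones(mat.shape[0])
    degenerate = np.zeros(mat.shape[0], dtype=bool)
    for g in range(mat.shape[0]):
        row = mat[g]
        if np.all(row == row[0]):
            degenerate[g] = True
            continue
        pvals[g] = mann_whitney_u(row[labels], row[~labels]).p_value
    return pd.DataFrame({"p_value": pvals, "degenerate": degenerate}, index=norm.genes)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def differential_analysis(norm: NormalizedMatrix, labels) -> pd.DataFrame:
    """Full per-gene table: log2FC, raw p, BH-adjusted p, degeneracy flag."""
    fc = log2_fold_change(norm, labels)
    tests = per_gene_test(norm, labels)
    return pd.DataFrame(
        {
            "log2_fold_change": fc,
            "p_value": tests["p_value"],
            "adjusted_p": bh_adjust(tests["p_value"].to_numpy()),
            "degenerate": tests["degenerate"],
        },
        index=norm.genes,
    )


def pearson_correlation(x, y) -> float:
    """Product-moment correlation of two equal-length non-constant vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("correlation needs >= 3 points")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector has undefined correlation")
    return float(stats.pearsonr(x, y).statistic)


def cross_cohort_concordance(
    discovery: pd.DataFrame,
    validation_fc: pd.Series,
    adj_p_threshold: float = 0.1,
) -> tuple[float, int]:
    """Pearson r between discovery-significant log2FCs and validation log2FCs.

    ``discovery`` is a ``differential_analysis`` table; genes with adjusted
    p below the threshold are inner-joined on gene identifier with the
    validation fold-change vector.
    """
    significant = discovery.loc[discovery["adjusted_p"] < adj_p_threshold, "log2_fold_change"]
    joined = pd.concat([significant, validation_fc], axis=1, join="inner")
    if len(joined) < 3:
        raise ValueError(f"only {len(joined)} genes overlap after thresholding; need >= 3")
    r = pearson_correlation(joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy())
    return r, len(joined)
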