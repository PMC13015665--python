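"""Sample-level quality filters for cfRNA libraries.

Three rules, all evaluated on precomputed summary metrics (never on the
counts themselves):

* DNA contamination — intron-to-exon read ratio strictly above a cutoff.
* RNA degradation — 5'/3' coverage bias strictly more than ``k`` standard
  deviations above the reference-group mean, with the mean and SD frozen on
  the pre-filter distribution (single pass, no re-computation).
* Sequencing depth — strictly fewer than a minimum number of
  feature-aligned reads.

A discarded sample carries every reason code that applies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

REASON_DNA = "dna_contamination"
REASON_DEGRADATION = "rna_degradation"
REASON_DEPTH = "low_depth"

_METRIC_FIELDS = ("intron_exon_ratio", "five_three_bias", "total_counts")


@dataclass(frozen=True)
class QCThresholds:
    """Cutoffs for the three library-quality rules (strict inequalities)."""

    max_intron_exon_ratio: float = 3.0
    bias_sd_multiplier: float = 3.0
    min_total_counts: int = 100_000

    def __post_init__(self) -> None:
        if self.max_intron_exon_ratio <= 0 or self.bias_sd_multiplier <= 0:
            raise ValueError("QC thresholds must be positive")
        if self.min_total_counts <= 0:
            raise ValueError("min_total_counts must be positive")


@dataclass
class QCResult:
    kept: list[str]
    discarded: pd.DataFrame  # columns: sample_id, reasons (';'-joined codes)

    @property
    def discarded_ids(self) -> list[str]:
        return list(self.discarded["sample_id"])


def apply_qc_filters(
    metadata: pd.DataFrame,
    thresholds: QCThresholds | None = None,
    bias_reference_group: str = "all",
) -> QCResult:
    """Apply the three sample filters to a metadata table.

    Parameters
    ----------
    metadata
        Table with at least ``sample_id`` and the three QC metric columns.
    thresholds
        Cutoffs; defaults follow the printed rules (ratio > 3, bias > mean +
        3 SD, depth < 100,000).
    bias_reference_group
        ``"all"`` — degradation statistics over the full input set (default),
        or ``"cohort"`` — computed within each cohort.

    Returns
    -------
    QCResult with kept sample IDs (input order) and a table of discarded
    samples, each annotated with all applicable reason codes.
    """
    thresholds = thresholds or QCThresholds()
    for field in _METRIC_FIELDS:
        if field not in metadata.columns:
            raise ValueError(f"metadata missing QC metric column {field!r}")
        bad = metadata[metadata[field].isna() | ~np.isfinite(metadata[field].astype(float))]
        if len(bad):
            sid = bad["sample_id"].iloc[0]
            raise ValueError(f"sample {sid!r}: QC metric {field!r} is missing or non-finite")
    if bias_reference_group not in ("all", "cohort"):
        raise ValueError("bias_reference_group must be 'all' or 'cohort'")

    bias = metadata["five_three_bias"].astype(float)
    # Reference statistics frozen on the pre-filter distribution.
    if bias_reference_group == "cohort":
        mean = metadata.groupby("cohort")["five_three_bias"].transform("mean")
        sd = metadata.groupby("cohort")["five_three_bias"].transform(lambda x: x.std(ddof=1))
    else:
        mean = pd.Series(bias.mean(), index=metadata.index)
        sd = pd.Series(bias.std(ddof=1), index=metadata.index)
    sd = sd.fillna(0.0)

    fails_dna = metadata["intron_exon_ratio"].astype(float) > thresholds.max_intron_exon_ratio
    fails_bias = bias > mean + thresholds.bias_sd_multiplier * sd
    fails_depth = metadata["total_counts"].astype(float) < thresholds.min_total_counts

    kept: list[str] = []
    rows: list[dict] = []
    for i, sid in enumerate(metadata["sample_id"]):
        reasons = []
        if fails_dna.iloc[i]:
            reasons.append(REASON_DNA)
        if fails_bias.iloc[i]:
            reasons.append(REASON_DEGRADATION)
        if fails_depth.iloc[i]:
            reasons.append(REASON_DEPTH)
        if reasons:
            rows.append({"sample_id": sid, "reasons": ";".join(reasons)})
        else:
            kept.append(sid)
    discarded = pd.DataFrame(rows, columns=["sample_id", "reasons"])
    return QCResult(kept=kept, discarded=discarded)


def qc_report(result: QCResult, metadata: pd.DataFrame) -> pd.DataFrame:
    """Two-column per-sample report: sample_id, reason codes or ``pass``."""
    reason_map = dict(zip(result.discarded["sample_id"], result.discarded["reasons"]))
    return pd.DataFrame(
        {
            "sample_id": metadata["sample_id"],
            "qc": [reason_map.get(s, "pass") for s in metadata["sample_id"]],
        }
    )
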