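"""End-to-end orchestration: qc -> normalize -> score -> survival -> cv ->
differential, with a JSON manifest recording config, seed, per-stage output
checksums and collected warnings."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cv as cv_mod
from . import differential as diff_mod
from . import io as io_mod
from . import normalize as norm_mod
from . import qc as qc_mod
from . import scoring as scoring_mod
from . import survival as surv_mod

STAGES = ("qc", "normalize", "score", "survival", "cv", "differential")


@dataclass
class PipelineConfig:
    counts_path: str
    metadata_path: str
    outdir: str
    gmt_path: str | None = None  # None -> packaged archetype sets
    counts_format: str = "tsv"
    qc_thresholds: qc_mod.QCThresholds = field(default_factory=qc_mod.QCThresholds)
    bias_reference_group: str = "all"
    norm_config: norm_mod.NormalizationConfig = field(default_factory=norm_mod.NormalizationConfig)
    scoring_config: scoring_mod.ScoringConfig = field(default_factory=scoring_mod.ScoringConfig)
    cv_config: cv_mod.CVConfig = field(default_factory=cv_mod.CVConfig)
    feature_sets: list[str] = field(default_factory=lambda: ["all", "LN", "FMAC", "TEX"])
    survival_score: str = "LN_scaled"
    discovery_cohorts: list[str] = field(default_factory=lambda: ["cohort1", "cohort2"])
    validation_cohort: str = "cohort3"
    adj_p_threshold: float = 0.1
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())  # YAML is a JSON superset
        raw.update(overrides)
        for key, sub in (
            ("qc_thresholds", qc_mod.QCThresholds),
            ("norm_config", norm_mod.NormalizationConfig),
            ("scoring_config", scoring_mod.ScoringConfig),
            ("cv_config", cv_mod.CVConfig),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)

    def validate_paths(self) -> None:
        for name, p in (("counts", self.counts_path), ("metadata", self.metadata_path), ("gene sets", self.gmt_path)):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_dict(config: PipelineConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    return convert(config)


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run all six stages, writing outputs and a manifest under ``outdir``.

    Any stage error aborts with the stage name attached.  Reruns with the
    same config and seed produce byte-identical outputs.
    """
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config": _config_dict(config),
        "stages": {},
        "warnings": [],
        "outputs": {},
    }
    caught: list[str] = []

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"][stage] = "complete"
        for p in paths:
            manifest["outputs"][p.name] = _sha256(p)

    def run_stage(stage, fn):
        try:
            with warnings.catch_warnings(record=True) as w:
                warnings.simplefilter("always")
                result = fn()
            for item in w:
                msg = f"{stage}: {item.message}"
                if msg not in caught:
                    caught.append(msg)
            return result
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # --- qc ---
    def stage_qc():
        counts = io_mod.read_count_matrix(config.counts_path, format=config.counts_format)
        meta = io_mod.read_metadata(config.metadata_path)
        result = qc_mod.apply_qc_filters(meta, config.qc_thresholds, config.bias_reference_group)
        report = qc_mod.qc_report(result, meta)
        report.to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
        kept_meta = meta[meta["sample_id"].isin(result.kept)].reset_index(drop=True)
        kept_counts = counts[result.kept]
        record("qc", outdir / "qc_report.tsv")
        return kept_counts, kept_meta

    counts, meta = run_stage("qc", stage_qc)
    labels = (meta["response"] == "responder").to_numpy()

    # --- normalize ---
    def stage_normalize():
        expressed = norm_mod.filter_expressed(counts)
        factors = norm_mod.tmm_factors(expressed, config.norm_config)
        norm = norm_mod.log2_cpm(expressed, factors, config.norm_config)
        factors.rename("tmm_factor").to_frame().to_csv(outdir / "tmm_factors.tsv", sep="\t", index_label="sample_id")
        norm.logcpm.to_csv(outdir / "logcpm.tsv", sep="\t", index_label="gene_id")
        record("normalize", outdir / "tmm_factors.tsv", outdir / "logcpm.tsv")
        return norm

    norm = run_stage("normalize", stage_normalize)

    # --- score ---
    def stage_score():
        if config.gmt_path is None:
            sets = io_mod.archetype_gene_sets()
        else:
            sets = io_mod.read_gene_sets(config.gmt_path)
        scored = scoring_mod.score_archetypes(norm, sets, config.scoring_config)
        scored.table.to_csv(outdir / "module_scores.tsv", sep="\t")
        (outdir / "control_manifest.json").write_text(json.dumps(scored.manifests, indent=1))
        record("score", outdir / "module_scores.tsv", outdir / "control_manifest.json")
        return sets, scored

    gene_sets, scored = run_stage("score", stage_score)

    # --- survival ---
    def stage_survival():
        col = config.survival_score
        if col not in scored.table.columns:
            raise ValueError(f"survival_score column {col!r} not in score table")
        scores = scored.table[col].to_numpy()
        result = surv_mod.survival_by_median_score(scores, meta["pfs_time"], meta["pfs_event"])
        result["km_high"].to_csv(outdir / "km_high.tsv", sep="\t", index=False)
        result["km_low"].to_csv(outdir / "km_low.tsv", sep="\t", index=False)
        payload = {
            "score_column": col,
            "logrank": dataclasses.asdict(result["logrank"]),
            "cox": dataclasses.asdict(result["cox"]),
            "mann_whitney_by_response": dataclasses.asdict(
                surv_mod.mann_whitney_u(scores[labels], scores[~labels])
            ),
        }
        (outdir / "survival.json").write_text(json.dumps(payload, indent=1))
        record("survival", outdir / "km_high.tsv", outdir / "km_low.tsv", outdir / "survival.json")

    run_stage("survival", stage_survival)

    # --- cv ---
    def stage_cv():
        by_name = {s.name: s for s in gene_sets}
        summaries: dict[str, dict] = {}
        rows = []
        rec_frames = []
        if not config.feature_sets:
            pd.DataFrame(columns=["feature_set", "iteration", "auc"]).to_csv(outdir / "cv_iterations.tsv", sep="\t", index=False)
            pd.DataFrame(columns=["feature_set", "feature", "selection_frequency"]).to_csv(outdir / "feature_recurrence.tsv", sep="\t", index=False)
            (outdir / "auc_summary.json").write_text("{}")
            record("cv", outdir / "cv_iterations.tsv", outdir / "feature_recurrence.tsv", outdir / "auc_summary.json")
            return
        for fs in config.feature_sets:
            feature_set = "all" if fs == "all" else by_name[fs]
            results = cv_mod.monte_carlo_cv(norm, labels, feature_set, config.cv_config)
            summaries[fs] = cv_mod.auc_summary(results)
            for r in results:
                rows.append(
                    {
                        "feature_set": fs,
                        "iteration": r.iteration,
                        "auc": r.auc,
                        "selected_lambda": r.selected_lambda,
                        "n_nonzero": len(r.coefficients),
                        "valid": r.valid,
                    }
                )
            rec = cv_mod.recurrence_table(cv_mod.feature_recurrence(results))
            rec.insert(0, "feature_set", fs)
            rec_frames.append(rec)
        pd.DataFrame(rows).to_csv(outdir / "cv_iterations.tsv", sep="\t", index=False)
        pd.concat(rec_frames).to_csv(outdir / "feature_recurrence.tsv", sep="\t", index=False)
        (outdir / "auc_summary.json").write_text(json.dumps(summaries, indent=1))
        record(
            "cv",
            outdir / "cv_iterations.tsv",
            outdir / "feature_recurrence.tsv",
            outdir / "auc_summary.json",
        )

    run_stage("cv", stage_cv)

    # --- differential ---
    def stage_differential():
        disc_mask = meta["cohort"].isin(config.discovery_cohorts).to_numpy()
        val_mask = (meta["cohort"] == config.validation_cohort).to_numpy()
        if disc_mask.sum() == 0 or val_mask.sum() == 0:
            raise ValueError("discovery or validation cohort is empty")
        disc_samples = meta.loc[disc_mask, "sample_id"]
        val_samples = meta.loc[val_mask, "sample_id"]
        disc_counts = norm_mod.filter_expressed(counts[disc_samples])
        val_counts = norm_mod.filter_expressed(counts[val_samples])
        disc_norm = norm_mod.log2_cpm(disc_counts, norm_mod.tmm_factors(disc_counts, config.norm_config), config.norm_config)
        val_norm = norm_mod.log2_cpm(val_counts, norm_mod.tmm_factors(val_counts, config.norm_config), config.norm_config)
        table = diff_mod.differential_analysis(disc_norm, labels[disc_mask])
        val_fc = diff_mod.log2_fold_change(val_norm, labels[val_mask])
        table.to_csv(outdir / "differential.tsv", sep="\t", index_label="gene_id")
        r, n = diff_mod.cross_cohort_concordance(table, val_fc, config.adj_p_threshold)
        n_significant = int((table["adjusted_p"] < config.adj_p_threshold).sum())
        (outdir / "concordance.json").write_text(
            json.dumps(
                {
                    "pearson_r": r,
                    "n_genes_compared": n,
                    "n_significant": n_significant,
                    "adj_p_threshold": config.adj_p_threshold,
                },
                indent=1,
            )
        )
        record("differential", outdir / "differential.tsv", outdir / "concordance.json")

    run_stage("differential", stage_differential)

    manifest["warnings"] = caught
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def generate_report(manifest: dict | str | Path, outdir: str | Path | None = None) -> str:
    """Assemble a markdown summary from a completed run's outputs.

    Regeneration from the same manifest is idempotent.
    """
    if not isinstance(manifest, dict):
        manifest = json.loads(Path(manifest).read_text())
    missing = [s for s in STAGES if manifest.get("stages", {}).get(s) != "complete"]
    if missing:
        raise ValueError(f"manifest incomplete; missing stages: {missing}")
    outdir = Path(outdir) if outdir is not None else Path(manifest["config"]["outdir"])

    lines = ["# cfTME pipeline report", "", f"Seed: {manifest['seed']}", ""]
    qc = pd.read_csv(outdir / "qc_report.tsv", sep="\t")
    lines += [
        "## Sample QC",
        f"- {int((qc['qc'] == 'pass').sum())} of {len(qc)} samples pass",
        "",
    ]
    surv = json.loads((outdir / "survival.json").read_text())
    lines += [
        "## Survival stratification",
        f"- score: {surv['score_column']}",
        f"- log-rank chi2 = {surv['logrank']['statistic']:.3f}, p = {surv['logrank']['p_value']:.4g}",
        f"- Cox HR (high vs low) = {surv['cox']['hazard_ratio']:.3f}, Wald p = {surv['cox']['p_value']:.4g}",
        f"- Mann-Whitney responder vs non-responder p = {surv['mann_whitney_by_response']['p_value']:.4g}",
        "",
    ]
    auc_path = outdir / "auc_summary.json"
    summaries = json.loads(auc_path.read_text()) if auc_path.exists() else {}
    if summaries:
        lines += ["## Monte Carlo CV (median test AUC)"]
        for fs, s in summaries.items():
            lines.append(f"- {fs}: median AUC {s['median_auc']:.3f} (IQR {s['q1_auc']:.3f}-{s['q3_auc']:.3f}, {s['n_valid']} valid iterations)")
        rec = pd.read_csv(outdir / "feature_recurrence.tsv", sep="\t")
        top = rec.sort_values(["feature_set", "selection_frequency"], ascending=[True, False]).groupby("feature_set").head(3)
        lines += ["", "Top recurrent features per set:"]
        for _, row in top.iterrows():
            lines.append(f"- {row['feature_set']}: {row['feature']} ({100 * row['selection_frequency']:.1f}%)")
        lines.append("")
    else:
        lines += ["## Monte Carlo CV", "- no feature sets configured; section omitted", ""]
    conc = json.loads((outdir / "concordance.json").read_text())
    lines += [
        "## Differential abundance and concordance",
        f"- {conc['n_significant']} genes at BH-adjusted p < {conc['adj_p_threshold']}",
        f"- cross-cohort Pearson r = {conc['pearson_r']:.3f} over {conc['n_genes_compared']} genes",
        "",
    ]
    return "\n".join(lines)
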