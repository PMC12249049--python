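"""End-to-end pipeline driver: match -> preprocess -> DE ensemble ->
consensus -> targets, with a machine-readable run manifest.

Every stage writes TSV artifacts into the output directory; the manifest
records seeds, thresholds, and sample/gene counts at each transition so the
bookkeeping (samples in = matched + excluded + outliers removed) can always
be reconciled. All randomness flows from the configured seed; a config
without one fails fast.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .consensus import RMCConfig, RMCModel
from .de import DesignSpec, MANDATORY_METHODS
from .matching import PropensityMatch
from .preprocess import batch_adjust, detect_outliers, normalize
from .targets import associate_targets, correlate_clinical, select_targets, \
    stratify_clinical

logger = logging.getLogger("rmcseq")

__all__ = ["PipelineConfig", "run_pipeline", "intersect_biomarkers"]


@dataclass
class PipelineConfig:
    counts_path: str
    samples_path: str
    out_dir: str
    seed: int | None = None
    annotation_path: str | None = None
    counts_format: str = "tsv"
    covariates: list[str] = field(default_factory=lambda: ["age"])
    caliper_sd: float | None = None
    batch_col: str | None = None
    outlier_method: str = "umap"  # umap | pca | off
    methods: list[str] = field(default_factory=lambda: list(MANDATORY_METHODS))
    fdr_threshold: float = 0.05
    effect_threshold: float = 0.40
    low_count_threshold: float = 10.0
    g_min: float = 0.3
    folds: int = 5
    stratify: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("pipeline config requires an explicit seed")

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) if path.endswith((".yaml", ".yml")) \
                else json.load(fh)
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written as JSON)."""
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {},
                      "thresholds": {"fdr": config.fdr_threshold,
                                     "effect": config.effect_threshold,
                                     "low_count": config.low_count_threshold}}
    stage = "load"
    try:
        counts = rio.read_counts(config.counts_path, config.counts_format)
        samples = rio.read_samples(config.samples_path)
        annotation = (rio.read_annotation(config.annotation_path)
                      if config.annotation_path else None)
        shared = [s for s in counts.sample_ids if s in set(samples.sample_ids)]
        counts = counts.subset_samples(shared)
        samples = samples.subset(shared)
        manifest["stages"]["load"] = {"n_genes": counts.n_genes,
                                      "n_samples": counts.n_samples}
        logger.info("load: %d genes x %d samples", counts.n_genes, counts.n_samples)

        stage = "match"
        res = PropensityMatch(samples, config.covariates).fit(config.caliper_sd)
        matched = res.match.matched_cases + res.match.matched_controls
        res.match.to_frame().to_csv(_p(config, "pairs.tsv"), sep="\t", index=False)
        pd.DataFrame({"sample_id": res.match.excluded_controls + res.match.excluded_cases}
                     ).to_csv(_p(config, "excluded.tsv"), sep="\t", index=False)
        res.balance.table.to_csv(_p(config, "balance.tsv"), sep="\t")
        counts = counts.subset_samples(matched)
        samples = samples.subset(matched)
        manifest["stages"]["match"] = {
            "pairs": len(res.match.pairs),
            "excluded_controls": len(res.match.excluded_controls),
            "excluded_cases": len(res.match.excluded_cases)}
        logger.info("match: %d pairs, %d controls excluded", len(res.match.pairs),
                    len(res.match.excluded_controls))

        stage = "preprocess"
        if config.batch_col:
            counts = batch_adjust(counts, samples.data[config.batch_col],
                                  samples.condition)
        normmat = normalize(counts, "size_factor")
        keep_genes = [g for g, m in zip(counts.gene_ids,
                                        normmat.values.mean(axis=1))
                      if m >= config.low_count_threshold]
        n_outliers = 0
        if config.outlier_method != "off":
            expressed = counts.subset_genes(keep_genes)
            rep = detect_outliers(normalize(expressed, "log2cpm"),
                                  method=config.outlier_method, seed=config.seed)
            rep.embedding.to_csv(_p(config, "embedding.tsv"), sep="\t")
            pd.DataFrame({"sample_id": rep.outliers}).to_csv(
                _p(config, "outliers.tsv"), sep="\t", index=False)
            if rep.outliers:
                keep = [s for s in counts.sample_ids if s not in set(rep.outliers)]
                counts = counts.subset_samples(keep)
                samples = samples.subset(keep)
            n_outliers = len(rep.outliers)
        normmat = normalize(counts, "size_factor")
        pd.DataFrame({"sample_id": counts.sample_ids, "size_factor": normmat.factors}
                     ).to_csv(_p(config, "size_factors.tsv"), sep="\t", index=False)
        manifest["stages"]["preprocess"] = {"outliers_removed": n_outliers,
                                            "n_samples": counts.n_samples}

        stage = "consensus"
        design = DesignSpec.from_samples(samples, counts.sample_ids,
                                         seed=config.seed)
        cfg = RMCConfig(config.fdr_threshold, config.effect_threshold,
                        config.low_count_threshold)
        fit = RMCModel(counts, design, methods=config.methods, config=cfg).fit()
        for name, mres in fit.method_results.items():
            mres.table.to_csv(_p(config, f"de_{name}.tsv"), sep="\t")
        fit.consensus.table.to_csv(_p(config, "consensus.tsv"), sep="\t")
        fit.consensus.class_counts().rename("count").to_csv(
            _p(config, "class_counts.tsv"), sep="\t")
        venn, flow = fit.compare_with(config.methods[0])
        pd.Series(venn).rename("count").to_csv(_p(config, "venn.tsv"), sep="\t")
        flow.to_csv(_p(config, "sankey.tsv"), sep="\t")
        manifest["stages"]["consensus"] = {
            "class_counts": fit.consensus.class_counts().to_dict(),
            "degs": int(fit.consensus.table["is_deg"].sum()),
            "rescued": int(fit.consensus.table["rescued"].sum())}
        logger.info("consensus: %s", manifest["stages"]["consensus"])

        stage = "targets"
        targets = select_targets(fit.consensus, fit.normmat, design.is_case,
                                 annotation, g_min=config.g_min,
                                 folds=config.folds, seed=config.seed)
        targets.to_csv(_p(config, "targets.tsv"), sep="\t")
        manifest["stages"]["targets"] = {
            "candidates": int(len(targets)),
            "selected": int(targets["selected"].sum()) if len(targets) else 0}
        corr_rows = []
        clin = samples.data
        for xa, xb in (("cag", "onset_age"), ("cag", "death_age"),
                       ("onset_age", "death_age")):
            if xa in clin.columns and xb in clin.columns:
                sub = clin[[xa, xb]].dropna()
                if len(sub) >= 3 and sub[xa].var() > 0 and sub[xb].var() > 0:
                    r, p, _line = correlate_clinical(sub[xa], sub[xb])
                    corr_rows.append({"x": xa, "y": xb, "r": r, "p": p,
                                      "n": len(sub)})
        pd.DataFrame(corr_rows).to_csv(_p(config, "correlations.tsv"),
                                       sep="\t", index=False)
        sel = targets[targets["selected"]] if len(targets) else targets
        for feature in config.stratify:
            spec = stratify_clinical(samples, feature)
            assoc = associate_targets(sel if len(sel) else targets,
                                      fit.consensus, fit.normmat, spec,
                                      seed=config.seed, g_min=config.g_min)
            assoc.table.to_csv(_p(config, f"assoc_{feature}.tsv"), sep="\t")
    except Exception:
        manifest["failed_stage"] = stage
        with open(_p(config, "FAILED"), "w") as fh:
            fh.write(stage + "\n")
        with open(_p(config, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise

    with open(_p(config, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _p(config: PipelineConfig, name: str) -> str:
    return os.path.join(config.out_dir, name)


def intersect_biomarkers(symbols_a, symbols_b,
                         directions_a: dict | None = None,
                         directions_b: dict | None = None) -> pd.DataFrame:
    """Case-insensitive symbol intersection of two DEG sets with per-set
    direction labels (e.g. a blood panel against a brain target panel)."""
    norm_a = {str(s).upper(): s for s in symbols_a if pd.notna(s)}
    norm_b = {str(s).upper(): s for s in symbols_b if pd.notna(s)}
    shared = sorted(set(norm_a) & set(norm_b))
    rows = []
    for key in shared:
        rows.append({
            "symbol": norm_a[key],
            "direction_a": (directions_a or {}).get(norm_a[key], "NA"),
            "direction_b": (directions_b or {}).get(norm_b[key], "NA"),
        })
    return pd.DataFrame(rows, columns=["symbol", "direction_a", "direction_b"])
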