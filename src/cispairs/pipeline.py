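"""End-to-end orchestration: simulate -> preprocess -> screen -> pair -> infer.

A run is driven by one :class:`PipelineConfig` (YAML-loadable), executes its
stages in a fixed order, writes per-stage TSV/JSON artifacts into the output
directory, and finishes with a machine-readable manifest capturing every
parameter, seed, and per-stage record count — enough to re-execute the run
and to audit the discovery funnel (how many features survive each filter).
Partial failure leaves completed stage outputs intact; the manifest then
names the failing stage.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as cio
from .cluster import hierarchical_cluster
from .containers import AnnotationSet, ExpressionMatrix
from .correlation import (
    celltype_contingency,
    correlations_to_frame,
    pearson,
    stratified_correlation,
)
from .differential import (
    DEFAULT_FC_THRESHOLD,
    filter_de,
    fold_changes,
    records_to_frame,
)
from .pairs import DEFAULT_MAX_DISTANCE, find_cis_pairs, pairs_to_frame, rank_pairs
from .prep import FilterConfig, floor_filter, quantile_normalize, summarize_probesets
from .stats import bca_bootstrap_median_diff, mann_whitney, resampling_adjust
from .synth import (
    GeneratorConfig,
    generate_annotation,
    generate_array_experiment,
    generate_paired_cohort,
    generate_single_cell,
)

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "validate_inputs"]

logger = logging.getLogger(__name__)

STAGES = ["simulate", "preprocess", "differential", "pairs", "correlate", "stats", "cluster"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All knobs of one run; defaults match the module-level defaults."""

    out_dir: str = "cispairs_run"
    simulate: bool = True
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    # external-input paths (used when simulate is False)
    annotation_path: str | None = None
    expression_path: str | None = None
    design_path: str | None = None
    probe_map_path: str | None = None
    cohort_path: str | None = None
    cells_path: str | None = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    filter_before_normalization: bool = True
    fc_threshold: float = DEFAULT_FC_THRESHOLD
    max_distance: int = DEFAULT_MAX_DISTANCE
    bootstrap_B: int = 2000
    level: float = 0.95
    run_cluster: bool = True

    @classmethod
    def demo(cls, out_dir: str = "cispairs_demo", seed: int = 0) -> "PipelineConfig":
        """Small fully synthetic configuration used by docs and smoke tests."""
        return cls(out_dir=out_dir, generator=GeneratorConfig(seed=seed))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = raw.pop("generator", {})
        filt = raw.pop("filter", {})
        cfg = cls(**raw)
        if gen:
            cfg.generator = GeneratorConfig(**gen)
        if filt:
            cfg.filter = FilterConfig(**filt)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"]["strata_spec"] = [
            dataclasses.asdict(s) if dataclasses.is_dataclass(s) else s
            for s in self.generator.strata_spec
        ]
        return d


@dataclass
class Finding:
    severity: str  # error | warning
    message: str


def validate_inputs(config: PipelineConfig) -> list[Finding]:
    """Static validation of a config and (for external inputs) its files.

    Never mutates inputs; returns findings rather than raising, so a caller
    can present all problems at once.
    """
    findings: list[Finding] = []
    if config.max_distance <= 0:
        findings.append(Finding("error", "max_distance must be > 0"))
    if config.fc_threshold <= 1:
        findings.append(Finding("error", "fc_threshold must be > 1"))
    if not (0 < config.level < 1):
        findings.append(Finding("error", "level must be in (0, 1)"))
    if config.bootstrap_B < 999:
        findings.append(Finding("error", "bootstrap_B must be >= 999"))
    if config.simulate:
        return findings

    for name in ("annotation_path", "expression_path", "design_path"):
        p = getattr(config, name)
        if p is None:
            findings.append(Finding("error", f"{name} is required when simulate is false"))
        elif not Path(p).exists():
            findings.append(Finding("error", f"{name}: no such file: {p}"))
    if any(f.severity == "error" for f in findings):
        return findings

    try:
        if str(config.annotation_path).endswith((".gtf", ".gff")):
            annotation = cio.read_annotation_gtf(config.annotation_path)
        else:
            annotation = cio.read_annotation_tsv(config.annotation_path)
    except Exception as exc:  # noqa: BLE001 - reported, not raised
        findings.append(Finding("error", f"annotation unreadable: {exc}"))
        annotation = None
    try:
        matrix = cio.read_expression(config.expression_path, config.design_path)
    except Exception as exc:  # noqa: BLE001
        findings.append(Finding("error", f"expression/design unreadable: {exc}"))
        matrix = None
    if matrix is not None and annotation is not None:
        features = set(matrix.feature_ids)
        if config.probe_map_path:
            pm = cio.read_probe_map(config.probe_map_path)
            unmapped = features - set(pm)
            if unmapped:
                findings.append(
                    Finding("error", f"probes missing from probe map: {sorted(unmapped)[:5]}")
                )
            features = set(pm.values())
        known = set(annotation.table["transcript_id"])
        orphans = features - known
        if orphans:
            findings.append(
                Finding("error", f"features without annotation: {sorted(orphans)[:5]}")
            )
    return findings


def _manifest_stage(manifest: dict, name: str, **info) -> None:
    manifest["stages"].append({"name": name, "status": "completed", **info})


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run manifest (also written to disk)."""
    errors = [f for f in validate_inputs(config) if f.severity == "error"]
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(f.message for f in errors))

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.generator.seed,
        "config": config.to_dict(),
        "stages": [],
        "timestamps": {"started": datetime.datetime.now().isoformat()},
    }
    stage = "simulate"
    try:
        # ---- simulate / load --------------------------------------------
        if config.simulate:
            gen = config.generator
            annotation = generate_annotation(gen)
            matrix = generate_array_experiment(annotation, gen)
            cohort = generate_paired_cohort(gen)
            cells = generate_single_cell(gen)
            probe_map = matrix.probe_map
            cio.write_annotation_tsv(annotation, out / "annotation.tsv")
            cio.write_annotation_gtf(annotation, out / "annotation.gtf")
            cio.write_expression(matrix, out / "probes.tsv", out / "design.tsv")
            cio.write_probe_map(probe_map, out / "probe_map.tsv")
            cio.write_json(
                {"annotation": annotation.truth, "array": matrix.truth,
                 "cohort": cohort.attrs["truth"], "cells": cells.attrs["truth"]},
                out / "truth.json",
            )
            cohort.to_csv(out / "cohort.tsv", sep="\t", index=False)
            cells.to_csv(out / "cells.tsv", sep="\t", index=False)
            _manifest_stage(
                manifest, stage,
                n_transcripts=len(annotation), n_probes=matrix.n_features,
                n_patients=len(cohort), n_cells=len(cells),
            )
        else:
            if str(config.annotation_path).endswith((".gtf", ".gff")):
                annotation = cio.read_annotation_gtf(config.annotation_path)
            else:
                annotation = cio.read_annotation_tsv(config.annotation_path)
            matrix = cio.read_expression(config.expression_path, config.design_path)
            probe_map = (
                cio.read_probe_map(config.probe_map_path)
                if config.probe_map_path
                else {f: f for f in matrix.feature_ids}
            )
            cohort = (
                pd.read_csv(config.cohort_path, sep="\t") if config.cohort_path else None
            )
            cells = (
                pd.read_csv(config.cells_path, sep="\t") if config.cells_path else None
            )
            _manifest_stage(
                manifest, "load",
                n_transcripts=len(annotation), n_probes=matrix.n_features,
            )

        # ---- preprocess --------------------------------------------------
        stage = "preprocess"
        n_in = matrix.n_features
        if config.filter_before_normalization:
            filtered = floor_filter(matrix, config.filter)
            normalized = quantile_normalize(filtered)
        else:
            normalized = floor_filter(quantile_normalize(matrix), config.filter)
        summarized = summarize_probesets(normalized, probe_map)
        cio.write_expression(summarized, out / "expression.tsv", out / "design.tsv")
        _manifest_stage(
            manifest, stage, probes_in=n_in,
            probes_kept=normalized.n_features, features_out=summarized.n_features,
        )

        # ---- differential ------------------------------------------------
        stage = "differential"
        records = fold_changes(summarized)
        de = filter_de(records, config.fc_threshold)
        records_to_frame(records, config.fc_threshold).to_csv(
            out / "differential.tsv", sep="\t", index=False, float_format="%.17g"
        )
        _manifest_stage(
            manifest, stage, features_in=len(records), features_de=len(de),
            fc_threshold=config.fc_threshold,
        )

        # ---- cis pairs ----------------------------------------------------
        stage = "pairs"
        biotype = dict(
            zip(annotation.table["transcript_id"], annotation.table["biotype"])
        )
        de_lnc = [r for r in de if biotype.get(r.feature_id) == "lncRNA"]
        de_mrna = [r for r in de if biotype.get(r.feature_id) == "coding"]
        pairs = find_cis_pairs(de_lnc, de_mrna, annotation, config.max_distance)
        ranked = rank_pairs(pairs, {r.feature_id: r for r in de})
        pairs_to_frame(ranked).to_csv(out / "cis_pairs.tsv", sep="\t", index=False)
        cio.write_pairs_bedpe(ranked, annotation, out / "cis_pairs.bedpe")
        _manifest_stage(
            manifest, stage, de_lnc=len(de_lnc), de_mrna=len(de_mrna),
            n_pairs=len(pairs), max_distance=config.max_distance,
        )

        # ---- correlations -------------------------------------------------
        stage = "correlate"
        info: dict = {}
        if cells is not None:
            strat = stratified_correlation(cells)
            strat_frame = correlations_to_frame(strat)
            strat_frame.to_csv(
                out / "correlations.tsv", sep="\t", index=False, float_format="%.17g"
            )
            cio.write_json(
                strat_frame.replace({float("nan"): None}).to_dict(orient="records"),
                out / "correlations.json",
            )
            celltype_contingency(cells).to_csv(out / "contingency.tsv", sep="\t")
            info["n_strata"] = len(strat) - 1
        if cohort is not None:
            cohort_r = pearson(cohort["tumor_a"], cohort["tumor_b"])
            cio.write_json(
                {"r": cohort_r.r, "n": cohort_r.n, "p": cohort_r.p,
                 "log10_p": cohort_r.log10_p},
                out / "cohort_correlation.json",
            )
            info["cohort_r"] = cohort_r.r
        _manifest_stage(manifest, stage, **info)

        # ---- statistics ---------------------------------------------------
        stage = "stats"
        info = {}
        if cohort is not None:
            seed = config.generator.seed
            diffs = pd.DataFrame(
                {
                    "gene_a": np.log2(cohort["tumor_a"] / cohort["normal_a"]),
                    "gene_b": np.log2(cohort["tumor_b"] / cohort["normal_b"]),
                }
            )
            tests = resampling_adjust(
                diffs, test="signed_rank", B=config.bootstrap_B, seed=seed
            )
            rows = []
            for t in tests:
                ci = bca_bootstrap_median_diff(
                    np.log2(cohort[f"tumor_{t.feature_id.split('_')[1]}"]),
                    np.log2(cohort[f"normal_{t.feature_id.split('_')[1]}"]),
                    B=config.bootstrap_B, level=config.level,
                    seed=seed, paired=True,
                )
                rows.append(
                    {
                        "feature": t.feature_id, "method": t.method,
                        "statistic": t.statistic, "n": t.n, "mode": t.mode,
                        "p_raw": t.p_raw, "p_adjusted": t.p_adjusted,
                        "median_diff_log2": ci.estimate,
                        "ci_lower": ci.lower, "ci_upper": ci.upper,
                        "level": ci.level, "B": ci.B, "seed": seed,
                        "median_fold": float(2**ci.estimate),
                    }
                )
            pd.DataFrame(rows).to_csv(
                out / "cohort_tests.tsv", sep="\t", index=False, float_format="%.17g"
            )
            smoker = cohort["smoking"] == "smoker"
            ratio_a = cohort["tumor_a"] / cohort["normal_a"]
            if 0 < smoker.sum() < len(cohort):
                mw = mann_whitney(ratio_a[smoker], ratio_a[~smoker])
                cio.write_json(
                    {"U": mw.statistic, "n": mw.n, "m": mw.m, "mode": mw.mode,
                     "p": mw.p_raw},
                    out / "smoker_vs_never_mw.json",
                )
            info["n_tests"] = len(tests)
        _manifest_stage(manifest, stage, **info)

        # ---- clustering ---------------------------------------------------
        stage = "cluster"
        if config.run_cluster:
            de_ids = [r.feature_id for r in de]
            target = summarized.subset(de_ids) if len(de_ids) >= 2 else summarized
            dendro = hierarchical_cluster(target)
            dendro.merges.to_csv(out / "cluster_merges.tsv", sep="\t", index=False,
                                 float_format="%.17g")
            pd.Series(dendro.leaf_order, name="feature_id").to_csv(
                out / "cluster_leaf_order.tsv", sep="\t", index=False
            )
            _manifest_stage(manifest, stage, n_features=len(dendro.leaf_order))
    except Exception as exc:
        manifest["stages"].append({"name": stage, "status": "failed", "error": str(exc)})
        manifest["timestamps"]["finished"] = datetime.datetime.now().isoformat()
        cio.write_json(manifest, out / "manifest.json")
        raise StageError(stage, exc) from exc

    manifest["timestamps"]["finished"] = datetime.datetime.now().isoformat()
    cio.write_json(manifest, out / "manifest.json")
    return manifest
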