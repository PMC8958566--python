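"""End-to-end orchestration: simulate -> extract -> normalize -> analyze
-> correlate -> pca, with a single JSON run report.

Each stage reads only the files the previous stage wrote, so stages can
be re-run independently; a fixed seed makes the whole run reproducible
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import design as design_mod
from .anova import bonferroni_threshold, run_univariate_suite, suite_frame
from .config import PipelineConfig
from .errors import FacekinError
from .mocap import (read_feature_table, read_manifest, read_trial,
                    read_vocal_table, vocal_wide, write_feature_table)
from .multimodal import compare_self, correlate_face_voice, correlations_frame
from .normalize import normalize_cohort, screen_outliers
from .pca import impute_similar_case, pca_varimax, zscore_within_subject
from .segments import (DEFAULT_SEGMENTS, SUPPLEMENTARY_SEGMENTS,
                       extract_trial_features, features_to_frame)
from .simulate import simulate_cohort

log = logging.getLogger("facekin")

__all__ = ["RunReport", "run_pipeline"]


@dataclass
class RunReport:
    """Summary of one pipeline run: stage row counts, output paths,
    warnings (imputed cells, dropped trials) and the config hash."""

    config_hash: str
    seed: int
    counts: dict[str, int] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


def _config_hash(config: PipelineConfig) -> str:
    blob = config.model_dump_json().encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def stage_simulate(config: PipelineConfig) -> None:
    simulate_cohort(config.simulate, config.out_dir)


def stage_extract(config: PipelineConfig) -> pd.DataFrame:
    manifest = read_manifest(config.out_dir / "manifest.csv")
    specs = DEFAULT_SEGMENTS + (SUPPLEMENTARY_SEGMENTS
                                if config.include_supplementary_segments else ())
    features = []
    for _, row in manifest.iterrows():
        traj = read_trial(row["path"], sample_rate=config.simulate.sample_rate)
        features.append(extract_trial_features(
            traj, specs, subject_id=row["subject_id"],
            condition=row["condition"], min_coverage=config.min_coverage))
    table = features_to_frame(features)
    write_feature_table(table, config.out_dir / "features.csv")
    return table


def stage_normalize(config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    features = read_feature_table(config.out_dir / "features.csv")
    features = features[[c for c in features.columns
                         if not c.startswith("coverage_")]]
    normalized = normalize_cohort(features, config.baseline_condition)
    flags = screen_outliers(normalized, config.outlier_z_threshold)
    write_feature_table(normalized, config.out_dir / "normalized.csv")
    flags.to_csv(config.out_dir / "outlier_report.csv", index=False)
    return normalized, flags


def _segment_names(config: PipelineConfig) -> tuple[str, ...]:
    specs = DEFAULT_SEGMENTS + (SUPPLEMENTARY_SEGMENTS
                                if config.include_supplementary_segments else ())
    return tuple(s.name for s in specs)


def stage_analyze(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    normalized = read_feature_table(config.out_dir / "normalized.csv")
    segments = _segment_names(config)
    out = {}
    for kind in ("character", "emotion"):
        suite = run_univariate_suite(
            normalized, kind=kind, segments=segments,
            scheme=config.simulate.character_scheme, reml=config.reml,
            alpha=config.alpha)
        frame = suite_frame(suite)
        frame.to_csv(config.out_dir / f"anova_{kind}.csv", index=False)
        frame.to_json(config.out_dir / f"anova_{kind}.json",
                      orient="records", indent=2)
        emmeans = pd.concat(
            [t.emmeans.assign(response=seg) for seg, t in suite.items()
             if not isinstance(t, Exception)], ignore_index=True)
        emmeans.to_csv(config.out_dir / f"emmeans_{kind}.csv", index=False)
        for seg, t in suite.items():
            if isinstance(t, Exception):
                log.warning("segment %s (%s): %s", seg, kind, t)
        out[kind] = frame
        log.info("%s ANOVA: Bonferroni threshold %.4f over %d segments",
                 kind, bonferroni_threshold(config.alpha, len(segments)),
                 len(segments))
    return out


def stage_correlate(config: PipelineConfig) -> pd.DataFrame:
    normalized = read_feature_table(config.out_dir / "normalized.csv")
    vocal = vocal_wide(read_vocal_table(config.out_dir / "vocal.csv"))
    frames = []
    for condition_set in ("character", "emotion"):
        results = correlate_face_voice(
            normalized, vocal, condition_set=condition_set,
            scheme=config.simulate.character_scheme, alpha=config.alpha)
        frames.append(correlations_frame(results))
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(config.out_dir / "correlations.csv", index=False)
    table.to_json(config.out_dir / "correlations.json", orient="records",
                  indent=2)

    performed = normalized[normalized["condition"] == "self"]
    control = normalized[normalized["condition"] == "control_self"]
    if len(performed) and len(control):
        contrast = compare_self(performed, control)
        contrast.to_csv(config.out_dir / "self_contrast.csv", index=False)
    return table


def stage_pca(config: PipelineConfig) -> dict:
    normalized = read_feature_table(config.out_dir / "normalized.csv")
    vocal = vocal_wide(read_vocal_table(config.out_dir / "vocal.csv"))
    # multivariate set: characters + all 9 emotions (neutral included as
    # an all-zero row, it is a condition of interest here), no control-self
    face = normalized[normalized["condition"] != "control_self"]
    face = face[["subject_id", "condition"]
                + [s for s in _segment_names(config) if s in face.columns]]
    neutral_rows = pd.DataFrame({
        "subject_id": sorted(face["subject_id"].unique()),
        "condition": "neutral",
    })
    for s in _segment_names(config):
        if s in face.columns:
            neutral_rows[s] = 0.0
    face = pd.concat([face, neutral_rows], ignore_index=True)
    table = face.merge(vocal, on=["subject_id", "condition"], how="left")

    z = zscore_within_subject(table)
    complete, imputed = impute_similar_case(z)
    result = pca_varimax(complete, k=config.pca_components)

    result.loadings_frame().to_csv(config.out_dir / "pca_loadings.csv",
                                   index=False)
    result.condition_scores.to_csv(config.out_dir / "pca_condition_scores.csv",
                                   index=False)
    result.scree.to_csv(config.out_dir / "pca_scree.csv", index=False)
    report = {
        "n_rows": int(len(complete)),
        "n_parameters": len(result.parameters),
        "kaiser_k": result.kaiser_k,
        "k": result.k,
        "variance_pct_per_component": [round(100 * v, 2)
                                       for v in result.variance_fraction],
        "total_variance_pct": round(100 * float(result.variance_fraction.sum()), 2),
        "eigenvalues": [round(float(v), 6) for v in result.eigenvalues],
        "loadings": result.loadings_frame().to_dict("records"),
        "condition_scores": result.condition_scores.round(6).to_dict("records"),
        "imputed_cells": imputed.to_dict("records"),
    }
    with open(config.out_dir / "pca_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run every stage in order and return the run report.

    Any stage error aborts the run with the stage named in the message.
    """
    config.out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=_config_hash(config),
                       seed=config.simulate.seed)
    stages = [
        ("simulate", stage_simulate),
        ("extract", stage_extract),
        ("normalize", stage_normalize),
        ("analyze", stage_analyze),
        ("correlate", stage_correlate),
        ("pca", stage_pca),
    ]
    for name, fn in stages:
        log.info("stage %s", name)
        try:
            result = fn(config)
        except Exception as exc:
            raise FacekinError(f"stage {name!r} failed: {exc}") from exc
        if name == "extract":
            report.counts["trials"] = len(result)
        elif name == "normalize":
            normalized, flags = result
            report.counts["normalized_rows"] = len(normalized)
            if len(flags):
                report.warnings.append(f"{len(flags)} outlier flags")
        elif name == "analyze":
            dtable = design_mod.build_design_table(
                read_feature_table(config.out_dir / "normalized.csv"),
                config.simulate.character_scheme)
            report.counts["character_rows"] = int((dtable["kind"] == "character").sum())
            report.counts["emotion_rows"] = int((dtable["kind"] == "emotion").sum())
        elif name == "pca":
            report.counts["pca_rows"] = result["n_rows"]
            if result["imputed_cells"]:
                report.warnings.append(
                    f"{len(result['imputed_cells'])} imputed vocal cells")
    for f in sorted(config.out_dir.glob("*.csv")) + sorted(
            config.out_dir.glob("*.json")):
        report.outputs[f.name] = str(f)
    report.to_json(config.out_dir / "run_report.json")
    report.outputs["run_report.json"] = str(config.out_dir / "run_report.json")
    return report
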