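"""End-to-end pipeline driver: simulate -> fit -> segment -> features ->
compare/classify/evaluate, with a YAML-configurable entry point and a JSON
run report."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import classify as clf
from . import io as cio
from .features import features_from_segments
from .phantom import (CohortImagingParams, contours_from_spec,
                      generate_phantom_subject, sample_subject_spec)
from .segmentation import ImageGrid, build_segment_masks, segment_statistics
from .stats import compare_groups
from .t2fit import fit_map

__all__ = ["PipelineConfig", "run_pipeline", "simulate_cohort_tables",
           "STAGES"]

log = logging.getLogger("cardiomad")

STAGES = ["simulate", "fit", "segment", "features", "evaluate"]


@dataclass
class PipelineConfig:
    """Configuration of a full phantom-cohort run."""

    out_dir: str = "cardiomad_run"
    n_hv: int = 4
    n_acm: int = 4
    seed: int = 0
    fit_method: str = "rician_mle"
    image_size: int = 128
    n_slices: int = 6
    madsd_cut: float = clf.MADSD_CUTOFF
    maxt2_cut: float = clf.MAXT2_CUTOFF_MS
    rule: str = "and"
    write_images: bool = False
    min_pixels: int = 10
    cohort: dict = field(default_factory=dict)  # CohortImagingParams overrides

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def simulate_cohort_tables(n_hv: int, n_acm: int, seed: int = 0,
                           fit_method: str = "rician_mle",
                           params: CohortImagingParams | None = None,
                           image_size: int = 128, n_slices: int = 6,
                           min_pixels: int = 10,
                           keep_subject_data: bool = False):
    """Image-level cohort: phantoms -> pixel-wise fits -> segment tables ->
    features. Returns ``(features_df, segments_df, subjects)`` where
    ``subjects`` holds per-subject artefacts when ``keep_subject_data``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    params = params or CohortImagingParams()
    seg_frames, feat_rows, subjects = [], [], []
    labels = ["HV"] * n_hv + ["ACM"] * n_acm
    for i, label in enumerate(labels):
        sid = f"{label}{i:03d}"
        spec = sample_subject_spec(label, rng, params=params,
                                   image_size=image_size, n_slices=n_slices)
        series, truth = generate_phantom_subject(spec)
        t2map = fit_map(series, method=fit_method)
        contours = contours_from_spec(spec)
        grid = ImageGrid(shape=series.grid_shape,
                         pixel_spacing_mm=spec.pixel_spacing_mm)
        seg_labels = build_segment_masks(contours, grid)
        table = segment_statistics(t2map, seg_labels, subject_id=sid,
                                   min_pixels=min_pixels)
        seg_frames.append(table)
        from .features import compute_features
        feats = compute_features(table)
        feats["subject_id"] = sid
        feats["label"] = label
        feat_rows.append(feats)
        if keep_subject_data:
            subjects.append({"subject_id": sid, "spec": spec, "series": series,
                             "truth": truth, "t2map": t2map,
                             "labels": seg_labels, "table": table})
    features = pd.DataFrame(feat_rows)[
        ["subject_id", "label"] + list(cio.FEATURE_CSV_COLUMNS[2:])]
    segments = pd.concat(seg_frames, ignore_index=True)
    return features, segments, subjects


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline per ``config`` and write all artefacts.

    Deterministic for a fixed seed; on stage failure the partial outputs and
    a manifest of completed stages are retained and the exception re-raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "package": f"cardiomad {__version__}",
        "seed": config.seed,
        "parameters": asdict(config),
        "stages": [],
        "results": {},
    }
    manifest = out / "manifest.json"
    try:
        log.info("stage=simulate+fit+segment+features seed=%d n=%d+%d",
                 config.seed, config.n_hv, config.n_acm)
        params = CohortImagingParams(**config.cohort)
        features, segments, subjects = simulate_cohort_tables(
            config.n_hv, config.n_acm, seed=config.seed,
            fit_method=config.fit_method, params=params,
            image_size=config.image_size, n_slices=config.n_slices,
            min_pixels=config.min_pixels,
            keep_subject_data=config.write_images)
        for stage in ("simulate", "fit", "segment", "features"):
            report["stages"].append(stage)
        if config.write_images:
            for sub in subjects:
                stem = out / "images" / sub["subject_id"]
                cio.save_echo_series(sub["series"], stem)
                cio.save_t2map(sub["t2map"], out / "maps" / sub["subject_id"])
                cio.save_labels(sub["labels"],
                                out / "maps" / (sub["subject_id"] + "_segments.nii.gz"))
        cio.save_table(segments, out / "segments.csv")
        cio.save_table(features, out / "features.csv")

        log.info("stage=evaluate")
        comparison = compare_groups(features)
        cio.save_table(comparison, out / "comparison.csv")
        predicted = clf.apply_cutoff_rule(features, config.madsd_cut,
                                          config.maxt2_cut, config.rule)
        features_out = features.copy()
        features_out["predicted"] = predicted.to_numpy()
        cio.save_table(features_out, out / "classification.csv")
        truth_pos = features["label"] == "ACM"
        pred_pos = features_out["predicted"] == "ACM"
        sens = float((pred_pos & truth_pos).sum() / truth_pos.sum())
        spec = float((~pred_pos & ~truth_pos).sum() / (~truth_pos).sum())
        logit = clf.DiagnosticLogit.from_dataframe(
            features, ["maxT2", "madSD"]).fit()
        scores = logit.predict(features[["maxT2", "madSD"]])
        auc = clf.roc(scores, features["label"].to_numpy()).auc
        report["results"] = {
            "n_subjects": len(features),
            "cutoff_rule": {"madSD": config.madsd_cut, "maxT2": config.maxt2_cut,
                            "combine": config.rule,
                            "sensitivity": sens, "specificity": spec},
            "logistic": {"coefficients": logit.params.to_dict(),
                         "converged": bool(logit.converged),
                         "auc": auc},
            "comparison": comparison.to_dict(orient="records"),
        }
        report["stages"].append("evaluate")
        cio.save_json(report, out / "report.json")
        cio.save_json({"completed_stages": report["stages"]}, manifest)
    except Exception:
        cio.save_json({"completed_stages": report["stages"], "failed": True},
                      manifest)
        log.exception("pipeline stage failed; partial outputs retained in %s", out)
        raise
    return report
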