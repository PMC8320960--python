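"""End-to-end driver: enhance -> segment -> features -> select -> classify.

``segment_patch`` runs the probability-image chain plus the clinical
cluster rules on one patch.  ``run_pipeline`` takes labelled samples
(patch + annotation outline + benign/malignant label), crops each
annotation-centred ROI, extracts the 51-feature vector from both the
unenhanced (alpha) and the enhanced (beta) segmentation, intersects the
CFS selections of the two variants, and cross-validates the
majority-vote ensemble and the stacked-generalization classifier on the
selected features of the enhanced variant.

Patches whose segmentation is empty (no MC cluster found) cannot yield a
feature vector; they are excluded from classification and reported in the
result.  Every run carries a manifest (config hash, package version,
sample count) sufficient to reproduce the report exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import EnsembleClassifier, EvalReport, StackedClassifier, cross_validate
from .cluster_rules import BlockGrid, apply_cluster_rule, block_side_px, \
    label_blobs, pre_clean
from .config import PipelineConfig
from .enhancement import enhance
from .features import extract_features, feature_names
from .feature_select import SelectionResult, intersect_protocol
from .io_formats import AnnotationOutline, DataError, ImagePatch, crop_roi, write_mask
from .mc_probability import probability_image

logger = logging.getLogger("mcclassify")

__all__ = ["LabelledSample", "PipelineResult", "segment_patch", "run_pipeline"]


@dataclass
class LabelledSample:
    patch: ImagePatch
    outline: AnnotationOutline | None = None
    label: str = "unknown"


@dataclass
class PipelineResult:
    table_alpha: pd.DataFrame
    table_beta: pd.DataFrame
    selection: SelectionResult
    ensemble_report: EvalReport
    stacked_report: EvalReport
    excluded: list[str] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "selection": {
                "subset": self.selection.subset,
                "merit": self.selection.merit,
            },
            "ensemble": self.ensemble_report.to_dict(),
            "stacked": self.stacked_report.to_dict(),
            "excluded": self.excluded,
            "manifest": self.manifest,
        }


def segment_patch(
    patch: ImagePatch, config: PipelineConfig | None = None
) -> dict:
    """Probability image + cluster rules; returns intermediates and mask.

    Keys: ``image_a``, ``image_b``, ``image_c``, ``pre_cleaned``,
    ``blobs`` (:class:`BlobSet` of the final mask) and ``mask``.
    """
    config = config or PipelineConfig()
    prob = probability_image(
        patch,
        subregion_px=config.subregion_px,
        fraction=config.top_fraction,
        fallback_fraction=config.fallback_fraction,
        smooth_step_px=config.smooth_step_px,
    )
    cleaned = pre_clean(prob["image_c"])
    blobs = label_blobs(cleaned)
    side = config.block_side_px or block_side_px(patch.spacing_um)
    grid = BlockGrid(shape=patch.shape, block_side_px=side)
    mask = apply_cluster_rule(blobs, grid, min_count=config.min_per_block)
    return {
        "image_a": prob["image_a"],
        "image_b": prob["image_b"],
        "image_c": prob["image_c"],
        "pre_cleaned": cleaned,
        "mask": mask,
        "blobs": label_blobs(mask),
        "background": prob["background"],
    }


def _roi(sample: LabelledSample, config: PipelineConfig) -> ImagePatch:
    if sample.outline is None:
        return sample.patch
    return crop_roi(sample.patch, sample.outline, margin_px=config.crop_margin_px)


def _feature_row(patch: ImagePatch, config: PipelineConfig, label: str):
    seg = segment_patch(patch, config)
    vec = extract_features(patch, seg["mask"], label=label)
    return vec


def run_pipeline(
    samples: list[LabelledSample],
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Full classification pipeline over labelled samples.

    Requires at least 10 segmentable samples with both classes present.
    When ``out_dir`` is given, masks, feature tables, the selection and
    the evaluation report are written there.
    """
    config = config or PipelineConfig()
    rows_a: list[dict] = []
    rows_b: list[dict] = []
    excluded: list[str] = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        (out_path / "masks").mkdir(parents=True, exist_ok=True)
    for sample in samples:
        sid = sample.patch.id
        try:
            roi = _roi(sample, config)
            vec_a = _feature_row(roi, config, sample.label)
            enhanced = enhance(
                roi,
                weight=config.enhance_weight,
                levels=config.enhance_levels,
                wavelet=config.wavelet,
            )
            seg_b = segment_patch(enhanced, config)
            vec_b = extract_features(enhanced, seg_b["mask"], label=sample.label)
        except DataError as exc:
            logger.warning("sample %s excluded at segmentation/features: %s",
                           sid, exc)
            excluded.append(sid)
            continue
        rows_a.append({"id": sid, "label": sample.label,
                       **dict(zip(vec_a.names, vec_a.values))})
        rows_b.append({"id": sid, "label": sample.label,
                       **dict(zip(vec_b.names, vec_b.values))})
        if out_path is not None:
            write_mask(seg_b["mask"], out_path / "masks" / f"{sid}.png")
    if len(rows_a) < 10:
        raise DataError(
            f"only {len(rows_a)} segmentable samples; need at least 10 for CV"
        )
    cols = ["id", "label", *feature_names()]
    table_a = pd.DataFrame(rows_a)[cols]
    table_b = pd.DataFrame(rows_b)[cols]
    selection = intersect_protocol(table_a, table_b,
                                   stale_limit=config.stale_limit)
    logger.info("selected features: %s (merit %.3f)",
                selection.subset, selection.merit)
    X = table_b[selection.subset].to_numpy(dtype=np.float64)
    y = (table_b["label"] == "malignant").to_numpy(dtype=int)
    ensemble_report = cross_validate(
        X, y, lambda seed: EnsembleClassifier(random_state=seed),
        scheme=config.scheme, seeds=config.seeds, n_folds=config.n_folds,
    )
    stacked_report = cross_validate(
        X, y,
        lambda seed: StackedClassifier(meta=config.meta, random_state=seed),
        scheme=config.scheme, seeds=config.seeds, n_folds=config.n_folds,
    )
    result = PipelineResult(
        table_alpha=table_a,
        table_beta=table_b,
        selection=selection,
        ensemble_report=ensemble_report,
        stacked_report=stacked_report,
        excluded=excluded,
        manifest={
            "config_hash": config.hash(),
            "config": config.to_dict(),
            "version": __version__,
            "n_samples": len(samples),
            "n_used": len(rows_a),
        },
    )
    if out_path is not None:
        table_a.to_csv(out_path / "features_alpha.csv", index=False)
        table_b.to_csv(out_path / "features_beta.csv", index=False)
        with open(out_path / "report.json", "w") as fh:
            json.dump(result.to_dict(), fh, indent=2, sort_keys=True)
    return result
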