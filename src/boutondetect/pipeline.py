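"""End-to-end orchestration of the bouton detection pipeline.

The flow on one stack is:

1. mean intensity projection of the stack;
2. negative-LoG enhancement of the projection;
3. determinant-of-Hessian interest points on the enhanced image;
4. non-maximum suppression (relocate to local max, deduplicate);
5. Gabor descriptor + SVM classification of each surviving candidate;
6. z-localization of each accepted bouton by the patch-sum argmax.

Stage candidate counts are recorded so a run can be audited; every run
is deterministic given its configuration, model, and input.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from . import classification, detection, enhancement, evaluation, gabor_features
from .classification import TrainedClassifier
from .detection import NmsConfig
from .enhancement import EnhancementConfig
from .evaluation import EvaluationReport, MatchCounts
from .gabor_features import GaborConfig
from .imaging_io import BoxSet, ImageStack, Image2D, mean_projection
from .localize3d import Detection3D, localize_detections
from .synthetic import SceneParams, generate_patches

logger = logging.getLogger("boutondetect")


@dataclass
class DetectorConfig:
    """Interest-point stage settings."""

    threshold: float = 5e-4
    n_octaves: int = 3
    n_scales: int = 4


@dataclass
class PipelineConfig:
    """All stage configurations plus run metadata."""

    enhancement: EnhancementConfig = field(default_factory=EnhancementConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    nms: NmsConfig = field(default_factory=NmsConfig)
    gabor: GaborConfig = field(default_factory=GaborConfig)
    enhance_enabled: bool = True
    patch_source: str = "projection"  # "projection" | "enhanced"
    localize_patch_side: int = 25
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


@dataclass
class DetectionResult:
    """Final detections with stage provenance."""

    detections: list[Detection3D]
    stage_counts: dict[str, int]
    config: PipelineConfig


def detect_boutons(
    stack: ImageStack, model: TrainedClassifier, cfg: PipelineConfig | None = None
) -> DetectionResult:
    """Run the full 2D detection + classification + z-localization flow."""
    if cfg is None:
        cfg = PipelineConfig()
    if model.n_features != cfg.gabor.n_angles:
        raise ValueError(
            f"model expects {model.n_features} features, Gabor bank yields "
            f"{cfg.gabor.n_angles}"
        )
    counts: dict[str, int] = {}

    proj = mean_projection(stack)
    enhanced = (
        enhancement.enhance(proj, cfg.enhancement) if cfg.enhance_enabled else proj
    )
    nms_image = (
        enhanced
        if cfg.enhancement.nms_intensity_source == "enhanced"
        else proj
    )
    patch_image = enhanced if cfg.patch_source == "enhanced" else proj

    points = detection.detect_interest_points(
        enhanced,
        threshold=cfg.detector.threshold,
        n_octaves=cfg.detector.n_octaves,
        n_scales=cfg.detector.n_scales,
    )
    counts["interest_points"] = len(points)
    points = detection.relocate_to_local_max(points, nms_image, cfg.nms)
    points = detection.suppress_duplicates(points, nms_image, cfg.nms)
    counts["after_nms"] = len(points)

    if points:
        feats = gabor_features.describe_points(patch_image, points, cfg.gabor)
        labels, scores = classification.classify(model, feats)
        accepted = [(p, s) for p, lab, s in zip(points, labels, scores) if lab == 1]
    else:
        accepted = []
    counts["accepted"] = len(accepted)
    logger.info("stage counts: %s", counts)

    dets = localize_detections(
        stack,
        [(p.row, p.col) for p, _ in accepted],
        [s for _, s in accepted],
        patch_side=cfg.localize_patch_side,
    )
    dets.sort(key=lambda d: (-d.score, d.row, d.col))
    return DetectionResult(dets, counts, cfg)


def run_evaluation(
    result: DetectionResult | list[Detection3D],
    truth: BoxSet,
    tn_mode: str = "none",
) -> tuple[MatchCounts, tuple[float, float, float]]:
    """Score one image's detections against its ground-truth boxes."""
    dets = result.detections if isinstance(result, DetectionResult) else result
    pts = [(d.row, d.col) for d in dets]
    for r, c in pts:
        if not (0 <= r < truth.frame_shape[0] and 0 <= c < truth.frame_shape[1]):
            raise ValueError(
                f"detection {(r, c)} outside ground-truth frame {truth.frame_shape}"
            )
    counts = evaluation.match_detections(
        pts, truth, [d.score for d in dets], tn_mode=tn_mode
    )
    return counts, evaluation.metrics(counts)


def evaluate_batch(
    results: list[DetectionResult | list[Detection3D]],
    truths: list[BoxSet],
    tn_mode: str = "none",
) -> EvaluationReport:
    """Aggregate per-image evaluation into one report."""
    report = EvaluationReport()
    for res, truth in zip(results, truths):
        counts, _ = run_evaluation(res, truth, tn_mode)
        report.counts.append(counts)
        report.n_boutons.append(len(truth))
    return report


def train_from_synthetic(
    params: SceneParams | None = None,
    n_per_class: int = 450,
    gabor_cfg: GaborConfig | None = None,
    classifier_params: classification.ClassifierParams | None = None,
    split_seed: int = 0,
) -> TrainedClassifier:
    """Train the SVM on synthetic labelled patches (450 per class default)."""
    if params is None:
        params = SceneParams()
    if gabor_cfg is None:
        gabor_cfg = GaborConfig()
    patches, labels = generate_patches(params, n_per_class)
    feats = features_from_patches(patches, gabor_cfg)
    data = classification.LabelledFeatureSet(feats, labels)
    return classification.train(
        data, classifier_params, split_seed=split_seed, calibrate_threshold=True
    )


def features_from_patches(
    patches: np.ndarray, cfg: GaborConfig | None = None
) -> np.ndarray:
    """Descriptor matrix for a batch of training patches.

    Patches of other sizes are bilinearly resampled to the bank's patch
    size first.
    """
    if cfg is None:
        cfg = GaborConfig()
    size = gabor_features.patch_size_from_sigma(cfg.sigma_x)
    bank = gabor_features.build_bank(cfg, size)
    out = np.zeros((len(patches), cfg.n_angles))
    for i, patch in enumerate(patches):
        patch = gabor_features.resize_patch(patch, size)
        if cfg.normalize_patch:
            patch = gabor_features.normalize_patch(patch)
        out[i] = gabor_features.describe(patch, bank)
    return out
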