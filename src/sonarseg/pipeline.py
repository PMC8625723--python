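"""End-to-end pipelines: raw-baseline and CRF-preprocessed segmentation.

`RawPipeline` feeds the raw middle sonar frame straight to the instance
backend -- the baseline whose accuracy collapses when the imaging
environment changes.  `CrfPipeline` first maps the frame stack to a
per-pixel fish posterior with the trained CRF segmenter and hands the
backend the standardized posterior channel instead; in directional mode
it enumerates the 15 motion-direction subsets and fuses the per-subset
detections with mask NMS.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .backend import SegmentationBackend, ThresholdBackend, detect_instances
from .masks import InstanceMask
from .model import CrfSegmenter
from .standardize import (
    enumerate_direction_combinations,
    fuse_detections_nms,
    standardize_binary,
    standardize_directional,
    standardize_raw,
)
from .training import TrainingConfig, fit
from .unary import FrameStack, UnaryConfig

__all__ = ["RawPipeline", "CrfPipeline", "evaluate_pipeline"]


def _stack(scene) -> FrameStack:
    s = scene.stack
    return s() if callable(s) else s


def _raw_middle(scene) -> np.ndarray:
    if hasattr(scene, "raw_middle"):
        return scene.raw_middle
    return scene.middle_frame


@dataclass
class RawPipeline:
    """Instance backend applied directly to the raw middle frame."""

    backend: SegmentationBackend = field(default_factory=ThresholdBackend)
    score_thr: float = 0.2

    def fit(self, scenes, seed: int = 0) -> "RawPipeline":
        return self  # nothing to train

    def detect(self, scene) -> list[InstanceMask]:
        img = standardize_raw(_raw_middle(scene))
        return detect_instances(img, self.backend, self.score_thr)


@dataclass
class CrfPipeline:
    """CRF segmenter -> standardized posterior -> instance backend.

    The default architecture is sized for desk-scale experiments: four
    dilated blocks of one 3x3 layer and 8 channels each (32 channels
    after concatenation), a 16-channel head, 5 mean-field iterations.
    """

    unary_config: UnaryConfig = field(
        default_factory=lambda: UnaryConfig(
            in_channels=3, num_labels=2, block_width=8,
            convs_per_block=1, head_width=16, dropout=0.1,
        )
    )
    train_config: TrainingConfig = field(
        default_factory=lambda: TrainingConfig(
            learning_rate=0.2, momentum=0.9, batch_size=2, epochs=30
        )
    )
    mf_iterations: int = 5
    sim_hidden: int = 8
    directional: bool = False
    backend: SegmentationBackend = field(default_factory=ThresholdBackend)
    score_thr: float = 0.2
    nms_iou: float = 0.5
    model: CrfSegmenter | None = None

    def __post_init__(self):
        want = 5 if self.directional else 2
        if self.unary_config.num_labels != want:
            self.unary_config = replace(self.unary_config, num_labels=want)

    def fit(self, scenes, seed: int = 0) -> "CrfPipeline":
        model = CrfSegmenter(
            self.unary_config,
            mf_iterations=self.mf_iterations,
            sim_hidden=self.sim_hidden,
            seed=seed,
        )
        dataset = [(_stack(s), s.annotation) for s in scenes]
        cfg = replace(self.train_config, seed=seed)
        model, _ = fit(model, dataset, cfg)
        self.model = model
        return self

    def detect(self, scene) -> list[InstanceMask]:
        if self.model is None:
            raise RuntimeError("pipeline is not fitted")
        q = self.model.predict(_stack(scene))
        if not self.directional:
            img = standardize_binary(q)
            return detect_instances(img, self.backend, self.score_thr)
        lists = []
        for subset in enumerate_direction_combinations():
            img = standardize_directional(q, subset)
            lists.append(detect_instances(img, self.backend, self.score_thr))
        return fuse_detections_nms(lists, self.nms_iou)


def evaluate_pipeline(
    pipeline, scenes, iou_thresholds=(0.5, 0.75), score_thr: float = 0.2
) -> dict[float, float]:
    """Pooled mask AP of a fitted pipeline on a list of scenes."""
    from .metrics import dataset_average_precision, _scene_gt

    pairs = [(pipeline.detect(s), _scene_gt(s)) for s in scenes]
    return {
        thr: dataset_average_precision(pairs, thr, score_thr)
        for thr in iou_thresholds
    }
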