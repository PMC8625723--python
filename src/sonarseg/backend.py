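"""Pluggable instance-segmentation backends.

The pipeline treats the detect-then-segment stage as an adapter: any
object with a ``segment(StandardizedInput) -> list[InstanceMask]``
method can serve as the backend (e.g. a wrapper around an external
Mask R-CNN).  A lightweight connected-component segmenter is provided
so the full pipeline runs and is testable without any external
detector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np
from skimage import measure

from .masks import InstanceMask
from .standardize import StandardizedInput

__all__ = [
    "BackendError",
    "SegmentationBackend",
    "ThresholdBackend",
    "fallback_segment",
    "detect_instances",
]


class BackendError(RuntimeError):
    """Raised when the instance backend fails on an input."""


@runtime_checkable
class SegmentationBackend(Protocol):
    """Adapter contract: one standardized image in, scored masks out."""

    def segment(self, img: StandardizedInput) -> list[InstanceMask]: ...


@dataclass
class ThresholdBackend:
    """Connected-component fallback segmenter.

    Thresholds the fish channel (on the [0, 1] posterior scale),
    extracts 8-connected components of at least `min_area` pixels, and
    scores each component by its mean fish-channel value.
    """

    threshold: float = 0.5
    min_area: int = 20
    connectivity: int = 2  # skimage convention: 2 = 8-connectivity

    def segment(self, img: StandardizedInput) -> list[InstanceMask]:
        channel = img.fish_channel
        binary = channel >= self.threshold
        labeled = measure.label(binary, connectivity=self.connectivity)
        out = []
        for region in measure.regionprops(labeled):
            if region.area < self.min_area:
                continue
            mask = labeled == region.label
            score = float(np.clip(channel[mask].mean(), 0.0, 1.0))
            out.append(InstanceMask.from_mask(mask, score))
        out.sort(key=lambda d: -d.score)
        return out


def fallback_segment(
    img: StandardizedInput,
    threshold: float = 0.5,
    min_area: int = 20,
) -> list[InstanceMask]:
    """Functional form of the fallback connected-component segmenter."""
    return ThresholdBackend(threshold=threshold, min_area=min_area).segment(img)


def detect_instances(
    img: StandardizedInput,
    backend: SegmentationBackend,
    score_thr: float = 0.2,
) -> list[InstanceMask]:
    """Run a backend and keep detections with score >= score_thr,
    sorted by descending confidence.  Backend failures surface as
    BackendError."""
    try:
        detections = backend.segment(img)
    except Exception as exc:  # adapter boundary: normalize failures
        raise BackendError(f"instance backend failed: {exc}") from exc
    kept = [d for d in detections if d.score >= score_thr]
    kept.sort(key=lambda d: -d.score)
    return kept
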