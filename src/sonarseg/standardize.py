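"""Standardized inputs for the instance backend, and NMS fusion.

The semantic posterior map produced by the CRF segmenter is converted
into a "standardized" 3-channel image whose channel 0 carries the fish
posterior and whose other two channels are identically zero, so a
downstream instance segmenter sees the same representation regardless
of the imaging environment.

For the directional (5-label) model, each nonempty subset of the four
motion-direction categories {NW, NE, SW, SE} yields one standardized
input whose fish channel is the channelwise sum of the selected
direction posteriors -- 15 inputs in all, each a hypothesis about which
motion directions compose a fish.  The per-subset detections are then
fused by non-maximum suppression over mask IoU.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .crf import MeanFieldState
from .masks import InstanceMask, mask_iou

__all__ = [
    "DIRECTIONS",
    "StandardizedInput",
    "standardize_binary",
    "standardize_directional",
    "standardize_raw",
    "enumerate_direction_combinations",
    "fuse_detections_nms",
]

# Direction categories in annotation/channel order: channel 1 + index.
DIRECTIONS = ("NW", "NE", "SW", "SE")


@dataclass
class StandardizedInput:
    """3-channel backend input: fish signal in channel 0, zeros elsewhere.

    `scale` records the factor applied to the [0, 1] posterior (e.g. 255
    for 8-bit backends); `provenance` names the source: "fish", "raw",
    or the tuple of direction categories summed into channel 0.
    """

    img: np.ndarray
    provenance: tuple[str, ...] | str
    scale: float = 1.0

    def __post_init__(self):
        if self.img.ndim != 3 or self.img.shape[2] != 3:
            raise ValueError("standardized input must be H x W x 3")
        if np.any(self.img[:, :, 1:]):
            raise ValueError("channels 1 and 2 must be identically zero")

    @property
    def fish_channel(self) -> np.ndarray:
        """The [0, 1] signal recovered by undoing the scale factor."""
        return self.img[:, :, 0] / self.scale


def _as_q(q) -> np.ndarray:
    arr = q.q if isinstance(q, MeanFieldState) else np.asarray(q, dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError("posterior map must be H x W x L")
    return arr


def _pack(channel0: np.ndarray, provenance, scale: float) -> StandardizedInput:
    img = np.zeros(channel0.shape + (3,))
    img[:, :, 0] = channel0 * scale
    return StandardizedInput(img=img, provenance=provenance, scale=scale)


def standardize_binary(q, scale: float = 1.0) -> StandardizedInput:
    """Binary model output -> standardized input (fish posterior channel)."""
    arr = _as_q(q)
    if arr.shape[2] != 2:
        raise ValueError("binary standardization expects a 2-channel posterior")
    return _pack(arr[:, :, 1], "fish", scale)


def enumerate_direction_combinations() -> list[tuple[str, ...]]:
    """All 15 nonempty subsets of the four direction categories, in
    deterministic order (by size, then by category order)."""
    out: list[tuple[str, ...]] = []
    for r in range(1, len(DIRECTIONS) + 1):
        out.extend(combinations(DIRECTIONS, r))
    return out


def standardize_directional(q, subset, scale: float = 1.0) -> StandardizedInput:
    """Directional model output + direction subset -> standardized input.

    Channel 0 is the channelwise sum of the posterior over the selected
    motion-direction categories.
    """
    arr = _as_q(q)
    if arr.shape[2] != 5:
        raise ValueError("directional standardization expects a 5-channel posterior")
    subset = tuple(subset)
    if not subset:
        raise ValueError("direction subset must be nonempty")
    if len(set(subset)) != len(subset) or any(d not in DIRECTIONS for d in subset):
        raise ValueError(f"invalid direction subset {subset}")
    channels = [1 + DIRECTIONS.index(d) for d in subset]
    return _pack(arr[:, :, channels].sum(axis=2), subset, scale)


def standardize_raw(frame: np.ndarray, scale: float = 1.0) -> StandardizedInput:
    """Wrap a raw sonar frame in the standardized layout (baseline path)."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise ValueError("raw frame must be H x W")
    return _pack(frame, "raw", scale)


def fuse_detections_nms(
    detection_lists: list[list[InstanceMask]], iou_thr: float = 0.5
) -> list[InstanceMask]:
    """Greedy score-ordered NMS over the pooled detections of all lists.

    Detections are pooled across the per-subset lists, sorted by
    descending score (ties broken by earlier list, then top-left mask
    coordinate), and kept greedily: a detection is suppressed when its
    mask IoU with any already-kept detection reaches `iou_thr`.
    """
    pooled = []
    for li, dets in enumerate(detection_lists):
        for di, d in enumerate(dets):
            x, y = d.bbox[0], d.bbox[1]
            pooled.append(((-d.score, li, y, x, di), d))
    pooled.sort(key=lambda item: item[0])
    kept: list[InstanceMask] = []
    for _, d in pooled:
        if all(mask_iou(d, k) < iou_thr for k in kept):
            kept.append(d)
    return kept
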