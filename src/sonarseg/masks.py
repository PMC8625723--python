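"""Instance masks and their serialization.

An `InstanceMask` is one detected (or ground-truth) fish: a binary
mask, a confidence score and the tight bounding box of the mask.
Detections are exchanged as COCO-style JSON records carrying the score,
the (x, y, w, h) box and an uncompressed column-major run-length
encoding of the mask.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "InstanceMask",
    "mask_iou",
    "rle_encode",
    "rle_decode",
    "detections_to_json",
    "detections_from_json",
]


@dataclass
class InstanceMask:
    """One instance: binary mask, confidence in [0, 1], tight bbox (x, y, w, h)."""

    mask: np.ndarray
    score: float
    bbox: tuple[int, int, int, int]

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not self.mask.any():
            raise ValueError("mask must be nonempty")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError("score must lie in [0, 1]")
        self.bbox = tuple(int(v) for v in self.bbox)
        if self.bbox != tight_bbox(self.mask):
            raise ValueError("bbox is not the tight box of the mask")

    @classmethod
    def from_mask(cls, mask: np.ndarray, score: float) -> "InstanceMask":
        mask = np.asarray(mask, dtype=bool)
        return cls(mask=mask, score=float(score), bbox=tight_bbox(mask))

    @property
    def area(self) -> int:
        return int(self.mask.sum())


def tight_bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    """(x, y, w, h) of the smallest box containing all true pixels."""
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("empty mask has no bounding box")
    x0, x1 = int(xs.min()), int(xs.max())
    y0, y1 = int(ys.min()), int(ys.max())
    return (x0, y0, x1 - x0 + 1, y1 - y0 + 1)


def mask_iou(a: InstanceMask | np.ndarray, b: InstanceMask | np.ndarray) -> float:
    """Intersection-over-union of two binary masks."""
    ma = a.mask if isinstance(a, InstanceMask) else np.asarray(a, dtype=bool)
    mb = b.mask if isinstance(b, InstanceMask) else np.asarray(b, dtype=bool)
    if ma.shape != mb.shape:
        raise ValueError("masks must share a shape")
    if not ma.any() or not mb.any():
        raise ValueError("IoU of an empty mask is undefined")
    inter = np.logical_and(ma, mb).sum()
    union = np.logical_or(ma, mb).sum()
    return float(inter / union)


def rle_encode(mask: np.ndarray) -> dict:
    """COCO-style uncompressed RLE: column-major run lengths, 0-runs first."""
    mask = np.asarray(mask, dtype=bool)
    flat = mask.flatten(order="F").astype(np.int8)
    # run boundaries
    diffs = np.nonzero(np.diff(flat))[0] + 1
    starts = np.concatenate(([0], diffs, [flat.size]))
    counts = np.diff(starts).astype(int).tolist()
    if flat.size and flat[0] == 1:
        counts = [0] + counts
    return {"size": [int(mask.shape[0]), int(mask.shape[1])], "counts": counts}


def rle_decode(rle: dict) -> np.ndarray:
    h, w = rle["size"]
    flat = np.zeros(h * w, dtype=bool)
    pos, val = 0, False
    for count in rle["counts"]:
        if val:
            flat[pos : pos + count] = True
        pos += count
        val = not val
    return flat.reshape((h, w), order="F")


def detections_to_json(detections: list[InstanceMask], path=None) -> list[dict]:
    records = [
        {
            "score": float(d.score),
            "bbox": list(d.bbox),
            "segmentation": rle_encode(d.mask),
        }
        for d in detections
    ]
    if path is not None:
        Path(path).write_text(json.dumps(records))
    return records


def detections_from_json(source) -> list[InstanceMask]:
    if isinstance(source, (str, Path)):
        records = json.loads(Path(source).read_text())
    else:
        records = source
    return [
        InstanceMask(
            mask=rle_decode(r["segmentation"]),
            score=r["score"],
            bbox=tuple(r["bbox"]),
        )
        for r in records
    ]
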