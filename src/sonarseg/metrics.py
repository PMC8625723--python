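"""Mask-AP evaluation, k-fold splitting and the cross-environment harness.

Average precision follows the detection convention: predictions are
ranked by confidence, each is greedily matched to the unmatched ground
truth of highest mask IoU (a match requires IoU >= threshold, each
ground truth matches at most once), and AP is the area under the
all-points-interpolated precision-recall curve.  AP depends only on the
ranking of the scores, not their scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .masks import InstanceMask, mask_iou

__all__ = [
    "mask_iou",
    "match_detections",
    "average_precision",
    "dataset_average_precision",
    "precision_recall_points",
    "kfold_split",
    "EvaluationResult",
    "cross_environment_matrix",
]


def match_detections(
    preds: list[InstanceMask], gts: list[InstanceMask], iou_thr: float
) -> list[tuple[float, bool]]:
    """Greedy score-ordered matching; returns (score, is_true_positive)
    per prediction.  Ties on IoU resolve to the lower ground-truth index."""
    order = sorted(range(len(preds)), key=lambda i: (-preds[i].score, i))
    unmatched = list(range(len(gts)))
    out: list[tuple[float, bool]] = []
    for pi in order:
        best_iou, best_gi = 0.0, None
        for gi in unmatched:
            iou = mask_iou(preds[pi], gts[gi])
            if iou > best_iou:
                best_iou, best_gi = iou, gi
        if best_gi is not None and best_iou >= iou_thr:
            unmatched.remove(best_gi)
            out.append((preds[pi].score, True))
        else:
            out.append((preds[pi].score, False))
    return out


def _ap_from_flags(flagged: list[tuple[float, bool]], n_gt: int) -> float:
    if n_gt == 0 or not flagged:
        return 0.0
    flagged = sorted(flagged, key=lambda t: -t[0])
    tp = np.cumsum([f for _, f in flagged])
    fp = np.cumsum([not f for _, f in flagged])
    recall = tp / n_gt
    precision = tp / (tp + fp)
    # all-points interpolation: precision envelope, summed over recall steps
    mpre = precision.copy()
    for i in range(len(mpre) - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    prev_r, ap = 0.0, 0.0
    for r, p in zip(recall, mpre):
        ap += (r - prev_r) * p
        prev_r = r
    return float(ap)


def average_precision(
    preds: list[InstanceMask],
    gts: list[InstanceMask],
    iou_thr: float = 0.5,
    score_thr: float = 0.0,
) -> float:
    """Single-image mask AP at one IoU threshold."""
    return dataset_average_precision([(preds, gts)], iou_thr, score_thr)


def dataset_average_precision(
    pairs: list[tuple[list[InstanceMask], list[InstanceMask]]],
    iou_thr: float = 0.5,
    score_thr: float = 0.0,
) -> float:
    """Mask AP pooled over a dataset of (predictions, ground-truth) pairs."""
    flagged: list[tuple[float, bool]] = []
    n_gt = 0
    for preds, gts in pairs:
        preds = [p for p in preds if p.score >= score_thr]
        flagged.extend(match_detections(preds, gts, iou_thr))
        n_gt += len(gts)
    return _ap_from_flags(flagged, n_gt)


def precision_recall_points(
    pairs: list[tuple[list[InstanceMask], list[InstanceMask]]],
    iou_thr: float = 0.5,
    score_thr: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw (recall, precision) points of the pooled ranked detections."""
    flagged: list[tuple[float, bool]] = []
    n_gt = 0
    for preds, gts in pairs:
        preds = [p for p in preds if p.score >= score_thr]
        flagged.extend(match_detections(preds, gts, iou_thr))
        n_gt += len(gts)
    if n_gt == 0 or not flagged:
        return np.array([]), np.array([])
    flagged = sorted(flagged, key=lambda t: -t[0])
    tp = np.cumsum([f for _, f in flagged])
    fp = np.cumsum([not f for _, f in flagged])
    return tp / n_gt, tp / (tp + fp)


def kfold_split(n_items: int, k: int, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded k-fold split: k disjoint test folds covering range(n_items)."""
    if not (2 <= k <= n_items):
        raise ValueError("need 2 <= k <= n_items")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_items)
    folds = np.array_split(perm, k)
    out = []
    for i in range(k):
        test = np.sort(folds[i])
        train = np.sort(np.concatenate([folds[j] for j in range(k) if j != i]))
        out.append((train, test))
    return out


@dataclass
class EvaluationResult:
    """AP at each IoU threshold with per-fold (or per-seed) spread."""

    iou_thresholds: tuple[float, ...]
    per_fold: dict[float, list[float]] = field(default_factory=dict)

    def mean(self, thr: float) -> float:
        return float(np.mean(self.per_fold[thr]))

    def std(self, thr: float) -> float:
        return float(np.std(self.per_fold[thr]))

    def summary(self) -> dict[str, float]:
        out = {}
        for thr in self.iou_thresholds:
            out[f"ap{thr:g}_mean"] = self.mean(thr)
            out[f"ap{thr:g}_std"] = self.std(thr)
        return out


def cross_environment_matrix(
    train_envs: list[str],
    test_envs: list[str],
    pipelines: dict[str, object],
    seeds: list[int],
    simulate_fn,
    n_train: int = 8,
    n_test: int = 6,
    iou_thresholds: tuple[float, ...] = (0.5,),
    score_thr: float = 0.2,
) -> pd.DataFrame:
    """Train/test every pipeline across environment pairs.

    `simulate_fn(env_name, n_scenes, seed)` must return a list of scenes
    (objects with a frame stack, annotation and ground truth, as
    produced by the synthetic generator).  Each pipeline is trained per
    (train_env, seed) and evaluated on every test environment; the
    returned tidy table has one row per (pipeline, train_env, test_env,
    iou_thr) with the AP mean and std over seeds.
    """
    rows = []
    cells: dict[tuple, list[float]] = {}
    for name, pipeline in pipelines.items():
        for train_env in train_envs:
            for seed in seeds:
                train_scenes = simulate_fn(train_env, n_train, seed)
                fitted = pipeline.fit(train_scenes, seed=seed)
                for test_env in test_envs:
                    test_scenes = simulate_fn(test_env, n_test, seed + 10_000)
                    pairs = [
                        (fitted.detect(s), _scene_gt(s)) for s in test_scenes
                    ]
                    for thr in iou_thresholds:
                        ap = dataset_average_precision(pairs, thr, score_thr)
                        cells.setdefault((name, train_env, test_env, thr), []).append(ap)
    for (name, train_env, test_env, thr), aps in cells.items():
        rows.append(
            {
                "pipeline": name,
                "train_env": train_env,
                "test_env": test_env,
                "iou_thr": thr,
                "ap_mean": float(np.mean(aps)),
                "ap_std": float(np.std(aps)),
                "n_runs": len(aps),
            }
        )
    return pd.DataFrame(rows)


def _scene_gt(scene) -> list[InstanceMask]:
    if hasattr(scene, "gt_instances"):
        return scene.gt_instances()
    return scene.gt_masks
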