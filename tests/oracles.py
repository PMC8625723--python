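"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately written as plain Python loops, separate
from the vectorized implementations under test.
"""

from __future__ import annotations

import numpy as np

from sonarseg.masks import InstanceMask, mask_iou


def loop_pairwise_message(q, sim_values, c, offsets):
    """phi_p by explicit per-pixel, per-neighbor, per-label loops."""
    H, W, L = q.shape
    out = np.zeros((H, W, L))
    for y in range(H):
        for x in range(W):
            for u in range(L):
                acc = 0.0
                for v in range(L):
                    s = 0.0
                    for k, (dy, dx) in enumerate(offsets):
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < H and 0 <= nx < W:
                            s += sim_values[y, x, k] * q[ny, nx, v]
                    acc += c[u, v] * s
                out[y, x, u] = acc
    return out


def loop_meanfield_step(q, psi, sim_values, c, offsets):
    """One parallel update computed with explicit loops."""
    msg = loop_pairwise_message(q, sim_values, c, offsets)
    H, W, L = q.shape
    out = np.zeros_like(q)
    for y in range(H):
        for x in range(W):
            e = np.exp(-(psi[y, x] + msg[y, x]))
            out[y, x] = e / e.sum()
    return out


def loop_gibbs_energy(y_map, psi, sim_values, c, offsets):
    """E(Y|X) by explicit summation."""
    H, W = y_map.shape
    e = 0.0
    for y in range(H):
        for x in range(W):
            e += psi[y, x, y_map[y, x]]
            for k, (dy, dx) in enumerate(offsets):
                ny, nx = y + dy, x + dx
                if 0 <= ny < H and 0 <= nx < W:
                    e += c[y_map[y, x], y_map[ny, nx]] * sim_values[y, x, k]
    return e


def brute_force_nms(detections, iou_thr):
    """Greedy NMS re-done with exhaustive pairwise comparisons.

    `detections` is the already-pooled, priority-ordered list (highest
    priority first).  A detection survives iff no higher-priority
    survivor overlaps it at IoU >= iou_thr.
    """
    survivors = []
    for d in detections:
        suppressed = False
        for s in survivors:
            if mask_iou(d, s) >= iou_thr:
                suppressed = True
                break
        if not suppressed:
            survivors.append(d)
    return survivors


def brute_force_average_precision(preds, gts, iou_thr):
    """AP recomputed with an independent matcher and rectangle integration."""
    ranked = sorted(range(len(preds)), key=lambda i: (-preds[i].score, i))
    used = [False] * len(gts)
    flags = []
    for pi in ranked:
        best, best_j = 0.0, -1
        for j in range(len(gts)):
            if used[j]:
                continue
            iou = mask_iou(preds[pi], gts[j])
            if iou > best:
                best, best_j = iou, j
        if best_j >= 0 and best >= iou_thr:
            used[best_j] = True
            flags.append(True)
        else:
            flags.append(False)
    if not gts or not flags:
        return 0.0
    # precision at every rank, envelope from the right, rectangle sum
    precisions, recalls = [], []
    tp = 0
    for rank, f in enumerate(flags, start=1):
        tp += bool(f)
        precisions.append(tp / rank)
        recalls.append(tp / len(gts))
    env = precisions[:]
    for i in range(len(env) - 2, -1, -1):
        env[i] = max(env[i], env[i + 1])
    ap, prev = 0.0, 0.0
    for r, p in zip(recalls, env):
        ap += (r - prev) * p
        prev = r
    return ap


def random_instance(rng, shape=(8, 8), num_labels=2, coupling=1.0):
    """A random CRF instance (psi, sim values, c) for oracle comparisons."""
    from sonarseg.crf import NeighborhoodSpec, SimilarityMap

    spec = NeighborhoodSpec()
    H, W = shape
    psi = rng.uniform(0.0, 3.0, (H, W, num_labels))
    sim = rng.uniform(0.0, 1.0, (H, W, len(spec.offsets))) * coupling
    sim *= spec.valid_mask((H, W))
    c = rng.uniform(0.0, 1.0, (num_labels, num_labels)) * coupling
    return psi, SimilarityMap(values=sim, spec=spec), c


def random_masks(rng, n, shape=(24, 24), min_size=3, max_size=10):
    """Random rectangular instance masks with random scores."""
    H, W = shape
    out = []
    for _ in range(n):
        h = int(rng.integers(min_size, max_size))
        w = int(rng.integers(min_size, max_size))
        y = int(rng.integers(0, H - h))
        x = int(rng.integers(0, W - w))
        m = np.zeros(shape, dtype=bool)
        m[y : y + h, x : x + w] = True
        out.append(InstanceMask.from_mask(m, float(rng.uniform(0.05, 1.0))))
    return out
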