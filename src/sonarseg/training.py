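"""Semi-supervised EM training on partially annotated frame stacks.

Annotation images label each pixel background, fish (or one of four
motion-direction categories), or leave it unlabeled.  Labeled pixels
carry constant one-hot indicators h; for unlabeled pixels the h are
latent.  Training maximizes the expected complete-data log-likelihood

    pi(Theta | Theta^(t-1)) =
        sum_s sum_{i not in A_s} sum_u E[h_{s,i,u}] log Q_i;Theta(u | X_s)
      + C * sum_{i in A_s} sum_u h_{s,i,u} log Q_i;Theta(u | X_s)

where A_s is the labeled-pixel set of image s, the E-step expectation
for an unlabeled pixel is the previous model's posterior
E[h] = Q_i;Theta^(t-1), and the labeled-pixel weight C defaults to 1.
The M-step is mini-batch gradient descent on -pi with the E-step
expectations held constant; the compatibility table is projected back
onto the nonnegative orthant after every step.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .model import CrfSegmenter
from .unary import FrameStack

__all__ = [
    "AnnotationImage",
    "Responsibilities",
    "TrainingConfig",
    "e_step",
    "em_objective",
    "fit",
]

# Annotation pixel codes.  Directional annotations use codes 2-5 in the
# order of the directional label set (NW, NE, SW, SE).
UNLABELED, BACKGROUND, FISH = 0, 1, 2


@dataclass
class AnnotationImage:
    """Partial pixel labeling: 0 = unlabeled, 1 = background, 2.. = fish."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 2:
            raise ValueError("labels must be an H x W map")
        if self.labels.min() < 0:
            raise ValueError("label codes must be nonnegative")

    @property
    def labeled_mask(self) -> np.ndarray:
        """A_s: boolean mask of manually annotated pixels."""
        return self.labels > 0

    def num_labeled(self) -> int:
        return int(self.labeled_mask.sum())

    def class_indices(self) -> np.ndarray:
        """0-based class index per pixel (undefined where unlabeled)."""
        return np.maximum(self.labels - 1, 0)

    def onehot(self, num_labels: int) -> np.ndarray:
        """(H, W, L) one-hot rows at labeled pixels, zeros elsewhere."""
        if self.labels.max() > num_labels:
            raise ValueError(
                f"label code {self.labels.max()} exceeds {num_labels} classes"
            )
        H, W = self.labels.shape
        out = np.zeros((H, W, num_labels))
        mask = self.labeled_mask
        iy, ix = np.nonzero(mask)
        out[iy, ix, self.labels[iy, ix] - 1] = 1.0
        return out


@dataclass
class Responsibilities:
    """Per-pixel expected label indicators: one-hot where annotated,
    the previous model's posterior where latent.  Rows sum to 1."""

    h: np.ndarray

    def __post_init__(self):
        sums = self.h.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("responsibility rows must sum to 1")


@dataclass
class TrainingConfig:
    """Hyperparameters of the EM loop and its gradient-based M-step."""

    labeled_weight: float = 1.0  # C
    learning_rate: float = 1e-3
    momentum: float = 0.9
    batch_size: int = 2
    epochs: int = 20
    em_refresh: int = 1  # recompute E-step every this many epochs
    seed: int = 0

    def __post_init__(self):
        if self.labeled_weight <= 0:
            raise ValueError("labeled weight C must be positive")
        if self.batch_size < 1 or self.epochs < 1 or self.em_refresh < 1:
            raise ValueError("batch_size, epochs and em_refresh must be >= 1")


def e_step(
    model: CrfSegmenter, x: FrameStack, ann: AnnotationImage
) -> Responsibilities:
    """Expectation step for one image under the current parameters.

    Labeled pixels keep their constant one-hot indicators; unlabeled
    pixels receive the model's current posterior Q, treated as constant
    during the subsequent M-step.
    """
    if ann.labels.shape != x.frames.shape[:2]:
        raise ValueError("annotation and frame stack shapes differ")
    h = ann.onehot(model.num_labels)
    mask = ann.labeled_mask
    if not mask.all():
        q = model.predict(x).q  # detached: no gradient flows through these
        h[~mask] = q[~mask]
    return Responsibilities(h=h)


def _em_objective_t(
    model: CrfSegmenter,
    x: FrameStack,
    resp: Responsibilities,
    ann: AnnotationImage,
    C: float = 1.0,
    training: bool = False,
    rng=None,
) -> Tensor:
    """Differentiable pi for one image (a scalar Tensor, always <= 0)."""
    q = model.forward_t(x.frames, training=training, rng=rng)
    logq = ad.log(ad.clamp_min(q, model.eps))
    weights = np.where(ann.labeled_mask, C, 1.0)[:, :, None]
    return ad.tsum(ad.mul(Tensor(resp.h * weights), logq))


def em_objective(
    model: CrfSegmenter,
    x: FrameStack,
    resp: Responsibilities,
    ann: AnnotationImage,
    C: float = 1.0,
) -> float:
    """pi(Theta | Theta^(t-1)) for one image: the expected complete-data
    log-likelihood, with labeled pixels weighted by C.  Nonpositive;
    equals 0 only when Q puts probability 1 on every expected label."""
    return float(_em_objective_t(model, x, resp, ann, C=C).data)


def _labeled_accuracy(model, dataset) -> float:
    correct = total = 0
    for x, ann in dataset:
        mask = ann.labeled_mask
        if not mask.any():
            continue
        pred = model.predict(x).label_map()
        correct += int((pred[mask] == (ann.labels[mask] - 1)).sum())
        total += int(mask.sum())
    return correct / total if total else float("nan")


def fit(
    model: CrfSegmenter,
    dataset: list[tuple[FrameStack, AnnotationImage]],
    cfg: TrainingConfig,
) -> tuple[CrfSegmenter, list[dict]]:
    """EM training loop: alternate E-steps with mini-batch ascent on pi.

    Per-image losses are normalized by pixel count so C keeps its
    meaning as a relative weight.  Returns the trained model and a
    per-epoch history (epoch, loss = mean -pi/HW, labeled accuracy).
    """
    if not dataset:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(cfg.seed)
    opt = ad.SGD(model.parameters(), lr=cfg.learning_rate, momentum=cfg.momentum)
    history: list[dict] = []
    resp: list[Responsibilities] = []
    n = len(dataset)
    for epoch in range(cfg.epochs):
        if epoch % cfg.em_refresh == 0:
            resp = [e_step(model, x, ann) for x, ann in dataset]
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            opt.zero_grad()
            loss_val = 0.0
            batch_loss = None
            for idx in batch:
                x, ann = dataset[idx]
                npix = x.frames.shape[0] * x.frames.shape[1]
                pi = _em_objective_t(
                    model, x, resp[idx], ann, C=cfg.labeled_weight,
                    training=True, rng=rng,
                )
                term = ad.scale(ad.neg(pi), 1.0 / (npix * len(batch)))
                batch_loss = term if batch_loss is None else ad.add(batch_loss, term)
            batch_loss.backward()
            loss_val = float(batch_loss.data)
            if not np.isfinite(loss_val):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {loss_val}"
                )
            opt.step()
            model.project()
            epoch_loss += loss_val * len(batch) / n
        history.append(
            {
                "epoch": epoch,
                "loss": epoch_loss,
                "labeled_accuracy": _labeled_accuracy(model, dataset),
            }
        )
    return model, history


def write_history_csv(history: list[dict], path):
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["epoch", "loss", "labeled_accuracy"])
        writer.writeheader()
        writer.writerows(history)
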