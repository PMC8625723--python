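"""Dilated fully-convolutional unary network.

The per-pixel label posterior phi_u(y_i | X) is produced by a small
fully-convolutional network that keeps the full input resolution
throughout: four blocks of 3x3 convolutions with dilation rates 1, 2, 4
and 6 widen the receptive field without any pooling or striding, the
last-layer outputs of the four blocks are concatenated channelwise, and
a fifth block (dropout followed by three 1x1 convolutions) maps the
concatenation to one logit per label, normalized by a softmax.

The first block's activation doubles as the per-pixel feature map
consumed by the pairwise similarity network of the CRF layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

DILATION_RATES = (1, 2, 4, 6)


@dataclass(frozen=True)
class LabelSet:
    """Label vocabulary: background plus fish, or plus 4 motion directions."""

    num_labels: int
    roles: tuple[str, ...]

    def __post_init__(self):
        if self.num_labels != len(self.roles):
            raise ValueError("num_labels must match roles")
        if self.num_labels not in (2, 5):
            raise ValueError("label set must be binary (2) or directional (5)")

    @classmethod
    def binary(cls) -> "LabelSet":
        return cls(2, ("background", "fish"))

    @classmethod
    def directional(cls) -> "LabelSet":
        return cls(5, ("background", "NW", "NE", "SW", "SE"))


@dataclass
class FrameStack:
    """K successive one-channel sonar frames stacked into an H x W x K array.

    Values are expected in [0, 1]; `from_frames` applies the per-frame
    min-max normalization used throughout the package.
    """

    frames: np.ndarray
    frame_interval: float = 1.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be H x W x K")
        if self.frames.shape[2] < 1:
            raise ValueError("need at least one frame")
        if self.frames.min() < -1e-9 or self.frames.max() > 1 + 1e-9:
            raise ValueError("frame values must lie in [0, 1]")

    @property
    def num_frames(self) -> int:
        return self.frames.shape[2]

    @property
    def middle_frame(self) -> np.ndarray:
        return self.frames[:, :, self.frames.shape[2] // 2]

    @classmethod
    def from_frames(cls, frames, frame_interval: float = 1.0) -> "FrameStack":
        """Stack raw frames, min-max rescaling each to [0, 1] (gain robust)."""
        arrs = [np.asarray(f, dtype=np.float64) for f in frames]
        shape = arrs[0].shape
        if any(a.shape != shape or a.ndim != 2 for a in arrs):
            raise ValueError("all frames must share the same H x W shape")
        norm = []
        for a in arrs:
            lo, hi = a.min(), a.max()
            norm.append((a - lo) / (hi - lo) if hi > lo else np.zeros_like(a))
        return cls(np.stack(norm, axis=2), frame_interval)

    @classmethod
    def from_files(cls, paths, frame_interval: float = 1.0) -> "FrameStack":
        """Assemble a stack from an ordered list of grayscale image files."""
        return cls.from_frames([iio.imread(p) for p in paths], frame_interval)


def sliding_stacks(directory, k: int = 3, pattern: str = "*.png"):
    """Yield FrameStacks from a sliding window over sorted frames on disk."""
    paths = sorted(Path(directory).glob(pattern))
    for i in range(len(paths) - k + 1):
        yield FrameStack.from_files(paths[i : i + k])


@dataclass(frozen=True)
class UnaryConfig:
    """Architecture knobs for the unary network.

    block_width: channels per dilated block (the fifth block sees
    4 * block_width concatenated channels).  convs_per_block: 3x3 layers
    in each dilated block.  dropout: rate of the fifth block's dropout
    layer, active only during training.
    """

    in_channels: int = 3
    num_labels: int = 2
    block_width: int = 32
    convs_per_block: int = 2
    head_width: int = 32
    dropout: float = 0.5
    dilation_rates: tuple[int, ...] = DILATION_RATES

    def __post_init__(self):
        if self.num_labels not in (2, 5):
            raise ValueError("num_labels must be 2 or 5")
        if self.block_width < 1 or self.convs_per_block < 1 or self.head_width < 1:
            raise ValueError("widths and layer counts must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        if any(d < 1 for d in self.dilation_rates) or len(self.dilation_rates) != 4:
            raise ValueError("expected four dilation rates >= 1")

    def to_dict(self) -> dict:
        return {
            "in_channels": self.in_channels,
            "num_labels": self.num_labels,
            "block_width": self.block_width,
            "convs_per_block": self.convs_per_block,
            "head_width": self.head_width,
            "dropout": self.dropout,
            "dilation_rates": list(self.dilation_rates),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "UnaryConfig":
        d = dict(d)
        d["dilation_rates"] = tuple(d.get("dilation_rates", DILATION_RATES))
        return cls(**d)


def _he_init(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class UnaryNetwork:
    """phi_u: frame stack -> per-pixel label posterior + first-block features."""

    def __init__(self, config: UnaryConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        w = config.block_width
        self.blocks: list[list[tuple[Tensor, Tensor]]] = []
        cin = config.in_channels
        for _ in config.dilation_rates:
            layers = []
            c = cin
            for _ in range(config.convs_per_block):
                layers.append(
                    (
                        ad.parameter(_he_init(rng, (3, 3, c, w), 9 * c)),
                        ad.parameter(np.zeros(w)),
                    )
                )
                c = w
            self.blocks.append(layers)
            cin = w  # blocks are chained: each block reads the previous one
        concat_c = w * len(config.dilation_rates)
        h = config.head_width
        self.head = [
            (ad.parameter(_he_init(rng, (concat_c, h), concat_c)), ad.parameter(np.zeros(h))),
            (ad.parameter(_he_init(rng, (h, h), h)), ad.parameter(np.zeros(h))),
            (
                ad.parameter(_he_init(rng, (h, config.num_labels), h)),
                ad.parameter(np.zeros(config.num_labels)),
            ),
        ]

    @property
    def dilation_rates(self) -> tuple[int, ...]:
        return tuple(self.config.dilation_rates)

    @property
    def feature_channels(self) -> int:
        return self.config.block_width

    def parameters(self) -> list[Tensor]:
        ps = []
        for block in self.blocks:
            for w, b in block:
                ps += [w, b]
        for w, b in self.head:
            ps += [w, b]
        return ps

    def forward_t(
        self, x: np.ndarray, training: bool = False, rng=None
    ) -> tuple[Tensor, Tensor]:
        """Tensor-valued forward pass: (probs H x W x L, features H x W x F)."""
        if x.ndim != 3 or x.shape[2] != self.config.in_channels:
            raise ValueError(
                f"expected H x W x {self.config.in_channels} input, got {x.shape}"
            )
        t = ad.as_tensor(x)
        block_outs = []
        for layers, rate in zip(self.blocks, self.config.dilation_rates):
            for w, b in layers:
                t = ad.relu(ad.conv3x3(t, w, b, dilation=rate))
            block_outs.append(t)
        features = block_outs[0]
        h = ad.concat(block_outs, axis=-1)
        if training and self.config.dropout > 0.0:
            if rng is None:
                raise ValueError("training-mode forward needs an rng for dropout")
            keep = 1.0 - self.config.dropout
            mask = (rng.random(h.shape) < keep) / keep
            h = ad.mul(h, Tensor(mask))
        (w0, b0), (w1, b1), (w2, b2) = self.head
        h = ad.relu(ad.conv1x1(h, w0, b0))
        h = ad.relu(ad.conv1x1(h, w1, b1))
        logits = ad.conv1x1(h, w2, b2)
        return ad.softmax(logits), features

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for bi, block in enumerate(self.blocks):
            for li, (w, b) in enumerate(block):
                out[f"block{bi}.conv{li}.w"] = w.data
                out[f"block{bi}.conv{li}.b"] = b.data
        for li, (w, b) in enumerate(self.head):
            out[f"head.conv{li}.w"] = w.data
            out[f"head.conv{li}.b"] = b.data
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for bi, block in enumerate(self.blocks):
            for li, (w, b) in enumerate(block):
                w.data = np.array(state[f"block{bi}.conv{li}.w"], dtype=np.float64)
                b.data = np.array(state[f"block{bi}.conv{li}.b"], dtype=np.float64)
        for li, (w, b) in enumerate(self.head):
            w.data = np.array(state[f"head.conv{li}.w"], dtype=np.float64)
            b.data = np.array(state[f"head.conv{li}.b"], dtype=np.float64)


def build_unary_network(config: UnaryConfig, seed: int = 0) -> UnaryNetwork:
    """Construct the dilated unary network from its configuration."""
    return UnaryNetwork(config, seed=seed)


def unary_forward(
    net: UnaryNetwork, x: FrameStack
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluation-mode forward pass (dropout off, deterministic).

    Returns (probs H x W x L, features H x W x F) as numpy arrays, at the
    full input resolution.
    """
    probs, feats = net.forward_t(x.frames, training=False)
    return probs.data, feats.data


def unary_potential(probs: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """psi_u = -log(max(phi_u, eps)): nonnegative cost per pixel and label."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    return -np.log(np.maximum(np.asarray(probs, dtype=np.float64), eps))
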