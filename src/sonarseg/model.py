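"""Full segmentation model: unary network + CRF layer, trained jointly.

`CrfSegmenter` wires the dilated unary network, the pairwise similarity
network and the compatibility table into a single differentiable
computation: unary posterior -> unary potential -> T recurrent parallel
mean-field updates -> per-pixel label posterior Q.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import autodiff as ad
from . import crf
from .autodiff import Tensor
from .unary import FrameStack, UnaryConfig, UnaryNetwork

__all__ = ["CrfSegmenter"]


class CrfSegmenter:
    """End-to-end trainable CRF segmenter for sonar frame stacks."""

    def __init__(
        self,
        unary_config: UnaryConfig,
        mf_iterations: int = 5,
        sim_hidden: int = 16,
        eps: float = 1e-8,
        seed: int = 0,
    ):
        if mf_iterations < 0:
            raise ValueError("mf_iterations must be >= 0")
        self.config = unary_config
        self.mf_iterations = int(mf_iterations)
        self.eps = float(eps)
        self.spec = crf.NeighborhoodSpec()
        self.unary = UnaryNetwork(unary_config, seed=seed)
        self.similarity = crf.SimilarityNet(
            self.unary.feature_channels, hidden=sim_hidden, spec=self.spec, seed=seed + 1
        )
        self.compat = crf.CompatibilityParams(unary_config.num_labels)

    @property
    def num_labels(self) -> int:
        return self.config.num_labels

    def parameters(self) -> list[Tensor]:
        return (
            self.unary.parameters()
            + self.similarity.parameters()
            + self.compat.parameters()
        )

    def project(self):
        """Re-impose parameter constraints (compatibility >= 0)."""
        self.compat.project()

    def forward_t(self, x: np.ndarray, training: bool = False, rng=None) -> Tensor:
        """Differentiable posterior Q (H x W x L) for a raw frame array."""
        probs, feats = self.unary.forward_t(x, training=training, rng=rng)
        psi = ad.neg(ad.log(ad.clamp_min(probs, self.eps)))
        sim = self.similarity.compute_t(feats)
        return crf._infer_t(psi, sim, self.compat.c, self.spec, self.mf_iterations)

    def predict(self, stack: FrameStack) -> crf.MeanFieldState:
        """Evaluation-mode posterior as a MeanFieldState (no gradients)."""
        q = self.forward_t(stack.frames, training=False)
        return crf.MeanFieldState(q=q.data, t=self.mf_iterations)

    # Persistence ----------------------------------------------------
    def save(self, path):
        """Write weights (.npz) and a plain-text JSON config side by side."""
        path = Path(path)
        state = {}
        state.update(self.unary.state_dict())
        state.update(self.similarity.state_dict())
        state["compat.c"] = self.compat.c.data
        np.savez(path.with_suffix(".npz"), **state)
        meta = {
            "unary": self.config.to_dict(),
            "mf_iterations": self.mf_iterations,
            "sim_hidden": self.similarity.w1.data.shape[1],
            "eps": self.eps,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "CrfSegmenter":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(
            UnaryConfig.from_dict(meta["unary"]),
            mf_iterations=meta["mf_iterations"],
            sim_hidden=meta["sim_hidden"],
            eps=meta["eps"],
        )
        with np.load(path.with_suffix(".npz")) as state:
            state = dict(state)
            model.unary.load_state_dict(state)
            model.similarity.load_state_dict(state)
            model.compat.c.data = np.array(state["compat.c"], dtype=np.float64)
        return model
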