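"""Trainable conditional random field with parallel mean-field inference.

The label map Y over a frame stack X is modeled by a Gibbs distribution

    P(Y|X) = exp(-E(Y|X)) / Z(X),
    E(Y|X) = sum_i psi_u(y_i|X) + sum_i sum_{j in N_i} c(y_i, y_j) f(f_i, f_j, d_ij),

where psi_u is the unary cost (-log of the unary network's posterior),
c(u, v) is a trainable nonnegative label-compatibility table, and
f(f_i, f_j, d_ij) in (0, 1) is a trainable similarity between the deep
features of neighboring pixels, realized as the product of two sigmoids
("nearby" and "feature-similar") computed by a stack of 1x1
convolutions on the aligned feature maps.  N_i is the 3x3 neighborhood
of pixel i (8 offsets, center excluded).

Inference uses the fully factorized mean-field approximation
Q(Y|X) = prod_i Q_i(y_i|X), iterated as a fixed point:

    Q_i^(t)(u) ∝ exp(-(psi_u(i, u) + sum_v c(u, v) sum_j f_ij Q_j^(t-1)(v)))

with Q^(0) ∝ exp(-psi_u).  All pixels update in parallel, so T
iterations form a recurrent layer that is differentiable end to end;
the whole parameter set (unary net, similarity net, compatibility)
trains jointly.

Exact enumeration oracles (posterior, marginals, KL divergence) are
provided for tiny instances and back the correctness tests.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "NeighborhoodSpec",
    "SimilarityMap",
    "SimilarityNet",
    "CompatibilityParams",
    "MeanFieldState",
    "ExactPosterior",
    "pairwise_similarity",
    "pairwise_message",
    "meanfield_init",
    "meanfield_step",
    "meanfield_infer",
    "meanfield_sweep_sequential",
    "gibbs_energy",
    "oracle_exact_posterior",
    "kl_divergence",
]


@dataclass(frozen=True)
class NeighborhoodSpec:
    """Offsets (dy, dx) defining N_i; default: 3x3 window minus the center."""

    offsets: tuple[tuple[int, int], ...] = tuple(
        (dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)
    )

    def __post_init__(self):
        for dy, dx in self.offsets:
            if (dy, dx) == (0, 0) or abs(dy) > 1 or abs(dx) > 1:
                raise ValueError("offsets must come from the 3x3 window, center excluded")

    @property
    def distances(self) -> tuple[float, ...]:
        return tuple(math.hypot(dy, dx) for dy, dx in self.offsets)

    def index_of(self, offset: tuple[int, int]) -> int:
        try:
            return self.offsets.index(tuple(offset))
        except ValueError:
            raise ValueError(f"offset {offset} not in neighborhood") from None

    def valid_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """(H, W, |N|) mask, 1 where the neighbor falls inside the image."""
        H, W = shape
        ones = np.ones((H, W))
        return np.stack(
            [ad.shift_array(ones, dy, dx) for dy, dx in self.offsets], axis=-1
        )


@dataclass
class SimilarityMap:
    """f(f_i, f_j, d_ij) for every pixel i and neighbor offset.

    values[y, x, k] is the similarity between pixel (y, x) and its
    neighbor at spec.offsets[k]; 0 where the neighbor is out of image.
    """

    values: np.ndarray
    spec: NeighborhoodSpec


@dataclass
class MeanFieldState:
    """Factorized posterior Q: one probability vector per pixel."""

    q: np.ndarray
    t: int = 0

    @property
    def num_labels(self) -> int:
        return self.q.shape[-1]

    def label_map(self) -> np.ndarray:
        return np.argmax(self.q, axis=-1)


class SimilarityNet:
    """Trainable pairwise similarity f = sigmoid(spatial) * sigmoid(feature).

    For each neighborhood offset the first-block feature map is zero-
    padded and shifted so that f_i and f_j align, the pair (f_i, f_j) is
    concatenated channelwise and mapped by two 1x1 convolution layers to
    two scalar logits.  A learned per-offset bias is added to the
    spatial ("nearby") logit -- with a fixed 3x3 neighborhood the
    distance d_ij only takes two values, so a per-offset bias encodes it
    exactly.  Out-of-image neighbors get similarity 0.
    """

    def __init__(
        self,
        feature_channels: int,
        hidden: int = 16,
        spec: NeighborhoodSpec | None = None,
        seed: int = 0,
        init_scale: float = 0.1,
    ):
        self.spec = spec or NeighborhoodSpec()
        self.feature_channels = feature_channels
        rng = np.random.default_rng(seed)
        f2 = 2 * feature_channels
        self.w1 = ad.parameter(rng.normal(0.0, init_scale, (f2, hidden)))
        self.b1 = ad.parameter(np.zeros(hidden))
        self.w2 = ad.parameter(rng.normal(0.0, init_scale, (hidden, 2)))
        self.b2 = ad.parameter(np.zeros(2))
        self.offset_bias = [ad.parameter(0.0) for _ in self.spec.offsets]

    def parameters(self) -> list[Tensor]:
        return [self.w1, self.b1, self.w2, self.b2, *self.offset_bias]

    def compute_t(self, features: Tensor) -> Tensor:
        """Tensor-valued similarity map (H, W, |N|)."""
        H, W = features.data.shape[:2]
        mask = self.spec.valid_mask((H, W))
        sims = []
        for k, (dy, dx) in enumerate(self.spec.offsets):
            fj = ad.shift2d(features, dy, dx)
            h = ad.relu(ad.conv1x1(ad.concat([features, fj], axis=-1), self.w1, self.b1))
            logits = ad.conv1x1(h, self.w2, self.b2)
            spatial = ad.add(ad.channel(logits, 0), self.offset_bias[k])
            s = ad.mul(ad.sigmoid(spatial), ad.sigmoid(ad.channel(logits, 1)))
            sims.append(ad.mul(s, Tensor(mask[:, :, k : k + 1])))
        return ad.concat(sims, axis=-1)

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {"sim.w1": self.w1.data, "sim.b1": self.b1.data,
               "sim.w2": self.w2.data, "sim.b2": self.b2.data}
        for k, b in enumerate(self.offset_bias):
            out[f"sim.offset_bias{k}"] = b.data
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]):
        self.w1.data = np.array(state["sim.w1"], dtype=np.float64)
        self.b1.data = np.array(state["sim.b1"], dtype=np.float64)
        self.w2.data = np.array(state["sim.w2"], dtype=np.float64)
        self.b2.data = np.array(state["sim.b2"], dtype=np.float64)
        for k, b in enumerate(self.offset_bias):
            b.data = np.array(state[f"sim.offset_bias{k}"], dtype=np.float64)


class CompatibilityParams:
    """Nonnegative label-compatibility table c(u, v), no bias, linear.

    c[u, v] is the cost coupling from a neighbor believed to carry label
    v onto label u at the center pixel.  Nonnegativity is enforced by
    projection (clamping at 0) after every optimizer step.
    """

    def __init__(self, num_labels: int, init: np.ndarray | None = None, seed: int = 0):
        if init is None:
            # Potts-like start: penalize disagreeing neighbor labels.
            init = 0.1 * (1.0 - np.eye(num_labels))
        init = np.asarray(init, dtype=np.float64)
        if init.shape != (num_labels, num_labels):
            raise ValueError("compatibility table must be L x L")
        if (init < 0).any():
            raise ValueError("compatibility entries must be nonnegative")
        self.c = ad.parameter(init)

    @property
    def num_labels(self) -> int:
        return self.c.data.shape[0]

    def parameters(self) -> list[Tensor]:
        return [self.c]

    def project(self):
        np.maximum(self.c.data, 0.0, out=self.c.data)


# ----------------------------------------------------------------------
# Internal tensor-valued ops (single implementation; numpy API wraps these)

def _coerce_sim(sim) -> tuple[object, NeighborhoodSpec]:
    if isinstance(sim, SimilarityMap):
        return sim.values, sim.spec
    raise TypeError("sim must be a SimilarityMap (values + neighborhood spec)")


def _coerce_c(c):
    if isinstance(c, CompatibilityParams):
        return c.c
    return ad.as_tensor(np.asarray(c, dtype=np.float64))


def _message_t(q: Tensor, sim: Tensor, c: Tensor, spec: NeighborhoodSpec) -> Tensor:
    """phi_p[i, u] = sum_v c[u, v] * sum_{j in N_i} f_ij * q[j, v]."""
    agg = None
    for k, (dy, dx) in enumerate(spec.offsets):
        term = ad.mul(ad.channel(sim, k), ad.shift2d(q, dy, dx))
        agg = term if agg is None else ad.add(agg, term)
    return ad.conv1x1(agg, ad.transpose2d(c))


def _init_t(psi: Tensor) -> Tensor:
    return ad.softmax(ad.neg(psi))


def _step_t(q: Tensor, psi: Tensor, sim: Tensor, c: Tensor, spec) -> Tensor:
    msg = _message_t(q, sim, c, spec)
    return ad.softmax(ad.neg(ad.add(psi, msg)))


def _infer_t(psi: Tensor, sim: Tensor, c: Tensor, spec, iterations: int) -> Tensor:
    q = _init_t(psi)
    for _ in range(iterations):
        q = _step_t(q, psi, sim, c, spec)
    return q


# ----------------------------------------------------------------------
# Public numpy-facing API

def pairwise_similarity(
    features: np.ndarray, spec: NeighborhoodSpec, net: SimilarityNet
) -> SimilarityMap:
    """Evaluate the similarity network on a feature map (no gradients)."""
    if spec.offsets != net.spec.offsets:
        raise ValueError("neighborhood spec does not match the similarity net")
    values = net.compute_t(ad.as_tensor(np.asarray(features, dtype=np.float64)))
    return SimilarityMap(values=values.data, spec=spec)


def pairwise_message(q, sim: SimilarityMap, c) -> np.ndarray:
    """One parallel message pass: phi_p for every pixel and label."""
    qa = q.q if isinstance(q, MeanFieldState) else np.asarray(q, dtype=np.float64)
    values, spec = _coerce_sim(sim)
    out = _message_t(ad.as_tensor(qa), ad.as_tensor(values), _coerce_c(c), spec)
    return out.data


def meanfield_init(psi: np.ndarray) -> MeanFieldState:
    """Q^(0) proportional to exp(-psi_u), normalized per pixel."""
    return MeanFieldState(q=_init_t(ad.as_tensor(psi)).data, t=0)


def meanfield_step(state: MeanFieldState, psi, sim: SimilarityMap, c) -> MeanFieldState:
    """One synchronous parallel update of every pixel's distribution."""
    values, spec = _coerce_sim(sim)
    q = _step_t(
        ad.as_tensor(state.q), ad.as_tensor(psi), ad.as_tensor(values), _coerce_c(c), spec
    )
    return MeanFieldState(q=q.data, t=state.t + 1)


def meanfield_infer(psi, sim: SimilarityMap, c, iterations: int = 5) -> MeanFieldState:
    """Initialize from the unary potential and run `iterations` parallel updates."""
    values, spec = _coerce_sim(sim)
    q = _infer_t(
        ad.as_tensor(psi), ad.as_tensor(values), _coerce_c(c), spec, iterations
    )
    return MeanFieldState(q=q.data, t=iterations)


def gibbs_energy(y: np.ndarray, psi, sim: SimilarityMap, c) -> float:
    """E(Y|X) = sum_i psi_u(y_i) + sum_i sum_{j in N_i} c(y_i, y_j) f_ij.

    `y` holds 0-based label indices.  Out-of-image neighbor terms are
    dropped (the valid mask zeroes them even if `sim.values` is nonzero
    at the boundary).
    """
    y = np.asarray(y)
    psi = np.asarray(psi, dtype=np.float64)
    values, spec = _coerce_sim(sim)
    cm = _coerce_c(c).data
    H, W = y.shape
    iy, ix = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    e = psi[iy, ix, y].sum()
    mask = spec.valid_mask((H, W))
    for k, (dy, dx) in enumerate(spec.offsets):
        # neighbor labels aligned at each pixel; pad value irrelevant (masked)
        yj = ad.shift_array(y.astype(np.int64), dy, dx)
        e += (mask[:, :, k] * values[:, :, k] * cm[y, yj]).sum()
    return float(e)


@dataclass
class ExactPosterior:
    """Exhaustively enumerated Gibbs posterior on a tiny grid."""

    shape: tuple[int, int]
    num_labels: int
    configs: np.ndarray  # (n_configs, H*W) label indices
    probs: np.ndarray  # (n_configs,)
    log_z: float
    marginals: np.ndarray  # (H, W, L)


def oracle_exact_posterior(psi, sim: SimilarityMap, c, max_configs: int = 2**20) -> ExactPosterior:
    """Enumerate every label map of a tiny instance and normalize exactly."""
    psi = np.asarray(psi, dtype=np.float64)
    H, W, L = psi.shape
    n = L ** (H * W)
    if n > max_configs:
        raise ValueError(f"instance too large to enumerate ({n} configurations)")
    configs = np.array(list(itertools.product(range(L), repeat=H * W)), dtype=np.int64)
    energies = np.array(
        [gibbs_energy(cfg.reshape(H, W), psi, sim, c) for cfg in configs]
    )
    m = energies.min()
    unnorm = np.exp(-(energies - m))
    z = unnorm.sum()
    probs = unnorm / z
    log_z = np.log(z) - m
    marginals = np.zeros((H, W, L))
    flat = marginals.reshape(H * W, L)
    for cfg, p in zip(configs, probs):
        flat[np.arange(H * W), cfg] += p
    return ExactPosterior(
        shape=(H, W), num_labels=L, configs=configs, probs=probs,
        log_z=log_z, marginals=marginals,
    )


def kl_divergence(state: MeanFieldState, exact: ExactPosterior) -> float:
    """D_KL(prod_i Q_i || P) over the enumerated configuration space."""
    H, W = exact.shape
    qflat = state.q.reshape(H * W, exact.num_labels)
    idx = np.arange(H * W)
    kl = 0.0
    for cfg, p in zip(exact.configs, exact.probs):
        qy = qflat[idx, cfg].prod()
        if qy > 0.0:
            kl += qy * (np.log(qy) - np.log(p))
    return float(kl)


def meanfield_sweep_sequential(
    state: MeanFieldState, psi, sim: SimilarityMap, c
) -> MeanFieldState:
    """One raster-order sweep of exact coordinate-ascent mean-field updates.

    Unlike the parallel fixed-point update, each pixel here is updated
    in turn using the full conditional expectation of the energy terms
    that contain it -- both orientations of every pairwise term.  Each
    such update is the exact minimizer of KL(Q || P) in that coordinate,
    so the KL divergence is non-increasing over sweeps.  Used as a
    correctness oracle on enumerable instances.
    """
    psi = np.asarray(psi, dtype=np.float64)
    values, spec = _coerce_sim(sim)
    cm = _coerce_c(c).data
    H, W, L = psi.shape
    mask = spec.valid_mask((H, W))
    q = state.q.copy()
    rev = [spec.index_of((-dy, -dx)) for dy, dx in spec.offsets]
    for y in range(H):
        for x in range(W):
            logits = -psi[y, x].copy()
            for k, (dy, dx) in enumerate(spec.offsets):
                ny, nx = y + dy, x + dx
                if not (0 <= ny < H and 0 <= nx < W):
                    continue
                # i as source: c(y_i, y_j) f_ij
                if mask[y, x, k]:
                    logits -= values[y, x, k] * (cm @ q[ny, nx])
                # i as target of neighbor j: c(y_j, y_i) f_ji
                kr = rev[k]
                if mask[ny, nx, kr]:
                    logits -= values[ny, nx, kr] * (cm.T @ q[ny, nx])
            logits -= logits.max()
            e = np.exp(logits)
            q[y, x] = e / e.sum()
    return MeanFieldState(q=q, t=state.t + 1)
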