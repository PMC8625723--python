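"""Seeded generator of sonar-like frame triplets with ground truth.

Real sonar sequences of farmed fish are not publicly available, so the
package ships a generator that emulates their salient statistics: fish
appear as bright oriented ellipses that move a few pixels between
successive frames; the background carries a bottom-echo band and
multiplicative Rayleigh-like speckle; environments differ in gain
(brightness), fish/background contrast and blur.  Three presets mirror
a gradient of difficulty: "A" a clear indoor pond, "B" the same pond at
a higher gain setting (brighter fish, more speckle), and "C" an outdoor
mud-bottom pond where fish are blurrier and lower contrast.

Annotations follow a partial-labeling protocol: only fish whose
boundary is unambiguous (here: non-overlapping and sufficiently
contrasted) receive fish labels, and only on an eroded core of the true
mask; a ring around each annotated fish and a few fish-free patches are
labeled background; everything else stays unlabeled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage import draw, morphology

from .masks import InstanceMask, rle_decode, rle_encode, tight_bbox
from .standardize import DIRECTIONS
from .training import AnnotationImage
from .unary import FrameStack

__all__ = [
    "EnvironmentProfile",
    "FishTrack",
    "SyntheticScene",
    "make_environment",
    "simulate_scene",
    "render_annotation",
    "write_dataset",
    "load_dataset",
]


@dataclass(frozen=True)
class EnvironmentProfile:
    """Imaging statistics of one fish-farm environment."""

    name: str
    background_level: float  # mean background intensity
    fish_level: float  # mean fish echo intensity
    speckle: float  # multiplicative speckle strength in [0, 1]
    blur_sigma: float  # Gaussian blur radius (px)
    band_center: float = 0.88  # bottom-echo band center, fraction of height
    band_width: float = 2.5  # band Gaussian width (rows)
    band_gain: float = 0.25  # band peak intensity above background

    def __post_init__(self):
        for v in (self.background_level, self.fish_level, self.band_gain):
            if not (0.0 <= v <= 1.0):
                raise ValueError("intensities must lie in [0, 1]")
        if self.fish_level <= self.background_level:
            raise ValueError("fish must be brighter than the background")

    @property
    def contrast(self) -> float:
        return self.fish_level - self.background_level


_PRESETS = {
    "A": EnvironmentProfile(
        name="A", background_level=0.15, fish_level=0.60,
        speckle=0.20, blur_sigma=0.7, band_gain=0.25,
    ),
    "B": EnvironmentProfile(
        name="B", background_level=0.18, fish_level=0.80,
        speckle=0.28, blur_sigma=0.7, band_gain=0.35,
    ),
    "C": EnvironmentProfile(
        name="C", background_level=0.18, fish_level=0.40,
        speckle=0.25, blur_sigma=1.6, band_gain=0.20,
    ),
}


def make_environment(preset: str) -> EnvironmentProfile:
    """Presets A (baseline), B (higher gain), C (low contrast, blurry)."""
    try:
        return _PRESETS[preset.upper()]
    except KeyError:
        raise ValueError(f"unknown environment preset {preset!r}") from None


@dataclass
class FishTrack:
    """One fish: middle-frame ellipse plus per-frame displacement."""

    center: tuple[float, float]  # (y, x) at the middle frame
    axes: tuple[float, float]  # (major, minor) semi-axes
    orientation: float  # radians
    displacement: tuple[float, float]  # (dy, dx) per frame step

    @property
    def direction(self) -> str:
        """Motion-direction category from the displacement signs
        (image rows grow southward)."""
        dy, dx = self.displacement
        if dy == 0 or dx == 0:
            raise ValueError("displacement components must be nonzero")
        ns = "N" if dy < 0 else "S"
        ew = "W" if dx < 0 else "E"
        return ns + ew


@dataclass
class SyntheticScene:
    """Frames, per-fish ground truth, and the partial annotation image."""

    frames: np.ndarray  # H x W x K, values in [0, 1]
    env: EnvironmentProfile
    tracks: list[FishTrack]
    masks: list[np.ndarray]  # middle-frame boolean masks
    intensities: list[float]  # realized per-fish echo levels
    overlap_flags: list[bool]  # placed deliberately overlapping
    ambiguous: list[bool]  # true mask intersects another fish
    seed: int
    annotation: AnnotationImage | None = None

    @property
    def directions(self) -> list[str]:
        return [t.direction for t in self.tracks]

    def stack(self) -> FrameStack:
        """Model input: per-frame min-max normalized frame stack."""
        k = self.frames.shape[2]
        return FrameStack.from_frames([self.frames[:, :, f] for f in range(k)])

    @property
    def middle_frame(self) -> np.ndarray:
        return self.frames[:, :, self.frames.shape[2] // 2]

    def gt_instances(self) -> list[InstanceMask]:
        """Evaluation ground truth: the unambiguous fish only."""
        return [
            InstanceMask.from_mask(m, 1.0)
            for m, amb in zip(self.masks, self.ambiguous)
            if not amb
        ]


def _draw_ellipse(shape, center, axes, orientation):
    rr, cc = draw.ellipse(
        center[0], center[1], axes[1], axes[0], shape=shape, rotation=orientation
    )
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def _sample_track(rng, shape, n_frames, axes_range, speed_range) -> FishTrack:
    (a_lo, a_hi), (b_lo, b_hi) = axes_range
    a = rng.uniform(a_lo, a_hi)
    b = rng.uniform(b_lo, b_hi)
    speed = rng.uniform(*speed_range)
    quad = rng.integers(4)  # NW, NE, SW, SE
    theta = np.deg2rad(rng.uniform(10.0, 80.0))
    sy = -1.0 if quad < 2 else 1.0
    sx = -1.0 if quad % 2 == 0 else 1.0
    disp = (sy * speed * np.sin(theta), sx * speed * np.cos(theta))
    orientation = np.arctan2(disp[0], disp[1]) + rng.normal(0.0, 0.15)
    margin = a + speed * (n_frames // 2) + 2.0
    H, W = shape
    if 2 * margin >= min(H, W):
        raise ValueError("fish larger than the frame: impossible geometry")
    center = (rng.uniform(margin, H - margin), rng.uniform(margin, W - margin))
    return FishTrack(center=center, axes=(a, b), orientation=orientation,
                     displacement=disp)


def simulate_scene(
    env: EnvironmentProfile,
    n_fish: int = 6,
    overlap_fraction: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (64, 64),
    n_frames: int = 3,
    annotate: bool = True,
    directional: bool = False,
    axes_range: tuple[tuple[float, float], tuple[float, float]] = (
        (4.0, 7.0),
        (2.0, 3.5),
    ),
    speed_range: tuple[float, float] = (1.5, 3.5),
) -> SyntheticScene:
    """Render one scene: moving elliptical fish over a noisy background.

    Each fish after the first is, with probability `overlap_fraction`,
    deliberately placed to overlap an earlier fish (center within the
    smaller fish's minor axis); otherwise placement is rejection-sampled
    to keep centers farther apart than the summed major semi-axes.
    `axes_range` gives (major, minor) semi-axis ranges in pixels; the
    defaults suit 64 x 64 frames and should be scaled down with the
    frame.  Deterministic for a fixed seed.
    """
    if n_fish < 0:
        raise ValueError("n_fish must be nonnegative")
    rng = np.random.default_rng(seed)
    H, W = shape
    tracks: list[FishTrack] = []
    overlap_flags: list[bool] = []
    for i in range(n_fish):
        overlap = i > 0 and rng.random() < overlap_fraction
        if overlap:
            host = tracks[rng.integers(len(tracks))]
            t = _sample_track(rng, shape, n_frames, axes_range, speed_range)
            r = rng.uniform(0.0, host.axes[1])
            phi = rng.uniform(0.0, 2 * np.pi)
            cy = float(np.clip(host.center[0] + r * np.sin(phi), 0, H - 1))
            cx = float(np.clip(host.center[1] + r * np.cos(phi), 0, W - 1))
            t.center = (cy, cx)
        else:
            for _ in range(200):
                t = _sample_track(rng, shape, n_frames, axes_range, speed_range)
                if all(
                    np.hypot(t.center[0] - o.center[0], t.center[1] - o.center[1])
                    > t.axes[0] + o.axes[0]
                    for o in tracks
                ):
                    break
            else:
                raise ValueError("could not place a non-overlapping fish")
        tracks.append(t)
        overlap_flags.append(overlap)

    intensities = [
        float(env.fish_level * rng.uniform(0.9, 1.1)) for _ in range(n_fish)
    ]
    rows = np.arange(H, dtype=np.float64)[:, None]
    base = env.background_level + env.band_gain * np.exp(
        -0.5 * ((rows - env.band_center * H) / env.band_width) ** 2
    )
    base = np.broadcast_to(base, (H, W))

    mid = (n_frames - 1) / 2.0
    frames = np.empty((H, W, n_frames))
    masks: list[np.ndarray] = []
    for f in range(n_frames):
        canvas = base.copy()
        for t, level in zip(tracks, intensities):
            cy = t.center[0] + (f - mid) * t.displacement[0]
            cx = t.center[1] + (f - mid) * t.displacement[1]
            m = _draw_ellipse((H, W), (cy, cx), t.axes, t.orientation)
            canvas = np.where(m, np.maximum(canvas, level), canvas)
            if f == n_frames // 2:
                masks.append(m)
        speckle = rng.rayleigh(scale=1.0 / np.sqrt(np.pi / 2.0), size=(H, W))
        canvas = canvas * (1.0 - env.speckle + env.speckle * speckle)
        canvas = ndimage.gaussian_filter(canvas, sigma=env.blur_sigma)
        frames[:, :, f] = np.clip(canvas, 0.0, 1.0)

    ambiguous = [
        any(
            j != i and np.logical_and(masks[i], masks[j]).any()
            for j in range(n_fish)
        )
        for i in range(n_fish)
    ]
    scene = SyntheticScene(
        frames=frames, env=env, tracks=tracks, masks=masks,
        intensities=intensities, overlap_flags=overlap_flags,
        ambiguous=ambiguous, seed=seed,
    )
    if annotate:
        scene.annotation = render_annotation(
            scene, seed=seed + 1, directional=directional
        )
    return scene


def default_ambiguity_rule(scene: SyntheticScene, i: int, min_contrast: float = 0.05):
    """A fish is annotatable when it overlaps nothing and its echo rises
    clearly above the background."""
    return (not scene.ambiguous[i]) and (
        scene.intensities[i] - scene.env.background_level > min_contrast
    )


def render_annotation(
    scene: SyntheticScene,
    ambiguity_rule=default_ambiguity_rule,
    seed: int = 0,
    directional: bool = False,
    n_bg_patches: int = 4,
    patch_size: int = 12,
) -> AnnotationImage:
    """Partial annotation: eroded cores of unambiguous fish, a background
    ring around each annotated fish, a few fish-free background patches,
    everything else unlabeled (code 0)."""
    H, W = scene.frames.shape[:2]
    rng = np.random.default_rng(seed)
    labels = np.zeros((H, W), dtype=np.int64)
    union = np.zeros((H, W), dtype=bool)
    for m in scene.masks:
        union |= m
    union_guard = morphology.dilation(union, morphology.disk(1))

    annotated = [
        ambiguity_rule(scene, i) for i in range(len(scene.masks))
    ]
    # background ring around each annotated fish, clear of every true mask
    for i, (m, ok) in enumerate(zip(scene.masks, annotated)):
        if not ok:
            continue
        ring = morphology.dilation(m, morphology.disk(4)) & ~union_guard
        labels[ring] = 1
    # a few sure-background patches away from any fish
    far = ~morphology.dilation(union, morphology.disk(6))
    for _ in range(n_bg_patches):
        y0 = int(rng.integers(0, max(1, H - patch_size)))
        x0 = int(rng.integers(0, max(1, W - patch_size)))
        patch = np.zeros((H, W), dtype=bool)
        patch[y0 : y0 + patch_size, x0 : x0 + patch_size] = True
        labels[patch & far] = 1
    # fish cores last so no background label can overwrite them
    for i, (m, ok) in enumerate(zip(scene.masks, annotated)):
        if not ok:
            continue
        core = morphology.erosion(m, morphology.disk(1))
        if not core.any():
            core = m
        code = 2 + DIRECTIONS.index(scene.tracks[i].direction) if directional else 2
        labels[core] = code
    return AnnotationImage(labels=labels)


# ----------------------------------------------------------------------
# On-disk dataset format: PNG frames + indexed-PNG annotation + JSON GT

def write_dataset(directory, scenes: list[SyntheticScene]) -> Path:
    """Write frame triplets, annotations and ground truth with a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, scene in enumerate(scenes):
        frame_files = []
        for f in range(scene.frames.shape[2]):
            name = f"scene{i:03d}_frame{f}.png"
            iio.imwrite(
                directory / name,
                np.round(scene.frames[:, :, f] * 255).astype(np.uint8),
            )
            frame_files.append(name)
        ann_name = f"scene{i:03d}_annotation.png"
        ann = scene.annotation or AnnotationImage(
            np.zeros(scene.frames.shape[:2], dtype=np.int64)
        )
        iio.imwrite(directory / ann_name, ann.labels.astype(np.uint8))
        gt_name = f"scene{i:03d}_gt.json"
        records = [
            {
                "segmentation": rle_encode(m),
                "bbox": list(tight_bbox(m)),
                "direction": t.direction,
                "ambiguous": bool(amb),
                "overlap": bool(ov),
            }
            for m, t, amb, ov in zip(
                scene.masks, scene.tracks, scene.ambiguous, scene.overlap_flags
            )
        ]
        (directory / gt_name).write_text(json.dumps(records))
        entries.append(
            {
                "frames": frame_files,
                "annotation": ann_name,
                "ground_truth": gt_name,
                "environment": scene.env.name,
                "seed": scene.seed,
            }
        )
    manifest = {"num_scenes": len(scenes), "scenes": entries}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return directory / "manifest.json"


@dataclass
class LoadedScene:
    """A dataset entry read back from disk."""

    stack: FrameStack
    raw_middle: np.ndarray
    annotation: AnnotationImage
    gt_masks: list[InstanceMask]
    gt_directions: list[str]
    environment: str


def load_dataset(directory) -> list[LoadedScene]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    out = []
    for entry in manifest["scenes"]:
        raws = [iio.imread(directory / f) for f in entry["frames"]]
        stack = FrameStack.from_frames(raws)
        raw_middle = np.asarray(raws[len(raws) // 2], dtype=np.float64) / 255.0
        ann = AnnotationImage(iio.imread(directory / entry["annotation"]))
        records = json.loads((directory / entry["ground_truth"]).read_text())
        gt_masks = [
            InstanceMask(
                mask=rle_decode(r["segmentation"]), score=1.0,
                bbox=tuple(r["bbox"]),
            )
            for r in records
            if not r["ambiguous"]
        ]
        gt_dirs = [r["direction"] for r in records if not r["ambiguous"]]
        out.append(
            LoadedScene(
                stack=stack, raw_middle=raw_middle, annotation=ann,
                gt_masks=gt_masks, gt_directions=gt_dirs,
                environment=entry["environment"],
            )
        )
    return out
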