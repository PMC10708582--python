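"""Synthetic labeled cuboids with class-specific motion statistics.

Renders a textured ellipsoidal "mouse" on a cage-like background (static
high-contrast structure so dense optical flow is well posed) and animates it
with one of eight behavior-specific kinematic programs: drinking and eating
happen as small motions at fixed cage landmarks (spout / hopper), grooming is
a localized periodic deformation, hanging and rearing are vertical, walking
is a linear translation, micromovement is sub-pixel jitter and resting is a
static pose. The default geometry is the package's CPU-scale study condition
(T=8 frames of 16x16 RGB); nothing in the generator depends on that choice.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import flow_cuboid
from .video_io import Cuboid, DatasetSplit

__all__ = ["SyntheticSpec", "DEFAULT_CLASSES", "generate_clip",
           "generate_dataset", "motion_energy"]

DEFAULT_CLASSES = ("drink", "eat", "groom", "hang", "micromovement",
                   "rear", "rest", "walk")


@dataclass
class SyntheticSpec:
    classes: tuple = DEFAULT_CLASSES
    clips_per_class: int = 10
    T: int = 8
    H: int = 16
    W: int = 16
    C: int = 3
    walk_speed: float = 1.5        # px/frame
    jitter_sd: float = 0.5         # px, micromovement
    osc_amplitude: float = 0.8     # px, landmark behaviors
    osc_frequency: float = 1.0     # cycles per clip
    noise_sd: float = 0.01         # additive pixel noise (0-1 scale)
    imbalance: dict = field(default_factory=dict)  # class -> count divisor
    flow_radius: int = 3
    seed: int = 0

    def class_index(self, name):
        return self.classes.index(name)


def _background(spec, rng):
    """Static cage backdrop: gradient + bars + bedding speckle."""
    h, w = spec.H, spec.W
    yy, xx = np.mgrid[0:h, 0:w]
    bg = 0.25 + 0.15 * yy / max(h - 1, 1)
    bg = bg + 0.12 * np.sin(2 * np.pi * xx / max(w / 3.0, 1))  # cage bars
    bg = bg + rng.normal(0, 0.03, (h, w))                      # bedding texture
    frame = np.stack([bg * 0.95, bg, bg * 0.85], axis=-1)
    return np.clip(frame, 0, 1)


def _render_mouse(frame, cy, cx, ry, rx, brightness=0.75, patch=None):
    h, w = frame.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    d = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
    body = np.clip(1.0 - d, 0.0, 1.0) ** 0.5
    texture = 0.08 * np.sin(3.0 * (yy - cy)) * np.sin(3.0 * (xx - cx))
    color = np.stack([0.9, 0.8, 0.7])
    out = frame.copy()
    mask = body[..., None]
    out = out * (1 - mask) + mask * (brightness + texture)[..., None] * color
    if patch is not None:
        pcy, pcx, pr, pval = patch
        pd = ((yy - pcy) ** 2 + (xx - pcx) ** 2) / pr ** 2
        pm = np.clip(1.0 - pd, 0.0, 1.0)[..., None]
        out = out * (1 - pm) + pm * pval
    return np.clip(out, 0, 1)


def _pose(cls, t, spec, rng, phase):
    """Center/axes/patch of the mouse at frame t for a behavior class."""
    h, w = spec.H, spec.W
    ry, rx = h * 0.16, w * 0.22
    cy, cx = h * 0.62, w * 0.5
    osc = spec.osc_amplitude * np.sin(
        2 * np.pi * (spec.osc_frequency * t / spec.T + phase))
    patch = None
    if cls == "rest":
        # curled up in the bedding corner, immobile
        cy, cx = h * 0.78, w * 0.22
        rx *= 0.8
    elif cls == "micromovement":
        cy += rng.normal(0, spec.jitter_sd)
        cx += rng.normal(0, spec.jitter_sd)
    elif cls == "walk":
        cx = w * 0.2 + spec.walk_speed * t
    elif cls == "groom":
        cx = w * 0.68
        ry *= 1.0 + 0.15 * np.sin(2 * np.pi * (t / spec.T + phase))
        patch = (cy - ry * 0.6, cx - rx * 0.4,
                 2.0 + 1.0 * np.sin(2 * np.pi * (t / spec.T + phase)), 1.0)
    elif cls == "rear":
        stretch = 1.0 + 1.2 * t / max(spec.T - 1, 1)
        ry *= stretch
        cy = h * 0.62 - (stretch - 1.0) * h * 0.25
        rx *= 0.8
    elif cls == "hang":
        cy = h * 0.18 + 0.5 * osc
        ry *= 0.85
    elif cls == "eat":
        cy, cx = h * 0.45, w * 0.85 + osc
    elif cls == "drink":
        cy, cx = h * 0.3 + osc, w * 0.12
    else:
        raise ValueError(f"unknown behavior class {cls!r}")
    return cy, cx, ry, rx, patch


def generate_clip(class_name, spec: SyntheticSpec, seed: int) -> Cuboid:
    """One labeled cuboid (with matching flow block) for a behavior class."""
    if class_name not in spec.classes:
        raise ValueError(f"unknown class {class_name!r}")
    rng = np.random.default_rng(seed)
    bg = _background(spec, rng)
    phase = rng.random()
    frames = []
    for t in range(spec.T):
        cy, cx, ry, rx, patch = _pose(class_name, t, spec, rng, phase)
        f = _render_mouse(bg, cy, cx, ry, rx, patch=patch)
        f = np.clip(f + rng.normal(0, spec.noise_sd, f.shape), 0, 1)
        frames.append(f)
    data = np.stack(frames).astype(np.float32)
    if spec.C == 1:
        data = data.mean(axis=-1, keepdims=True)
    flow = flow_cuboid((data * 255).astype(np.uint8), radius=spec.flow_radius)
    return Cuboid(data, spec.class_index(class_name),
                  origin=(f"synthetic/{class_name}", seed), flow=flow)


def generate_dataset(spec: SyntheticSpec) -> DatasetSplit:
    """Stratified 70/15/15 split with exact per-class bookkeeping."""
    if spec.clips_per_class < 1:
        raise ValueError("clips_per_class must be >= 1")
    split = DatasetSplit(num_classes=len(spec.classes))
    for ci, cls in enumerate(spec.classes):
        count = max(1, int(round(spec.clips_per_class
                                 / spec.imbalance.get(cls, 1))))
        clips = [generate_clip(cls, spec,
                               spec.seed * 100003 + ci * 1009 + j)
                 for j in range(count)]
        n_train = max(1, int(np.floor(0.7 * count)))
        n_val = int(np.floor(0.15 * count))
        split.train.extend(clips[:n_train])
        split.validation.extend(clips[n_train:n_train + n_val])
        split.test.extend(clips[n_train + n_val:])
    return split


def motion_energy(cuboid: Cuboid) -> float:
    """Mean inter-frame absolute intensity change (a flow-free statistic)."""
    d = np.abs(np.diff(cuboid.data, axis=0))
    return float(d.mean())
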