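"""Appearance normalization and optical-flow stream generation.

Most home-cage recordings are daytime video while a minority are infrared
night recordings; *nightification* removes this appearance imbalance by
weighting the [0-1]-normalized day pixels with the mean night-video R, G and
B values and expanding back to [0-255]. The second network stream carries
dense optical flow between consecutive (downsampled) frames, rendered by
default as a 3-channel angle/magnitude color wheel so both streams share one
input geometry.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.colors import hsv_to_rgb
from skimage.registration import optical_flow_ilk

from .video_io import FrameSequence

__all__ = [
    "NightReference", "FlowField", "compute_night_reference", "nightify_frame",
    "nightify_sequence", "to_grayscale", "compute_flow_stream",
    "encode_flow_frames", "flow_cuboid",
]

#: ITU-R 601 luminance weights.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class NightReference:
    """Per-channel mean pixel values (0-255 scale) of the night videos."""

    mean_rgb: tuple

    def __post_init__(self):
        self.mean_rgb = tuple(float(v) for v in self.mean_rgb)
        if len(self.mean_rgb) != 3:
            raise ValueError("mean_rgb must have three components")
        if not all(0.0 <= v <= 255.0 for v in self.mean_rgb):
            raise ValueError("mean_rgb components must lie in [0, 255]")


@dataclass
class FlowField:
    """Per-pixel displacement between a consecutive frame pair."""

    dx: np.ndarray
    dy: np.ndarray

    @property
    def magnitude(self):
        return np.hypot(self.dx, self.dy)

    @property
    def angle(self):
        return np.arctan2(self.dy, self.dx)


def compute_night_reference(night_videos) -> NightReference:
    """Arithmetic per-channel mean over every pixel of every night frame."""
    videos = list(night_videos)
    if not videos:
        raise ValueError("at least one night video is required")
    total = np.zeros(3, dtype=np.float64)
    count = 0
    for seq in videos:
        frames = seq.frames if isinstance(seq, FrameSequence) else np.asarray(seq)
        if frames.shape[-1] != 3:
            raise ValueError("night videos must be RGB")
        total += frames.reshape(-1, 3).sum(axis=0)
        count += frames.reshape(-1, 3).shape[0]
    return NightReference(tuple(total / count))


def nightify_frame(frame: np.ndarray, ref: NightReference) -> np.ndarray:
    """out_c = round(in_c * ref_c / 255) per channel."""
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[-1] != 3:
        raise ValueError("nightification requires an H x W x 3 frame "
                         "(convert to grayscale only afterwards)")
    scaled = frame.astype(np.float64) / 255.0 * np.asarray(ref.mean_rgb)
    return np.clip(np.rint(scaled), 0, 255).astype(np.uint8)


def nightify_sequence(seq: FrameSequence, ref: NightReference) -> FrameSequence:
    if seq.is_night:
        return seq
    frames = np.stack([nightify_frame(f, ref) for f in seq.frames])
    return FrameSequence(frames, fps=seq.fps, source_id=seq.source_id,
                         is_night=True)


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """ITU-R 601 luminance; returns H x W x 1."""
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[-1] != 3:
        raise ValueError("grayscale conversion requires an H x W x 3 frame")
    lum = frame.astype(np.float64) @ _LUMA
    if np.issubdtype(frame.dtype, np.integer):
        lum = np.rint(lum).astype(frame.dtype)
    return lum[..., None]


def compute_flow_stream(seq, radius: int = 7) -> list[FlowField]:
    """Dense optical flow between consecutive frames (iterative Lucas-Kanade).

    Returns one FlowField per frame pair: entry ``t`` is the motion of scene
    content from frame ``t`` to frame ``t+1``, in pixels.
    """
    frames = seq.frames if isinstance(seq, FrameSequence) else np.asarray(seq)
    if frames.shape[0] < 2:
        raise ValueError("need at least two frames for optical flow")
    gray = frames.astype(np.float32)
    if gray.ndim == 4 and gray.shape[-1] == 3:
        gray = gray @ _LUMA.astype(np.float32)
    elif gray.ndim == 4:
        gray = gray[..., 0]
    fields = []
    for t in range(frames.shape[0] - 1):
        v = optical_flow_ilk(gray[t], gray[t + 1], radius=radius)
        fields.append(FlowField(dx=v[1], dy=v[0]))
    return fields


def encode_flow_frames(fields, mode: str = "hsv3",
                       max_magnitude: float = 8.0) -> np.ndarray:
    """Render flow fields for the model's flow stream.

    ``hsv3``: hue = flow angle, value = magnitude (saturating at
    ``max_magnitude``), converted to RGB in [0, 1] — the flow stream then has
    the same channel count as the RGB stream. ``raw2``: stacked (dx, dy).
    """
    if mode == "raw2":
        return np.stack([np.stack([f.dx, f.dy], axis=-1) for f in fields])
    if mode != "hsv3":
        raise ValueError(f"unknown flow encoding {mode!r}")
    out = []
    for f in fields:
        hue = (f.angle + np.pi) / (2 * np.pi)
        val = np.clip(f.magnitude / max_magnitude, 0.0, 1.0)
        hsv = np.stack([hue, np.ones_like(hue), val], axis=-1)
        out.append(hsv_to_rgb(hsv))
    return np.stack(out).astype(np.float32)


def flow_cuboid(rgb_frames: np.ndarray, mode: str = "hsv3",
                radius: int = 7) -> np.ndarray:
    """Flow-stream cuboid aligned with a T-frame RGB cuboid.

    Flow is computed for pairs (t, t+1); the final step is repeated so the
    flow block keeps the same temporal length T as the RGB block.
    """
    fields = compute_flow_stream(np.asarray(rgb_frames), radius=radius)
    enc = encode_flow_frames(fields, mode=mode)
    return np.concatenate([enc, enc[-1:]], axis=0)
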