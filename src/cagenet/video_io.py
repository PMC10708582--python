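"""Decoding, spatial/temporal resampling and cuboid assembly.

The preprocessing geometry follows the home-cage recording pipeline: frames
are resized to a square, the redundant vertical margins are cropped away
symmetrically (giving 96x128 at default settings), the sequence is temporally
downsampled at five-frame intervals, and consecutive non-overlapping windows
of ``T`` frames become labeled spatiotemporal cuboids.
"""
from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass, field

import h5py
import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "FrameSequence", "Cuboid", "DatasetSplit", "resize_and_crop",
    "temporal_downsample", "extract_cuboids", "assign_label",
    "write_cuboid_store", "read_cuboid_store", "load_frame_labels",
]


@dataclass
class FrameSequence:
    """An ordered stack of equally-shaped uint8 frames."""

    frames: np.ndarray            # (N, H, W, C) uint8
    fps: float = 30.0
    source_id: str = ""
    is_night: bool = False

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim == 3:
            self.frames = self.frames[..., None]
        if self.frames.ndim != 4:
            raise ValueError("frames must be (N, H, W, C)")
        if self.frames.shape[-1] not in (1, 3):
            raise ValueError("channel count must be 1 or 3")

    def __len__(self):
        return self.frames.shape[0]


@dataclass
class Cuboid:
    """A T x H x W x C block normalized to [0, 1], with a class label."""

    data: np.ndarray
    label: int
    origin: tuple = ("", 0)        # (source_id, start frame index)
    flow: np.ndarray | None = None  # matching flow-stream block, if computed

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4:
            raise ValueError("cuboid data must be (T, H, W, C)")


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test cuboid collections."""

    train: list = field(default_factory=list)
    validation: list = field(default_factory=list)
    test: list = field(default_factory=list)
    num_classes: int = 8

    def class_counts(self, part="train"):
        cubs = getattr(self, part)
        counts = np.zeros(self.num_classes, dtype=int)
        for c in cubs:
            counts[c.label] += 1
        return counts


def resize_and_crop(frame: np.ndarray, target_hw=(96, 128)) -> np.ndarray:
    """Bilinear-resize to a (W x W) square, then center-crop rows to H.

    With the default (96, 128) target this is the 128x128 resize followed by
    removal of 16 rows from the top and 16 from the bottom. Dtype preserved.
    """
    frame = np.asarray(frame)
    if frame.size == 0:
        raise ValueError("empty frame")
    h, w = target_hw
    if h > w:
        raise ValueError("target height must not exceed target width")
    squeeze = frame.ndim == 2
    if squeeze:
        frame = frame[..., None]
    out = _sk_resize(frame, (w, w), order=1, anti_aliasing=False,
                     preserve_range=True)
    margin = (w - h) // 2
    out = out[margin:margin + h]
    if np.issubdtype(frame.dtype, np.integer):
        out = np.rint(out).astype(frame.dtype)
    else:
        out = out.astype(frame.dtype)
    return out[..., 0] if squeeze else out


def temporal_downsample(seq: FrameSequence, interval: int = 5) -> FrameSequence:
    """Keep frames at indices 0, interval, 2*interval, ..."""
    if interval < 1:
        raise ValueError("interval must be >= 1")
    return FrameSequence(seq.frames[::interval], fps=seq.fps / interval,
                         source_id=seq.source_id, is_night=seq.is_night)


def assign_label(window_labels) -> int:
    """Majority vote; ties broken by the temporally central frame's label."""
    labels = list(window_labels)
    if not labels:
        raise ValueError("empty label window")
    counts = Counter(labels)
    top = max(counts.values())
    winners = {lab for lab, c in counts.items() if c == top}
    if len(winners) == 1:
        return winners.pop()
    return labels[len(labels) // 2]


def extract_cuboids(seq: FrameSequence, labels, T: int = 8,
                    normalize: bool = True) -> list[Cuboid]:
    """Cut consecutive non-overlapping T-frame windows into cuboids.

    ``labels`` holds one class id per frame of ``seq``. The trailing
    remainder shorter than T is discarded.
    """
    labels = np.asarray(labels)
    if len(labels) != len(seq):
        raise ValueError(f"got {len(labels)} labels for {len(seq)} frames")
    if T < 1:
        raise ValueError("T must be >= 1")
    out = []
    n = len(seq) // T
    for i in range(n):
        window = seq.frames[i * T:(i + 1) * T]
        data = window.astype(np.float32)
        if normalize and np.issubdtype(seq.frames.dtype, np.integer):
            data = data / 255.0
        out.append(Cuboid(data, int(assign_label(labels[i * T:(i + 1) * T])),
                          origin=(seq.source_id, i * T)))
    return out


# ---------------------------------------------------------------------------
# Persistence (HDF5 groups: data [, flow], labels, origins per part)
# ---------------------------------------------------------------------------

_PARTS = ("train", "validation", "test")


def write_cuboid_store(split: DatasetSplit, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["num_classes"] = split.num_classes
        for part in _PARTS:
            cubs = getattr(split, part)
            grp = f.create_group(part)
            if cubs:
                grp.create_dataset("data", data=np.stack([c.data for c in cubs]))
                if all(c.flow is not None for c in cubs):
                    grp.create_dataset("flow",
                                       data=np.stack([c.flow for c in cubs]))
            else:
                grp.create_dataset("data", shape=(0,), dtype=np.float32)
            grp.create_dataset("labels",
                               data=np.array([c.label for c in cubs], dtype=np.int64))
            src = [str(c.origin[0]) for c in cubs]
            grp.create_dataset("sources", data=np.array(src, dtype=h5py.string_dtype()))
            grp.create_dataset("starts",
                               data=np.array([int(c.origin[1]) for c in cubs],
                                             dtype=np.int64))


def read_cuboid_store(path) -> DatasetSplit:
    if not os.path.exists(path):
        raise IOError(f"cuboid store not found: {path}")
    try:
        with h5py.File(path, "r") as f:
            split = DatasetSplit(num_classes=int(f.attrs.get("num_classes", 8)))
            for part in _PARTS:
                grp = f[part]
                labels = grp["labels"][()]
                data = grp["data"][()]
                flow = grp["flow"][()] if "flow" in grp else None
                sources = [s.decode() if isinstance(s, bytes) else str(s)
                           for s in grp["sources"][()]]
                starts = grp["starts"][()]
                cubs = []
                for i in range(len(labels)):
                    cubs.append(Cuboid(
                        data[i], int(labels[i]),
                        origin=(sources[i], int(starts[i])),
                        flow=None if flow is None else flow[i]))
                setattr(split, part, cubs)
            return split
    except OSError as e:
        raise IOError(f"corrupt cuboid store {path}: {e}") from e


def load_frame_labels(path) -> np.ndarray:
    """Read per-frame labels from a two-column CSV (frame_index,label)."""
    rows = np.loadtxt(path, delimiter=",", dtype=int, ndmin=2)
    labels = np.zeros(rows[:, 0].max() + 1, dtype=int)
    labels[rows[:, 0]] = rows[:, 1]
    return labels
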