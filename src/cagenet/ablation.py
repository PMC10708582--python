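"""Matched ablation sweeps on the synthetic desk-scale dataset.

Three axes mirror the framework's ablation studies: *variant* (feature
sharing vs standalone streams), *input_kind* (grayscale / raw RGB /
nightified image stream) and *temporal_length* (T = 4, 8, 16 with the SRS
flow crop scaled in proportion). Every configuration in a sweep is trained
under identical seeds so rows are directly comparable.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .architectures import ModelSpec, build_model
from .evaluation import aggregate_seeds, evaluate
from .preprocess import NightReference, nightify_frame
from .synthetic import SyntheticSpec, generate_dataset
from .training import TrainingConfig, train
from .video_io import DatasetSplit

__all__ = ["run_ablation"]

#: mean channel intensities of an infrared night recording (0-255)
_NIGHT_REF = NightReference((96.0, 104.0, 118.0))


def _nightify_split(split: DatasetSplit) -> DatasetSplit:
    out = DatasetSplit(num_classes=split.num_classes)
    for part in ("train", "validation", "test"):
        for c in getattr(split, part):
            frames = np.stack([
                nightify_frame(np.rint(f * 255).astype(np.uint8), _NIGHT_REF)
                for f in c.data])
            c2 = type(c)(frames.astype(np.float32) / 255.0, c.label,
                         origin=c.origin, flow=c.flow)
            getattr(out, part).append(c2)
    return out


def _score(model, cubs):
    xr = np.stack([c.data for c in cubs])
    xf = np.stack([c.flow for c in cubs])
    y = np.array([c.label for c in cubs])
    probs = np.vstack([model.predict_proba(xr[i:i + 16], xf[i:i + 16])
                       for i in range(0, len(y), 16)])
    return evaluate(probs, y)


def _run_one(spec: ModelSpec, split, seeds, epochs):
    reports = []
    for seed in seeds:
        model = build_model(spec)
        cfg = TrainingConfig(epochs=epochs, batch_size=16,
                             learning_rate=spec.learning_rate,
                             plateau_patience=5,
                             early_stop_patience=max(epochs, 12))
        train(model, split, cfg, seed=seed)
        reports.append(_score(model, split.test or split.train))
    return aggregate_seeds(reports)


def run_ablation(axis, name="baseline", seeds=(0,), clips_per_class=10,
                 epochs=12) -> pd.DataFrame:
    rows = []
    if axis == "variant":
        split = generate_dataset(SyntheticSpec(clips_per_class=clips_per_class))
        for variant in ("sharing", "standalone"):
            spec = ModelSpec.desk(name, variant, dropout_rate=0.0)
            mean, std = _run_one(spec, split, seeds, epochs)
            rows.append({"variant": variant, "seeds": len(seeds)}
                        | {k: round(v, 4) for k, v in mean.items()}
                        | {f"{k}_sd": round(v, 4) for k, v in std.items()})
    elif axis == "input_kind":
        base = generate_dataset(SyntheticSpec(clips_per_class=clips_per_class))
        gray = generate_dataset(SyntheticSpec(clips_per_class=clips_per_class,
                                              C=1))
        for kind, split in (("grayscale", gray), ("raw", base),
                            ("nightified", _nightify_split(base))):
            c = split.train[0].data.shape[-1]
            spec = ModelSpec.desk(name, input_shape=(8, 16, 16, c),
                                  dropout_rate=0.0)
            mean, std = _run_one(spec, split, seeds, epochs)
            rows.append({"input_kind": kind, "seeds": len(seeds)}
                        | {k: round(v, 4) for k, v in mean.items()})
    elif axis == "temporal_length":
        for t_len in (4, 8, 16):
            split = generate_dataset(SyntheticSpec(
                clips_per_class=clips_per_class, T=t_len))
            overrides = dict(input_shape=(t_len, 16, 16, 3), dropout_rate=0.0)
            if name == "srs":
                overrides["temporal_crop"] = t_len // 4  # halved/doubled with T
            spec = ModelSpec.desk(name, **overrides)
            mean, std = _run_one(spec, split, seeds, epochs)
            rows.append({"T": t_len, "srs_crop": t_len // 4 if name == "srs" else "-",
                         "seeds": len(seeds)}
                        | {k: round(v, 4) for k, v in mean.items()})
    else:
        raise ValueError(f"unknown ablation axis {axis!r}")
    return pd.DataFrame(rows)
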