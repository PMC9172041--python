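"""Ensemble inference: softmax averaging over fold models and mirrored copies.

The k cross-validation models predict jointly: each patch is presented in the
four mirror variants {none, horizontal, vertical, both} (test-time
augmentation), every model scores every variant, and the class probabilities
are averaged — 20 predictions per pattern for a five-model ensemble.  A frame
is selected as a single hit when the averaged single-hit probability strictly
exceeds the threshold (default 0.5; an exact tie is conservatively
non-single).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import _nn
from .cnn import CrossValResult, ModelConfig, TrainConfig, build_model, _as_nhwc
from .errors import FormatError, InvalidParameterError
from .geomio import NormalizationStats

__all__ = ["Selection", "TrainedEnsemble", "ensemble_predict", "predict_single_model"]

MIRROR_VARIANTS = ((False, False), (True, False), (False, True), (True, True))


@dataclass
class Selection:
    """A named set of pattern identifiers (e.g. the predicted single hits)."""

    name: str
    ids: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.ids = frozenset(self.ids)

    def __len__(self) -> int:
        return len(self.ids)

    def intersection(self, other: "Selection", name: str | None = None) -> "Selection":
        return Selection(name or f"{self.name}&{other.name}", self.ids & other.ids)

    def difference(self, other: "Selection", name: str | None = None) -> "Selection":
        return Selection(name or f"{self.name}-{other.name}", self.ids - other.ids)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"name": self.name, "ids": sorted(self.ids)}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Selection":
        d = json.loads(Path(path).read_text())
        return cls(name=d["name"], ids=frozenset(d["ids"]))


@dataclass
class TrainedEnsemble:
    """Fold models + preprocessing statistics, used jointly at inference."""

    members: list[_nn.Model]
    stats: NormalizationStats
    model_config: ModelConfig
    train_config: TrainConfig | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise InvalidParameterError("ensemble needs at least one member")

    @classmethod
    def from_crossval(cls, cv: CrossValResult) -> "TrainedEnsemble":
        members = []
        for fold in cv.folds:
            m = build_model(cv.model_config)
            m.set_state(fold.model_state)
            members.append(m)
        return cls(members=members, stats=cv.stats,
                   model_config=cv.model_config, train_config=cv.train_config)

    # -- persistence (npz checkpoint + json sidecar of configs) ----------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {}
        for i, m in enumerate(self.members):
            for j, a in enumerate(m.get_state()):
                arrays[f"m{i}_{j}"] = a
        from dataclasses import asdict
        meta = {
            "n_members": len(self.members),
            "stats": {"mu": self.stats.mu, "sigma": self.stats.sigma,
                      "log_scale": self.stats.log_scale},
            "model_config": asdict(self.model_config),
            "train_config": asdict(self.train_config) if self.train_config else None,
        }
        np.savez(path, **arrays)
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1, default=list))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedEnsemble":
        path = Path(path)
        meta_path = path.with_suffix(".json")
        if not meta_path.exists():
            raise FormatError(f"missing ensemble metadata file {meta_path}")
        meta = json.loads(meta_path.read_text())

        def _tup(d, keys):
            for k in keys:
                if k in d and d[k] is not None:
                    d[k] = tuple(tuple(v) if isinstance(v, list) else v for v in d[k]) \
                        if isinstance(d[k], list) and d[k] and isinstance(d[k][0], list) \
                        else tuple(d[k])
            return d

        mc = _tup(dict(meta["model_config"]),
                  ["input_size", "downsample_plan", "final_size"])
        model_config = ModelConfig(**mc)
        tc = None
        if meta.get("train_config"):
            from .cnn import AugmentConfig
            tcd = dict(meta["train_config"])
            aug = tcd.pop("augmentation", None)
            if aug:
                for k in ("scale_range", "gamma_range", "blur_sigma"):
                    aug[k] = tuple(aug[k])
                tcd["augmentation"] = AugmentConfig(**aug)
            tcd["class_loss_weights"] = tuple(tcd["class_loss_weights"])
            tc = TrainConfig(**tcd)
        data = np.load(path if path.suffix else path.with_suffix(".npz"))
        members = []
        for i in range(meta["n_members"]):
            m = build_model(model_config)
            keys = sorted((k for k in data.files if k.startswith(f"m{i}_")),
                          key=lambda s: int(s.split("_")[1]))
            m.set_state([data[k] for k in keys])
            members.append(m)
        return cls(members=members,
                   stats=NormalizationStats(**meta["stats"]),
                   model_config=model_config, train_config=tc)


def _proba_one_model(model: _nn.Model, x: np.ndarray, batch_size: int) -> np.ndarray:
    """(N, 2) class probabilities for pre-shaped NHWC input."""
    out = np.empty((len(x), 2))
    for i in range(0, len(x), batch_size):
        scores = model.forward(x[i : i + batch_size], train=False)
        out[i : i + batch_size] = _nn.softmax(scores)
    return out


def predict_single_model(model: _nn.Model, patches: np.ndarray,
                         batch_size: int = 256) -> np.ndarray:
    """Single-hit probabilities from one model, no test-time augmentation."""
    x = _as_nhwc(np.asarray(patches, dtype=np.float32))
    return _proba_one_model(model, x, batch_size)[:, 1]


def ensemble_predict(
    ensemble: TrainedEnsemble,
    patches: np.ndarray,
    ids: Sequence[str] | None = None,
    tta_mirror: bool = True,
    threshold: float = 0.5,
    selection_name: str = "predicted-single",
    batch_size: int = 256,
) -> tuple[np.ndarray, Selection]:
    """Averaged single-hit probability per patch + the thresholded Selection.

    ``patches`` must already be cropped and standardized with the ensemble's
    stats.  With ``tta_mirror`` the average runs over members x 4 mirror
    variants; the label is single iff probability > threshold (strict).
    """
    x = _as_nhwc(np.asarray(patches, dtype=np.float32))
    expected = tuple(ensemble.model_config.input_size)
    if x.shape[1:3] != expected:
        raise InvalidParameterError(
            f"patch shape {x.shape[1:3]} does not match model input {expected}")
    variants = MIRROR_VARIANTS if tta_mirror else ((False, False),)
    acc = np.zeros((len(x), 2))
    for flip_r, flip_c in variants:
        xv = x
        if flip_r:
            xv = xv[:, ::-1, :, :]
        if flip_c:
            xv = xv[:, :, ::-1, :]
        xv = np.ascontiguousarray(xv)
        for m in ensemble.members:
            acc += _proba_one_model(m, xv, batch_size)
    proba = (acc / (len(variants) * len(ensemble.members)))[:, 1]
    if ids is None:
        ids = [str(i) for i in range(len(x))]
    selected = frozenset(i for i, p in zip(ids, proba) if p > threshold)
    return proba, Selection(name=selection_name, ids=selected)


def predictions_frame(ids: Sequence[str], proba: np.ndarray,
                      threshold: float = 0.5) -> pd.DataFrame:
    """CSV-ready table: id, probability, label."""
    return pd.DataFrame({
        "id": list(ids),
        "probability": np.asarray(proba),
        "label": (np.asarray(proba) > threshold).astype(int),
    })
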