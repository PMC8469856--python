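"""Focal-loss segmentation training, prediction and annotation assistance.

The segmentation model is a compact fully-convolutional pixel classifier:
a fixed multi-scale feature transform (color channels, a redness index at
several Gaussian scales, luminance and its large-scale local context —
injuries are small reddish regions *on* bright bird bodies, while similar
reddish distractors lie on dark litter) feeds a small trainable MLP head
applied at every pixel.  The head is trained by minibatch Adam on the focal
loss

    L(gt, pr) = -gt * a * (1 - pr)^g * log(pr) - (1 - gt) * a * pr^g * log(1 - pr)

with defaults a = 0.25 and g = 2.0, which down-weights the abundant easy
background pixels so the rare injury pixels drive the gradient.  Gradients
are written out analytically; everything runs in NumPy on one CPU core and
is deterministic given the seed.

Training monitors validation loss with early stopping and returns the
parameters of the best epoch.  Prediction produces a per-pixel injury
probability map; connected components (8-connectivity) of the thresholded
map above a minimum area become injury-mask instances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .annotation_store import AnnotationSet, ImageFrame, InjuryMask, Stage, sparsify
from .section_sampler import TrainingSection

_EPS = 1e-7


@dataclass(frozen=True)
class LossParams:
    alpha: float = 0.25
    gamma: float = 2.0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must be in (0, 1]")
        if self.gamma < 0.0:
            raise ValueError("gamma must be >= 0")


def focal_loss(gt: np.ndarray, pr: np.ndarray, params: LossParams = LossParams()) -> float:
    """Mean per-pixel focal loss; probabilities are clipped to [eps, 1-eps]."""
    gt = np.asarray(gt, dtype=np.float64)
    pr = np.asarray(pr, dtype=np.float64)
    if gt.shape != pr.shape:
        raise ValueError(f"shape mismatch: gt {gt.shape} vs pr {pr.shape}")
    p = np.clip(pr, _EPS, 1.0 - _EPS)
    a, g = params.alpha, params.gamma
    loss = -gt * a * (1.0 - p) ** g * np.log(p) - (1.0 - gt) * a * p ** g * np.log(1.0 - p)
    return float(loss.mean())


def _focal_grad_p(gt: np.ndarray, p: np.ndarray, params: LossParams) -> np.ndarray:
    """dL/dp of the per-pixel focal loss (before averaging)."""
    a, g = params.alpha, params.gamma
    pos = a * g * (1.0 - p) ** (g - 1.0) * np.log(p) - a * (1.0 - p) ** g / p
    neg = -a * g * p ** (g - 1.0) * np.log(1.0 - p) + a * p ** g / (1.0 - p)
    return gt * pos + (1.0 - gt) * neg


# ---------------------------------------------------------------------------
# fixed feature transform

N_FEATURES = 9


def image_features(channels: np.ndarray) -> np.ndarray:
    """(H, W, 9) float32 feature stack for an (H, W, 3) uint8 RGB image."""
    x = np.asarray(channels, dtype=np.float32) / 255.0
    r, g, b = x[..., 0], x[..., 1], x[..., 2]
    lum = 0.299 * r + 0.587 * g + 0.114 * b
    red = r - 0.5 * (g + b)
    sm = ndimage.gaussian_filter
    red1 = sm(red, 1.5)
    red2 = sm(red, 4.0)
    ctx = sm(lum, 8.0)  # bright large-scale context = on a bird
    var = np.clip(sm(lum * lum, 3.0) - sm(lum, 3.0) ** 2, 0.0, None)
    tex = np.sqrt(var)
    return np.stack([r, g, b, red, red1, red2, lum, ctx, tex], axis=-1)


# ---------------------------------------------------------------------------
# model

@dataclass
class TrainConfig:
    architecture: str = "multiscale_fcn"
    encoder_preset: str = "default"
    hidden_units: int = 16
    epochs_max: int = 10
    patience: int = 3
    min_delta: float = 0.0
    batch_size: int = 2048
    learning_rate: float = 0.04
    loss: LossParams = field(default_factory=LossParams)
    prediction_threshold: float = 0.5
    min_instance_area: int = 10
    pixels_per_section: int = 1500
    max_pixels: int = 200_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture != "multiscale_fcn":
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if not (0.0 < self.prediction_threshold < 1.0):
            raise ValueError("prediction_threshold must be in (0, 1)")
        if isinstance(self.loss, dict):
            self.loss = LossParams(**self.loss)


@dataclass
class TrainedModel:
    params: Dict[str, np.ndarray]
    config: TrainConfig
    history: List[Dict[str, float]]
    stopped_epoch: int
    best_epoch: int

    def forward(self, feats: np.ndarray) -> np.ndarray:
        """Pixel probabilities for a (..., N_FEATURES) feature array."""
        shape = feats.shape[:-1]
        X = feats.reshape(-1, feats.shape[-1]).astype(np.float64)
        A = np.tanh(X @ self.params["W1"] + self.params["b1"])
        z = A @ self.params["W2"] + self.params["b2"]
        return _sigmoid(z).reshape(shape)

    def save(self, path) -> None:
        blob = {
            "params": {k: v.tolist() for k, v in self.params.items()},
            "config": _config_dict(self.config),
            "history": self.history,
            "stopped_epoch": self.stopped_epoch,
            "best_epoch": self.best_epoch,
        }
        Path(path).write_text(json.dumps(blob))

    @classmethod
    def load(cls, path) -> "TrainedModel":
        blob = json.loads(Path(path).read_text())
        cfg = blob["config"]
        cfg["loss"] = LossParams(**cfg["loss"])
        return cls(
            params={k: np.asarray(v, dtype=np.float64) for k, v in blob["params"].items()},
            config=TrainConfig(**cfg),
            history=blob["history"],
            stopped_epoch=blob["stopped_epoch"],
            best_epoch=blob["best_epoch"],
        )


def _config_dict(cfg: TrainConfig) -> dict:
    d = asdict(cfg)
    return d


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _pixels_from_sections(
    sections: Sequence[TrainingSection], per_section: int, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for s in sections:
        feats = image_features(s.image).reshape(-1, N_FEATURES)
        labels = s.labels.reshape(-1).astype(np.float64)
        n = labels.size
        take = min(per_section, n)
        idx = rng.choice(n, size=take, replace=False)
        # keep every (rare) positive pixel so the injury class is represented
        pos_idx = np.nonzero(labels)[0]
        idx = np.unique(np.concatenate([idx, pos_idx]))
        xs.append(feats[idx])
        ys.append(labels[idx])
    return np.concatenate(xs), np.concatenate(ys)


def train(
    train_sections: Sequence[TrainingSection],
    val_sections: Sequence[TrainingSection],
    config: TrainConfig = TrainConfig(),
) -> TrainedModel:
    """Fit the pixel classifier with Adam on the focal loss.

    Monitors validation loss each epoch; stops when it has not improved by
    ``min_delta`` for ``patience`` consecutive epochs (or at ``epochs_max``)
    and returns the parameters of the best epoch seen.
    """
    if config.epochs_max < 1:
        raise ValueError("epochs_max must be >= 1: nothing would be trained")
    if not train_sections or not val_sections:
        raise ValueError("both train and validation splits must be non-empty")
    rng = np.random.default_rng(config.seed)
    Xtr, ytr = _pixels_from_sections(train_sections, config.pixels_per_section, rng)
    Xva, yva = _pixels_from_sections(val_sections, config.pixels_per_section, rng)
    if Xtr.shape[0] > config.max_pixels:
        keep = rng.choice(Xtr.shape[0], size=config.max_pixels, replace=False)
        Xtr, ytr = Xtr[keep], ytr[keep]

    F, H = Xtr.shape[1], config.hidden_units
    params = {
        "W1": rng.normal(0.0, 1.0 / np.sqrt(F), size=(F, H)),
        "b1": np.zeros(H),
        "W2": rng.normal(0.0, 1.0 / np.sqrt(H), size=H),
        "b2": np.zeros(1),
    }
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(v_) for k, v_ in params.items()}
    b1m, b2m = 0.9, 0.999
    lr = config.learning_rate
    t = 0

    def eval_loss(X: np.ndarray, y: np.ndarray) -> float:
        A = np.tanh(X @ params["W1"] + params["b1"])
        p = _sigmoid(A @ params["W2"] + params["b2"])
        return focal_loss(y, p, config.loss)

    history: List[Dict[str, float]] = []
    best_val = np.inf
    best_params = {k: p.copy() for k, p in params.items()}
    best_epoch = 0
    since_best = 0
    stopped = config.epochs_max

    for epoch in range(1, config.epochs_max + 1):
        order = rng.permutation(Xtr.shape[0])
        for start in range(0, Xtr.shape[0], config.batch_size):
            idx = order[start : start + config.batch_size]
            X, y = Xtr[idx], ytr[idx]
            A = np.tanh(X @ params["W1"] + params["b1"])
            z = A @ params["W2"] + params["b2"]
            p = np.clip(_sigmoid(z), _EPS, 1.0 - _EPS)
            dz = _focal_grad_p(y, p, config.loss) * p * (1.0 - p) / X.shape[0]
            grads = {
                "W2": A.T @ dz,
                "b2": np.array([dz.sum()]),
            }
            dA = np.outer(dz, params["W2"])
            dZ1 = dA * (1.0 - A * A)
            grads["W1"] = X.T @ dZ1
            grads["b1"] = dZ1.sum(axis=0)
            t += 1
            for k in params:
                m[k] = b1m * m[k] + (1 - b1m) * grads[k]
                v[k] = b2m * v[k] + (1 - b2m) * grads[k] ** 2
                mhat = m[k] / (1 - b1m ** t)
                vhat = v[k] / (1 - b2m ** t)
                params[k] -= lr * mhat / (np.sqrt(vhat) + 1e-8)

        tr_loss = eval_loss(Xtr, ytr)
        va_loss = eval_loss(Xva, yva)
        history.append({"epoch": epoch, "train_loss": tr_loss, "val_loss": va_loss})
        if va_loss < best_val - config.min_delta:
            best_val = va_loss
            best_params = {k: p.copy() for k, p in params.items()}
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                stopped = epoch
                break
        stopped = epoch

    return TrainedModel(
        params=best_params,
        config=config,
        history=history,
        stopped_epoch=stopped,
        best_epoch=best_epoch,
    )


# ---------------------------------------------------------------------------
# prediction

def instances_from_probability(
    prob: np.ndarray,
    image_id: str,
    threshold: float = 0.5,
    min_instance_area: int = 10,
    annotator_id: str = "network",
) -> AnnotationSet:
    """Threshold a probability map and extract connected-component instances.

    Components use 8-connectivity; those smaller than ``min_instance_area``
    pixels are discarded.  Each surviving component becomes one InjuryMask
    whose pixels are exactly the thresholded pixels of the component.
    """
    binary = np.asarray(prob) >= threshold
    labeled, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    masks = []
    for k in range(1, n + 1):
        comp = labeled == k
        if int(comp.sum()) < min_instance_area:
            continue
        masks.append(
            InjuryMask(
                mask_id=f"{image_id}/net{len(masks):03d}",
                image_id=image_id,
                pixels=sparsify(comp),
                layer_label=f"net{len(masks):03d}",
            )
        )
    return AnnotationSet(image_id, masks, annotator_id=annotator_id, stage=Stage.network)


def predict(model: TrainedModel, image: ImageFrame) -> Tuple[np.ndarray, AnnotationSet]:
    """Probability map plus extracted network annotation set for one image."""
    prob = model.forward(image_features(image.channels))
    aset = instances_from_probability(
        prob,
        image.image_id,
        threshold=model.config.prediction_threshold,
        min_instance_area=model.config.min_instance_area,
    )
    return prob, aset


def assist(model: TrainedModel, images: Sequence[ImageFrame]) -> List[AnnotationSet]:
    """Batch prediction producing proposal sets (stage ``network``) for review."""
    return [predict(model, img)[1] for img in images]
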