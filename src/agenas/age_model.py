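"""Expected-value age estimation: distribution head, training, metrics.

A network emits logits over K = 76 integer age labels (0..75 years).
Training minimizes cross-entropy against label-smoothed one-hot targets;
at inference the predicted age is the expectation of the softmax
distribution over the labels,

    y = sum_k p_k * l_k ,

so predictions are continuous even though supervision is categorical.
Test-time inference averages the predictions on an image and its
horizontal mirror.  Evaluation reports mean absolute error (MAE),
the cumulative score CS(j) = 100% * #{|error| <= j} / N, and MAE per
age decade.

Ages above the label range (the source population reaches 93 years
while the label space stops at 75) are clamped to the top label with a
logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import nn

__all__ = [
    "NUM_AGE_LABELS",
    "AgeDistribution",
    "AgePrediction",
    "EvalReport",
    "TrainConfig",
    "dex_expected_age",
    "dex_ages_from_logits",
    "label_smoothing_target",
    "label_smoothing_targets",
    "predict_with_mirror",
    "predict_ages",
    "train",
    "evaluate",
    "mae",
    "cumulative_score",
    "per_age_group_mae",
    "load_manifest",
]

logger = logging.getLogger(__name__)

NUM_AGE_LABELS = 76  # integer ages 0..75


@dataclass(frozen=True)
class AgeDistribution:
    """A probability vector over the integer age labels 0..K-1."""

    probs: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.ndim != 1:
            raise ValueError("probs must be a vector")
        if np.any(p < -1e-12):
            raise ValueError("probs must be non-negative")
        if abs(p.sum() - 1.0) > 1e-6:
            raise ValueError(f"probs sum to {p.sum():.8f}, not 1")

    @property
    def labels(self) -> np.ndarray:
        return np.arange(len(self.probs))


@dataclass(frozen=True)
class AgePrediction:
    age_years: float


@dataclass(frozen=True)
class EvalReport:
    mae: float
    cs_curve: dict[int, float]
    per_bin_mae: dict[str, float]
    n: int

    def to_dict(self) -> dict:
        return {"mae": self.mae, "cs_curve": {str(j): v for j, v in self.cs_curve.items()},
                "per_bin_mae": self.per_bin_mae, "n": self.n}


# ---------------------------------------------------------------------------
# the expectation head and targets
# ---------------------------------------------------------------------------

def dex_expected_age(dist: AgeDistribution) -> AgePrediction:
    """Predicted age = expectation of the label distribution."""
    return AgePrediction(float(dist.probs @ dist.labels))


def dex_ages_from_logits(logits: np.ndarray) -> np.ndarray:
    """Batch expectation over softmax(logits); logits shape (N, K)."""
    z = logits - logits.max(axis=1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=1, keepdims=True)
    return p @ np.arange(logits.shape[1])


def clamp_ages(ages: np.ndarray, k: int = NUM_AGE_LABELS) -> np.ndarray:
    ages = np.asarray(ages)
    over = ages > k - 1
    if np.any(over):
        logger.warning("clamping %d age label(s) above %d to %d",
                       int(over.sum()), k - 1, k - 1)
    return np.clip(ages, 0, k - 1)


def label_smoothing_target(age: int, k: int = NUM_AGE_LABELS,
                           eps: float = 0.1) -> AgeDistribution:
    """(1 - eps) at the true label, eps / (K - 1) elsewhere."""
    if not 0 <= age <= k - 1:
        raise ValueError(f"age {age} outside label range 0..{k - 1}")
    probs = np.full(k, eps / (k - 1))
    probs[age] = 1.0 - eps
    return AgeDistribution(probs)


def label_smoothing_targets(ages: np.ndarray, k: int = NUM_AGE_LABELS,
                            eps: float = 0.1) -> np.ndarray:
    """Vectorized label-smoothed targets, shape (N, K). Ages are clamped."""
    ages = clamp_ages(np.asarray(ages, dtype=int), k)
    out = np.full((len(ages), k), eps / (k - 1))
    out[np.arange(len(ages)), ages] = 1.0 - eps
    return out


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def predict_ages(network: nn.Module, images: np.ndarray,
                 batch: int = 32, mirror: bool = False) -> np.ndarray:
    """Expected ages for a stack of images (N, C, H, W)."""
    network.eval()
    preds = []
    for i in range(0, len(images), batch):
        x = images[i:i + batch]
        logits = network(nn.Tensor(x)).data
        if mirror:
            logits = logits + network(nn.Tensor(x[..., ::-1].copy())).data
            logits = logits / 2.0
        preds.append(dex_ages_from_logits(logits))
    return np.concatenate(preds)


def predict_with_mirror(network: nn.Module, image: np.ndarray) -> AgePrediction:
    """Mean of the predicted ages on an image and its horizontal mirror."""
    if image.ndim == 3:
        image = image[None]
    network.eval()
    a = dex_ages_from_logits(network(nn.Tensor(image)).data)[0]
    b = dex_ages_from_logits(network(nn.Tensor(image[..., ::-1].copy())).data)[0]
    return AgePrediction(float((a + b) / 2.0))


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def mae(pred_ages: np.ndarray, true_ages: np.ndarray) -> float:
    pred_ages, true_ages = np.asarray(pred_ages, float), np.asarray(true_ages, float)
    if pred_ages.shape != true_ages.shape:
        raise ValueError("length mismatch between predictions and truths")
    if pred_ages.size == 0:
        raise ValueError("need at least one prediction")
    return float(np.mean(np.abs(pred_ages - true_ages)))


def cumulative_score(pred_ages: np.ndarray, true_ages: np.ndarray,
                     j: float) -> float:
    """Percentage of samples with absolute error no higher than j years."""
    if j < 0:
        raise ValueError("tolerance j must be non-negative")
    err = np.abs(np.asarray(pred_ages, float) - np.asarray(true_ages, float))
    return float(100.0 * np.mean(err <= j))


def per_age_group_mae(pred_ages: np.ndarray, true_ages: np.ndarray,
                      bin_width: int = 10) -> dict[str, float]:
    """MAE within each true-age decade; empty bins are absent."""
    pred_ages = np.asarray(pred_ages, float)
    true_ages = np.asarray(true_ages, float)
    out: dict[str, float] = {}
    if true_ages.size == 0:
        return out
    top = int(true_ages.max() // bin_width)
    for b in range(top + 1):
        m = (true_ages >= b * bin_width) & (true_ages < (b + 1) * bin_width)
        if np.any(m):
            out[f"{b * bin_width}-{(b + 1) * bin_width}"] = mae(
                pred_ages[m], true_ages[m])
    return out


# ---------------------------------------------------------------------------
# data handling
# ---------------------------------------------------------------------------

def load_manifest(manifest: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a manifest CSV (image_path, age) into arrays.

    Images are loaded as grayscale float maps in [0, 1] with a leading
    channel axis; unreadable images are skipped with a logged warning.
    """
    manifest = Path(manifest)
    df = pd.read_csv(manifest)
    if df.empty:
        raise ValueError(f"empty manifest {manifest}")
    root = manifest.parent
    images, ages = [], []
    for row in df.itertuples(index=False):
        path = Path(row.image_path)
        if not path.is_absolute():
            path = root / path
        try:
            with Image.open(path) as im:
                arr = np.asarray(im.convert("L"), dtype=np.float64) / 255.0
        except (OSError, ValueError) as exc:
            logger.warning("skipping unreadable image %s (%s)", path, exc)
            continue
        images.append(arr[None])
        ages.append(int(row.age))
    if not images:
        raise ValueError(f"no readable images in {manifest}")
    return np.stack(images), np.asarray(ages)


def _augment_batch(x: np.ndarray, rng: np.random.Generator,
                   scale_range=(0.9, 1.1), translate_frac=0.05) -> np.ndarray:
    """Random horizontal flip, isotropic scale and translation per image."""
    n, c, h, w = x.shape
    out = np.empty_like(x)
    for i in range(n):
        img = x[i]
        if rng.random() < 0.5:
            img = img[..., ::-1]
        s = rng.uniform(*scale_range)
        hh, ww = max(int(round(h * s)), 1), max(int(round(w * s)), 1)
        resized = np.stack([
            np.asarray(Image.fromarray(ch.astype(np.float32), mode="F")
                       .resize((ww, hh), Image.BILINEAR))
            for ch in img])
        canvas = np.zeros((c, h, w))
        if s >= 1.0:
            top, left = (hh - h) // 2, (ww - w) // 2
            canvas = resized[:, top:top + h, left:left + w]
        else:
            top, left = (h - hh) // 2, (w - ww) // 2
            canvas[:, top:top + hh, left:left + ww] = resized
        dy = int(round(rng.uniform(-translate_frac, translate_frac) * h))
        dx = int(round(rng.uniform(-translate_frac, translate_frac) * w))
        shifted = np.zeros((c, h, w))
        ys, yd = (dy, 0) if dy >= 0 else (0, -dy)
        xs, xd = (dx, 0) if dx >= 0 else (0, -dx)
        shifted[:, ys:h - yd, xs:w - xd] = canvas[:, yd:h - ys, xd:w - xs]
        out[i] = shifted
    return out


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 16
    lr: float = 1e-4
    weight_decay: float = 1e-4
    label_smooth_eps: float = 0.1
    augment: bool = True
    lr_schedule: str = "constant"  # "constant" | "cosine"
    seed: int = 0
    num_classes: int = NUM_AGE_LABELS
    log_every: int = 0  # epochs between INFO log lines; 0 = silent


def train(network: nn.Module, manifest, cfg: TrainConfig
          ) -> tuple[nn.Module, list[dict]]:
    """Train a distribution-head network on a manifest.

    ``manifest`` is either a CSV path (columns image_path, age) or an
    in-memory ``(images, ages)`` pair.  Returns the network and a log of
    per-epoch mean losses.  Fully deterministic for a fixed seed when
    augmentation is off (and seeded when on).
    """
    if isinstance(manifest, (str, Path)):
        images, ages = load_manifest(manifest)
    else:
        images, ages = manifest
        images = np.asarray(images, dtype=np.float64)
        ages = np.asarray(ages)
    if len(ages) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    targets = label_smoothing_targets(ages, cfg.num_classes, cfg.label_smooth_eps)
    opt = nn.Adam(network.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    n = len(ages)
    log: list[dict] = []
    network.train()
    for epoch in range(cfg.epochs):
        if cfg.lr_schedule == "cosine":
            opt.lr = cfg.lr * 0.5 * (1 + np.cos(np.pi * epoch / cfg.epochs))
        order = rng.permutation(n)
        epoch_losses = []
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb = images[idx]
            if cfg.augment:
                xb = _augment_batch(xb, rng)
            logits = network(nn.Tensor(xb))
            loss = nn.cross_entropy(logits, targets[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        entry = {"epoch": epoch, "loss": float(np.mean(epoch_losses))}
        log.append(entry)
        if cfg.log_every and (epoch + 1) % cfg.log_every == 0:
            logger.info("epoch %d: loss %.4f", epoch, entry["loss"])
        network.train()
    return network, log


def evaluate(network: nn.Module, manifest, mirror: bool = True,
             cs_tolerances=(0, 1, 2, 3, 5, 10)) -> EvalReport:
    """MAE / CS / per-decade report with mirror-averaged inference."""
    if isinstance(manifest, (str, Path)):
        images, ages = load_manifest(manifest)
    else:
        images, ages = manifest
        images = np.asarray(images, dtype=np.float64)
        ages = np.asarray(ages)
    preds = predict_ages(network, images, mirror=mirror)
    return EvalReport(
        mae=mae(preds, ages),
        cs_curve={int(j): cumulative_score(preds, ages, j) for j in cs_tolerances},
        per_bin_mae=per_age_group_mae(preds, ages),
        n=len(ages),
    )
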