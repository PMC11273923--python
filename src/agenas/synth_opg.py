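"""Synthetic pseudo-panoramic-radiograph generator.

The clinical dataset behind this line of work (tens of thousands of
orthopantomograms with verified ages) is not publicly available, so the
pipeline is exercised on rendered phantoms in which four well-known
radiographic signs of dental ageing each have one monotone visual proxy:

* eruption   — the number of rendered teeth ramps from 8 to 28 over ages
               0-12, then stays constant;
* abrasion   — crown height shrinks linearly with age;
* secondary dentin deposition — the dark pulp-chamber core shrinks with
               age;
* root transparency — the brightness gradient along the root steepens
               (roots render brighter) with age.

Teeth are drawn as smooth (anti-aliased) capsules in two opposing rows
along a shallow arch on a dark mandible band, plus optional additive
Gaussian noise.  Every image is fully determined by (age, rng state,
config).  These phantoms make the pipeline *learnable by construction*;
they do not emulate trabecular texture, projection geometry or
pathology, so results on them say nothing about clinical accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "SynthConfig",
    "SynthSample",
    "generate_sample",
    "generate_dataset",
    "sample_ages",
    "crown_thickness",
]


@dataclass(frozen=True)
class SynthConfig:
    n: int = 100
    image_size: int = 64
    age_min: int = 0
    age_max: int = 75
    age_sampler: str = "uniform"  # "uniform" | "skewed_median27"
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.age_min > self.age_max:
            raise ValueError("age_min must not exceed age_max")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.age_sampler not in ("uniform", "skewed_median27"):
            raise ValueError(f"unknown age sampler {self.age_sampler!r}")


@dataclass(frozen=True)
class SynthSample:
    image: np.ndarray      # (H, W) float in [0, 1]
    age: int
    provenance: dict       # generator parameters and rendered feature values


def _softbox(u: np.ndarray, center: float, half: float, soft: float) -> np.ndarray:
    """Smooth 1-D box profile in [0, 1] (anti-aliasing ramp of ~soft px)."""
    return np.clip((half - np.abs(u - center)) / soft + 0.5, 0.0, 1.0)


def _age_features(age: float, size: int) -> dict:
    """Noiseless feature values (pixels) at a given age."""
    a = np.clip(age, 0, 75) / 75.0
    return {
        "tooth_count": int(8 + round(20 * min(age, 12) / 12.0)),
        "crown_height": (0.19 - 0.115 * a) * size,   # ~12 -> ~4.8 px at 64
        "pulp_radius": (0.045 - 0.037 * a) * size,   # ~2.9 -> ~0.5 px at 64
        "root_grad": 0.04 + 0.34 * a,                # root brightening slope
    }


def generate_sample(age: int, rng: np.random.Generator,
                    cfg: SynthConfig) -> SynthSample:
    """Render one pseudo-OPG at the given integer age."""
    if not cfg.age_min <= age <= cfg.age_max:
        raise ValueError(f"age {age} outside [{cfg.age_min}, {cfg.age_max}]")
    s = cfg.image_size
    feats = _age_features(age, s)
    jitter = {k: (v * float(rng.uniform(0.95, 1.05)) if k != "tooth_count" else v)
              for k, v in feats.items()}

    yy, xx = np.mgrid[0:s, 0:s].astype(float)
    img = 0.08 + 0.10 * (yy / s)                       # dark tissue backdrop
    # mandible/maxilla band
    img += 0.12 * _softbox(yy, 0.52 * s, 0.30 * s, 0.08 * s)

    n_teeth = jitter["tooth_count"]
    crown_h = jitter["crown_height"]
    pulp_r = max(jitter["pulp_radius"], 0.3)
    grad = jitter["root_grad"]
    root_h = 0.16 * s
    per_row = [n_teeth - n_teeth // 2, n_teeth // 2]
    span_lo, span_hi = 0.10 * s, 0.90 * s
    for row, count in enumerate(per_row):
        if count == 0:
            continue
        sign = 1.0 if row == 0 else -1.0   # upper crowns point down, lower up
        occlusal = 0.50 * s - sign * 0.02 * s
        centers = np.linspace(span_lo, span_hi, count + 2)[1:-1]
        half_w = 0.40 * (span_hi - span_lo) / count
        for cx in centers:
            arch = 0.06 * s * (2.0 * (cx / s) - 1.0) ** 2
            base = occlusal - sign * arch
            wx = _softbox(xx, cx, half_w, 1.0)
            # crown: bright block adjacent to the occlusal line
            ccy = base - sign * crown_h / 2.0
            wy_c = _softbox(yy, ccy, crown_h / 2.0, 1.0)
            img += 0.78 * wx * wy_c
            # root: dimmer block beyond the crown, brightening with age
            rcy = ccy - sign * (crown_h / 2.0 + root_h / 2.0)
            wy_r = _softbox(yy, rcy, root_h / 2.0, 1.0)
            depth = np.clip(sign * (rcy - yy) / root_h + 0.5, 0.0, 1.0)
            img += wx * wy_r * (0.18 + grad * (1.0 - depth))
            # pulp chamber: dark core inside the crown
            rr = np.sqrt((xx - cx) ** 2 + (yy - ccy) ** 2)
            img -= 0.55 * np.clip(1.0 - rr / pulp_r, 0.0, 1.0) * wy_c
    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    provenance = {"age": int(age), "config": asdict(cfg), "features": jitter}
    return SynthSample(image=img, age=int(age), provenance=provenance)


def sample_ages(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw ages per the configured sampler.

    ``skewed_median27`` is a discretized log-normal with median 27 years
    (sigma 0.55), clipped to the configured range — a right-skewed
    distribution like the source population's.
    """
    if cfg.age_sampler == "uniform":
        return rng.integers(cfg.age_min, cfg.age_max + 1, size=cfg.n)
    raw = np.exp(rng.normal(np.log(27.0), 0.55, size=cfg.n))
    return np.clip(np.round(raw).astype(int), cfg.age_min, cfg.age_max)


def generate_dataset(cfg: SynthConfig, out_dir: str | Path) -> Path:
    """Write n PNGs + manifest.csv + provenance.json; return manifest path.

    The dataset is a pure function of the config (including its seed).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    ages = sample_ages(cfg, rng)
    rows, feats = [], []
    for i, age in enumerate(ages):
        sample = generate_sample(int(age), rng, cfg)
        name = f"opg_{i:05d}.png"
        Image.fromarray((sample.image * 255).round().astype(np.uint8),
                        mode="L").save(out_dir / name)
        rows.append({"image_path": name, "age": int(age)})
        feats.append(sample.provenance["features"])
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump({"config": asdict(cfg), "features": feats}, fh, indent=1)
    return manifest


def crown_thickness(image: np.ndarray, threshold: float = 0.88) -> float:
    """Mean vertical extent (rows) of bright crown pixels per occupied column.

    A geometry probe used to verify the abrasion proxy: on noiseless
    renders the measure is strictly larger for young dentitions than old
    ones (during the eruption phase, ages 0-12, tooth narrowing makes the
    probe non-monotone; past it the decline is monotone).
    """
    mask = image > threshold
    cols = mask.any(axis=0)
    if not cols.any():
        return 0.0
    return float(mask[:, cols].sum(axis=0).mean())
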