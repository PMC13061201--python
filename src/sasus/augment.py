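"""The SAS (Segment Anything Small) dual augmentation.

SAS turns a network-ready image/mask pair into a scale- and texture-perturbed
pair in two steps:

1. *Thumbnail scale simulation* — the ultrasound content is resized down to a
   randomly chosen thumbnail (64–256 px at the 256-px default input size,
   i.e. scaling ratios 0.25–1) and placed on an all-zero canvas of the network
   input size.  This mimics the on-screen zoom behaviour of ultrasound
   systems, where pixels outside the rendered viewport are zero-valued.
2. *Mask-restricted noise injection* — exactly one of four noise models
   (speckle, Gaussian, salt & pepper, Poisson), chosen uniformly at random,
   perturbs only the pixels inside the organ mask, simulating varying tissue
   texture while leaving the background bit-identical.

During training the transform is applied, with probability 0.5 by default,
only to images whose structure is *large* — mask area above 3% of the
original image — so that genuinely small structures are never shrunk further.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .io_preprocess import resize_image, resize_mask
from .types import Sample

NOISE_TYPES = ("speckle", "gaussian", "salt_pepper", "poisson")

__all__ = [
    "SASConfig",
    "NOISE_TYPES",
    "classify_size",
    "sample_thumbnail_size",
    "scale_to_thumbnail",
    "inject_noise",
    "sas_transform",
    "augment_policy",
]


@dataclass
class SASConfig:
    """All augmentation knobs.

    Noise magnitudes (``noise_params``) default to gaussian/speckle variance
    0.01, salt & pepper amount 0.05 (salt/pepper split 50/50) and Poisson
    photon scale 255.
    """

    input_size: int = 256
    thumb_min: int = 64
    thumb_max: int = 256
    size_threshold: float = 0.03
    apply_prob: float = 0.5
    noise_types: tuple[str, ...] = NOISE_TYPES
    noise_params: dict[str, float] = field(default_factory=lambda: {
        "gaussian_var": 0.01,
        "speckle_var": 0.01,
        "salt_pepper_amount": 0.05,
        "poisson_scale": 255.0,
    })
    placement: str = "random"
    enable_scale: bool = True
    enable_noise: bool = True

    def __post_init__(self) -> None:
        self.noise_types = tuple(self.noise_types)
        if not (0 < self.thumb_min <= self.thumb_max <= self.input_size):
            raise ValueError(
                f"need 0 < thumb_min <= thumb_max <= input_size, got "
                f"{self.thumb_min}, {self.thumb_max}, {self.input_size}"
            )
        if not 0.0 <= self.apply_prob <= 1.0:
            raise ValueError(f"apply_prob must be in [0,1], got {self.apply_prob}")
        if not 0.0 < self.size_threshold < 1.0:
            raise ValueError(f"size_threshold must be in (0,1), got {self.size_threshold}")
        unknown = set(self.noise_types) - set(NOISE_TYPES)
        if unknown:
            raise ValueError(f"unknown noise types: {sorted(unknown)}")
        if self.enable_noise and not self.noise_types:
            raise ValueError("noise_types must be nonempty when enable_noise")
        if self.placement not in ("random", "centered"):
            raise ValueError(f"placement must be 'random' or 'centered', got {self.placement!r}")

    def to_dict(self) -> dict[str, Any]:
        return {
            "input_size": self.input_size,
            "thumb_min": self.thumb_min,
            "thumb_max": self.thumb_max,
            "size_threshold": self.size_threshold,
            "apply_prob": self.apply_prob,
            "noise_types": list(self.noise_types),
            "noise_params": dict(self.noise_params),
            "placement": self.placement,
            "enable_scale": self.enable_scale,
            "enable_noise": self.enable_noise,
        }


def classify_size(area_ratio: float, threshold: float = 0.03) -> str:
    """Classify a structure as ``small`` (area ratio up to the threshold,
    inclusive) or ``large``.

    Classification always uses the *original* area ratio of the mask, never
    a post-augmentation ratio.
    """
    if not 0.0 <= area_ratio <= 1.0:
        raise ValueError(f"area_ratio must be in [0,1], got {area_ratio}")
    return "small" if area_ratio <= threshold else "large"


def sample_thumbnail_size(cfg: SASConfig, rng: np.random.Generator) -> int:
    """Uniform integer thumbnail size in [thumb_min, thumb_max]."""
    return int(rng.integers(cfg.thumb_min, cfg.thumb_max + 1))


def scale_to_thumbnail(sample: Sample, thumb_size: int, cfg: SASConfig,
                       rng: np.random.Generator) -> Sample:
    """Resize the content to a thumbnail and place it on a zero canvas.

    The image is resized bilinearly and the mask with nearest-neighbour so its
    values stay binary; the thumbnail is placed fully inside an all-zero
    ``input_size`` square, at a uniformly random position (default) or
    centered.  Every canvas pixel outside the thumbnail is exactly 0.
    """
    n = cfg.input_size
    if thumb_size > n:
        raise ValueError(f"thumb_size {thumb_size} exceeds input_size {n}")
    h, w = sample.shape
    s = thumb_size / max(h, w)
    th = max(1, round(h * s))
    tw = max(1, round(w * s))
    img_t = resize_image(sample.image, (th, tw))
    msk_t = resize_mask(sample.mask, (th, tw))
    if cfg.placement == "centered":
        top, left = (n - th) // 2, (n - tw) // 2
    else:
        top = int(rng.integers(0, n - th + 1))
        left = int(rng.integers(0, n - tw + 1))
    img = np.zeros((n, n), dtype=np.float64)
    msk = np.zeros((n, n), dtype=np.uint8)
    img[top:top + th, left:left + tw] = np.clip(img_t, 0.0, 1.0)
    msk[top:top + th, left:left + tw] = msk_t
    out = sample.with_arrays(img, msk)
    out.log("scale_to_thumbnail", thumb_size=thumb_size, top=top, left=left)
    return out


def _speckle(img: np.ndarray, roi: np.ndarray, var: float,
             rng: np.random.Generator) -> np.ndarray:
    noise = rng.normal(0.0, np.sqrt(var), size=int(roi.sum()))
    out = img.copy()
    out[roi] = img[roi] * (1.0 + noise)
    return out


def _gaussian(img: np.ndarray, roi: np.ndarray, var: float,
              rng: np.random.Generator) -> np.ndarray:
    noise = rng.normal(0.0, np.sqrt(var), size=int(roi.sum()))
    out = img.copy()
    out[roi] = img[roi] + noise
    return out


def _salt_pepper(img: np.ndarray, roi: np.ndarray, amount: float,
                 rng: np.random.Generator) -> np.ndarray:
    n = int(roi.sum())
    flip = rng.random(n) < amount
    salt = rng.random(n) < 0.5
    out = img.copy()
    vals = img[roi].copy()
    vals[flip & salt] = 1.0
    vals[flip & ~salt] = 0.0
    out[roi] = vals
    return out


def _poisson(img: np.ndarray, roi: np.ndarray, scale: float,
             rng: np.random.Generator) -> np.ndarray:
    out = img.copy()
    counts = rng.poisson(np.clip(img[roi], 0.0, 1.0) * scale)
    out[roi] = counts / scale
    return out


def inject_noise(sample: Sample, noise_type: str, cfg: SASConfig,
                 rng: np.random.Generator) -> Sample:
    """Perturb only the mask foreground with one noise model.

    Pixels where the mask is 0 are bit-identical to the input; the output is
    clipped to [0, 1]; the mask itself is unchanged.
    """
    p = cfg.noise_params
    roi = sample.mask.astype(bool)
    if noise_type == "speckle":
        img = _speckle(sample.image, roi, p["speckle_var"], rng)
    elif noise_type == "gaussian":
        img = _gaussian(sample.image, roi, p["gaussian_var"], rng)
    elif noise_type == "salt_pepper":
        img = _salt_pepper(sample.image, roi, p["salt_pepper_amount"], rng)
    elif noise_type == "poisson":
        img = _poisson(sample.image, roi, p["poisson_scale"], rng)
    else:
        raise ValueError(f"unknown noise type {noise_type!r}")
    img[roi] = np.clip(img[roi], 0.0, 1.0)
    out = sample.with_arrays(img, sample.mask.copy())
    out.log("inject_noise", noise_type=noise_type)
    return out


def sas_transform(sample: Sample, cfg: SASConfig,
                  rng: np.random.Generator) -> Sample:
    """Apply the two-step SAS transform: thumbnail scaling then noise.

    With ``enable_scale``/``enable_noise`` flags both off the sample is
    returned unchanged (this carries the ablation arms: noise-only,
    scale-only and full SAS).
    """
    out = sample
    if cfg.enable_scale:
        thumb = sample_thumbnail_size(cfg, rng)
        out = scale_to_thumbnail(out, thumb, cfg, rng)
    if cfg.enable_noise:
        noise_type = cfg.noise_types[int(rng.integers(len(cfg.noise_types)))]
        out = inject_noise(out, noise_type, cfg, rng)
    return out


def augment_policy(sample: Sample, cfg: SASConfig,
                   rng: np.random.Generator) -> Sample:
    """Training-time application policy.

    Large-structure samples are SAS-transformed with probability
    ``apply_prob`` (default 50%); small-structure samples pass through
    unchanged.  The decision is recorded in the sample history.
    """
    if sample.size_class is None:
        raise ValueError("sample.size_class must be assigned before augment_policy")
    if sample.size_class != "large":
        out = sample.with_arrays(sample.image, sample.mask)
        out.log("augment_policy", applied=False, reason="small_structure")
        return out
    if rng.random() < cfg.apply_prob:
        out = sas_transform(sample, cfg, rng)
        out.log("augment_policy", applied=True)
        return out
    out = sample.with_arrays(sample.image, sample.mask)
    out.log("augment_policy", applied=False, reason="coin_flip")
    return out
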