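"""Image/mask loading, ultrasound-window extraction and network preprocessing.

The preprocessing pipeline mirrors the standard recipe for 256-px promptable
segmentation encoders: resize so the longest dimension equals the target
size (bilinear for images, nearest for masks so mask values stay binary),
min-max normalize intensities to [0, 1], and zero-pad to a square canvas.
Padding is applied on the bottom/right only, which keeps the coordinate
mapping trivially invertible (see :class:`~sasus.types.PadRecord`).
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
from PIL import Image

from .types import PadRecord, Sample, as_binary_mask

logger = logging.getLogger(__name__)

__all__ = [
    "load_image_mask",
    "extract_us_window",
    "preprocess_pair",
    "resize_image",
    "resize_mask",
    "normalize_minmax",
    "load_dicom_image",
]


def resize_image(image: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Bilinear resize of a float image to ``shape`` (rows, cols)."""
    im = Image.fromarray(np.asarray(image, dtype=np.float32), mode="F")
    out = im.resize((shape[1], shape[0]), resample=Image.BILINEAR)
    return np.asarray(out, dtype=np.float64)

def resize_mask(mask: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resize of a binary mask; output values stay in {0,1}."""
    im = Image.fromarray(np.asarray(mask, dtype=np.uint8), mode="L")
    out = im.resize((shape[1], shape[0]), resample=Image.NEAREST)
    return as_binary_mask(np.asarray(out))


def normalize_minmax(image: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]; a constant image maps to all zeros."""
    image = np.asarray(image, dtype=np.float64)
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        logger.warning("constant-intensity image: min-max normalization maps to zeros")
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def load_image_mask(image_path: str | Path, mask_path: str | Path) -> Sample:
    """Load a grayscale PNG image and its binary mask into a :class:`Sample`.

    The mask is binarized (any nonzero pixel becomes foreground) and
    ``original_area_ratio`` is computed as foreground pixels / total pixels.
    An empty mask is allowed but triggers a warning.
    """
    image_path, mask_path = Path(image_path), Path(mask_path)
    try:
        img = np.asarray(Image.open(image_path).convert("I"), dtype=np.float64)
    except OSError as exc:
        raise OSError(f"cannot read image {image_path}: {exc}") from exc
    try:
        msk_raw = np.asarray(Image.open(mask_path).convert("I"))
    except OSError as exc:
        raise OSError(f"cannot read mask {mask_path}: {exc}") from exc
    mask = as_binary_mask(msk_raw)
    if img.shape != mask.shape:
        raise ValueError(
            f"image {img.shape} and mask {mask.shape} have mismatched shapes "
            f"({image_path.name} / {mask_path.name})"
        )
    ratio = float(mask.sum()) / mask.size
    if ratio == 0.0:
        warnings.warn(f"mask {mask_path.name} is empty", stacklevel=2)
    sample = Sample(image=img, mask=mask, original_area_ratio=ratio,
                    sample_id=image_path.stem)
    sample.log("load", image=str(image_path), mask=str(mask_path))
    return sample


def load_dicom_image(path: str | Path) -> np.ndarray:
    """Read the pixel array of a grayscale DICOM file.

    Only plain pixel-data access is supported; the ultrasound window must be
    supplied explicitly to :func:`extract_us_window` (vendor region-calibration
    tags are not parsed).
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = np.asarray(ds.pixel_array, dtype=np.float64)
    if arr.ndim == 3:  # RGB or multi-frame: collapse to grayscale 2-D
        arr = arr.mean(axis=-1) if arr.shape[-1] in (3, 4) else arr[0]
    return arr


def extract_us_window(sample: Sample, window: tuple[int, int, int, int]) -> Sample:
    """Crop image and mask to the ultrasound window ``(x0, y0, x1, y1)``.

    Coordinates are 0-based and half-open (x = col, y = row).  The area
    ratio is recomputed on the crop.
    """
    x0, y0, x1, y1 = window
    h, w = sample.shape
    if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
        raise ValueError(f"window {window} outside image bounds {(w, h)}")
    img = sample.image[y0:y1, x0:x1].copy()
    msk = sample.mask[y0:y1, x0:x1].copy()
    ratio = float(msk.sum()) / msk.size
    if ratio == 0.0 and sample.original_area_ratio > 0:
        warnings.warn("ultrasound window excludes all foreground", stacklevel=2)
    out = Sample(image=img, mask=msk, original_area_ratio=ratio,
                 size_class=sample.size_class, history=list(sample.history),
                 sample_id=sample.sample_id)
    out.log("extract_us_window", window=list(window))
    return out


def preprocess_pair(sample: Sample, target_size: int = 256) -> tuple[Sample, PadRecord]:
    """Resize-longest + normalize + zero-pad to ``target_size`` square.

    Returns the network-ready sample and a :class:`PadRecord` whose inverse
    maps padded coordinates back to the original grid.
    """
    if target_size <= 0:
        raise ValueError("target_size must be > 0")
    h, w = sample.shape
    if h == 0 or w == 0:
        raise ValueError("degenerate zero-area image")
    scale = target_size / max(h, w)
    new_h = max(1, round(h * scale))
    new_w = max(1, round(w * scale))
    img = normalize_minmax(resize_image(sample.image, (new_h, new_w)))
    msk = resize_mask(sample.mask, (new_h, new_w))
    canvas_img = np.zeros((target_size, target_size), dtype=np.float64)
    canvas_msk = np.zeros((target_size, target_size), dtype=np.uint8)
    canvas_img[:new_h, :new_w] = img
    canvas_msk[:new_h, :new_w] = msk
    out = Sample(image=canvas_img, mask=canvas_msk,
                 original_area_ratio=sample.original_area_ratio,
                 size_class=sample.size_class, history=list(sample.history),
                 sample_id=sample.sample_id)
    out.log("preprocess", target_size=target_size, scale=scale,
            resized=(new_h, new_w))
    return out, PadRecord(top=0, left=0, scale=scale)


def save_sample_png(sample: Sample, image_path: str | Path, mask_path: str | Path) -> None:
    """Write the pair as 8-bit PNGs (mask in the 0/255 on-disk convention)."""
    img = sample.image
    if img.max() <= 1.0:
        img = img * 255.0
    Image.fromarray(np.clip(img, 0, 255).astype(np.uint8), mode="L").save(image_path)
    Image.fromarray((sample.mask * 255).astype(np.uint8), mode="L").save(mask_path)
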