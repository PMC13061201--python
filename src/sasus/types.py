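"""Core in-memory containers shared across the package.

Images are 2-D ``float64`` arrays; after preprocessing intensities lie in
``[0, 1]``.  Masks are 2-D ``uint8`` arrays with values in ``{0, 1}``.
Coordinates follow the numpy ``(row, col)`` convention and are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

SizeClass = str  # "small" | "large"


@dataclass
class Sample:
    """A grayscale image paired with its binary segmentation mask.

    ``original_area_ratio`` is the foreground fraction measured on the
    original (pre-augmentation) image and is never updated by scale or
    noise transforms: size classification always refers to the structure's
    true size in the source image, not its size after thumbnail scaling.
    """

    image: np.ndarray
    mask: np.ndarray
    original_area_ratio: float
    size_class: SizeClass | None = None
    history: list[tuple[str, dict[str, Any]]] = field(default_factory=list)
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.image.ndim != 2 or self.mask.ndim != 2:
            raise ValueError("image and mask must be 2-D arrays")
        if self.image.size == 0:
            raise ValueError("degenerate zero-area image")
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image shape {self.image.shape} != mask shape {self.mask.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape

    def area_ratio(self) -> float:
        """Current foreground fraction (may differ from original_area_ratio
        after a scale transform)."""
        return float(self.mask.sum()) / self.mask.size

    def with_arrays(self, image: np.ndarray, mask: np.ndarray) -> "Sample":
        """Copy of this sample with new pixel data, preserving provenance."""
        return replace(self, image=image, mask=mask, history=list(self.history))

    def log(self, op: str, **params: Any) -> None:
        self.history.append((op, params))


@dataclass(frozen=True)
class PadRecord:
    """Geometry of a resize-then-pad preprocessing step.

    Maps coordinates between the original image grid and the padded
    square grid: ``padded = original * scale + offset``.
    """

    top: int
    left: int
    scale: float

    def __post_init__(self) -> None:
        if self.top < 0 or self.left < 0:
            raise ValueError("offsets must be >= 0")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")

    def to_padded(self, row: float, col: float) -> tuple[float, float]:
        return row * self.scale + self.top, col * self.scale + self.left

    def to_original(self, row: float, col: float) -> tuple[float, float]:
        return (row - self.top) / self.scale, (col - self.left) / self.scale


def as_binary_mask(arr: np.ndarray) -> np.ndarray:
    """Binarize a mask array: any nonzero value maps to 1."""
    return (np.asarray(arr) != 0).astype(np.uint8)
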