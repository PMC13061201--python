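"""Iterative click-prompt simulation for promptable segmentation.

The simulator emulates how a sonographer interacts with a point-promptable
model: the first (positive) click lands deep inside the reference-standard
(RS) mask — among the top 30% of foreground pixels ranked by Euclidean
distance to the mask boundary, i.e. near the structure's core — and each
subsequent click targets the dominant error region of the current
prediction.  A click inside the RS mask (a false-negative region) is labeled
positive; a click outside it (a false-positive region) is labeled negative.

Coordinates are 0-based with ``x`` = column and ``y`` = row.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .types import Sample

Predictor = Callable[[np.ndarray, Sequence["Click"]], np.ndarray]

__all__ = [
    "Click",
    "ErrorMap",
    "boundary_distance",
    "sample_initial_click",
    "compute_error_map",
    "sample_refinement_click",
    "simulate_click_sequence",
    "mask_bounding_box",
]

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class Click:
    x: int  # column
    y: int  # row
    label: str  # "positive" | "negative"
    iteration: int

    def __post_init__(self) -> None:
        if self.label not in ("positive", "negative"):
            raise ValueError(f"label must be positive/negative, got {self.label!r}")
        if self.iteration < 1:
            raise ValueError("iteration must be >= 1")


@dataclass(frozen=True)
class ErrorMap:
    """Symmetric difference between prediction and RS mask.

    ``fn_region`` = RS foreground the prediction missed; ``fp_region`` =
    predicted foreground outside the RS mask.  The two are disjoint and
    their union is ``pixels``.
    """

    pixels: np.ndarray
    fn_region: np.ndarray
    fp_region: np.ndarray

    @property
    def empty(self) -> bool:
        return not bool(self.pixels.any())


def boundary_distance(mask: np.ndarray) -> np.ndarray:
    """Per-pixel Euclidean distance from foreground to the nearest background.

    The image border counts as background, so an all-foreground mask still
    has distances growing from the edges inward.  Background pixels have
    distance 0.
    """
    mask = np.asarray(mask)
    if not mask.any():
        raise ValueError("boundary_distance requires a nonempty mask")
    padded = np.pad(mask.astype(bool), 1, constant_values=False)
    dist = ndimage.distance_transform_edt(padded)
    return dist[1:-1, 1:-1]


def sample_initial_click(mask: np.ndarray, rng: np.random.Generator,
                         top_fraction: float = 0.30) -> Click:
    """First positive click, drawn uniformly from the deepest 30% of pixels.

    Candidate pixels are foreground pixels whose boundary distance is at or
    above the ``(1 - top_fraction)`` quantile of all foreground distances.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("cannot click an empty mask")
    dist = boundary_distance(mask)
    fg_dist = dist[mask]
    cutoff = np.quantile(fg_dist, 1.0 - top_fraction)
    rows, cols = np.nonzero(mask & (dist >= cutoff))
    idx = int(rng.integers(len(rows)))
    return Click(x=int(cols[idx]), y=int(rows[idx]), label="positive", iteration=1)


def compute_error_map(pred: np.ndarray, rs: np.ndarray) -> ErrorMap:
    """Split prediction errors into false-negative and false-positive maps."""
    pred = np.asarray(pred).astype(bool)
    rs = np.asarray(rs).astype(bool)
    if pred.shape != rs.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs rs {rs.shape}")
    fn = rs & ~pred
    fp = pred & ~rs
    return ErrorMap(pixels=(fn | fp).astype(np.uint8),
                    fn_region=fn.astype(np.uint8),
                    fp_region=fp.astype(np.uint8))


def sample_refinement_click(err: ErrorMap, rs: np.ndarray, rng: np.random.Generator,
                            iteration: int) -> Click:
    """Click the interior-most pixel of the largest 8-connected error region.

    The dominant (largest) connected component of the error map is selected;
    within it the pixel with maximal boundary distance is clicked, ties broken
    in row-major order.  The label is positive when the pixel lies inside the
    RS mask (a missed region) and negative otherwise (an over-segmentation).

    Raises ``ValueError`` if the error map is empty — callers should treat an
    empty map as convergence before asking for another click.
    """
    if err.empty:
        raise ValueError("error map is empty: prediction already matches the RS mask")
    labels, n = ndimage.label(err.pixels, structure=_EIGHT)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    biggest = int(np.argmax(sizes)) + 1  # argmax ties -> lowest label id (row-major first)
    comp = labels == biggest
    dist = boundary_distance(comp)
    flat = int(np.argmax(dist))  # row-major tie-break
    row, col = np.unravel_index(flat, dist.shape)
    label = "positive" if err.fn_region[row, col] else "negative"
    return Click(x=int(col), y=int(row), label=label, iteration=iteration)


def simulate_click_sequence(predictor: Predictor, sample: Sample, n_clicks: int,
                            rng: np.random.Generator,
                            ) -> tuple[list[Click], list[np.ndarray]]:
    """Run the iterative prompting protocol against a predictor.

    Issues the initial click, then alternates predict → error map →
    refinement click until ``n_clicks`` clicks have been issued or the
    prediction matches the RS mask (convergence).  Returns all clicks and
    the prediction obtained after each click, so ``preds[k]`` is the
    segmentation produced from ``clicks[: k + 1]``.
    """
    if n_clicks < 1:
        raise ValueError("n_clicks must be >= 1")
    clicks: list[Click] = [sample_initial_click(sample.mask, rng)]
    preds: list[np.ndarray] = []
    while True:
        try:
            pred = np.asarray(predictor(sample.image, clicks)).astype(np.uint8)
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise RuntimeError(
                f"predictor failed at iteration {len(clicks)} "
                f"for sample {sample.sample_id!r}"
            ) from exc
        preds.append(pred)
        if len(clicks) >= n_clicks:
            break
        err = compute_error_map(pred, sample.mask)
        if err.empty:
            break  # converged: no further clicks needed
        clicks.append(sample_refinement_click(err, sample.mask, rng,
                                              iteration=len(clicks) + 1))
    return clicks, preds


def mask_bounding_box(mask: np.ndarray) -> tuple[int, int, int, int]:
    """Tight bounding box (x0, y0, x1, y1), half-open, of a nonempty mask.

    Utility for bounding-box-prompt comparisons; no jitter model.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask has no bounding box")
    rows, cols = np.nonzero(mask)
    return int(cols.min()), int(rows.min()), int(cols.max()) + 1, int(rows.max()) + 1
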