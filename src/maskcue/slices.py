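"""Difference images and slice-wise correlation analysis.

The informativeness of image regions for mask/face categorization is read
off difference images (average mask minus average face).  To compare a
subgroup's *perceptual* difference image against the *veridical* one, both
are cropped to the internal-features rectangle, cut into equal horizontal
slices (canonically 30 slices of 10 x 228 pixels, flattened row-major to
2280-value vectors), and correlated slice by slice with Pearson's r on the
raw signed difference values.  The "notch" is the slice with the minimum
defined correlation — in the emulated study design it sits directly under
the eyes, where masks and faces differ most.
"""

from __future__ import annotations

import logging
from typing import List, Tuple

import numpy as np

from .types import AverageImage, DifferenceImage, SliceCorrelationTable

logger = logging.getLogger(__name__)

DEFAULT_N_SLICES = 30


def diff_image(mask_avg: AverageImage, face_avg: AverageImage) -> DifferenceImage:
    """Signed pixelwise subtraction: mask average minus face average."""
    if mask_avg.texture.shape != face_avg.texture.shape:
        raise ValueError("average images differ in dimensions")
    if not np.allclose(mask_avg.shape.points, face_avg.shape.points, atol=1e-6):
        raise ValueError("average images are not in the same mean shape")
    return DifferenceImage(
        values=mask_avg.texture - face_avg.texture,
        minuend_label=mask_avg.label,
        subtrahend_label=face_avg.label,
    )


def rescale_for_visualization(diff: DifferenceImage) -> np.ndarray:
    """Map |difference| affinely onto 0..255 for display (uint8).

    Lighter pixels mean larger absolute difference.  Figures only — the
    correlation analysis always runs on the raw signed values.  A constant
    difference has no contrast to show; it maps to all zeros with a warning.
    """
    a = np.abs(diff.values)
    lo, hi = float(a.min()), float(a.max())
    if hi == lo:
        logger.warning("rescale_for_visualization: constant difference image; "
                       "output is all zeros")
        return np.zeros(diff.shape, dtype=np.uint8)
    return np.rint((a - lo) / (hi - lo) * 255.0).astype(np.uint8)


def crop_internal(diff: DifferenceImage,
                  rect: Tuple[int, int, int, int]) -> DifferenceImage:
    """Crop the background, keeping the internal-features rectangle.

    ``rect`` is (top, left, height, width); the canonical configuration
    yields a 300 x 228 sub-grid.
    """
    top, left, h, w = rect
    H, W = diff.shape
    if top < 0 or left < 0 or h <= 0 or w <= 0 or top + h > H or left + w > W:
        raise ValueError(f"crop rect {rect} out of bounds for {H}x{W} image")
    return DifferenceImage(
        values=diff.values[top:top + h, left:left + w],
        minuend_label=diff.minuend_label,
        subtrahend_label=diff.subtrahend_label,
    )


def slice_vectors(image: DifferenceImage, n_slices: int) -> List[np.ndarray]:
    """Cut a cropped difference image into equal horizontal slice vectors.

    Slice k (1-based, top-down) covers rows (k-1)*h .. k*h - 1 with
    h = height / n_slices, flattened row-major into one vector of length
    h * width.  A height not divisible by ``n_slices`` is an error — no
    silent padding or truncation.
    """
    vals = image.values
    height, width = vals.shape
    if n_slices <= 0:
        raise ValueError("n_slices must be positive")
    if height % n_slices != 0:
        raise ValueError(
            f"height {height} not divisible by n_slices {n_slices}")
    h = height // n_slices
    return [vals[k * h:(k + 1) * h].ravel(order="C") for k in range(n_slices)]


def slice_correlations(diff_a: DifferenceImage, diff_b: DifferenceImage,
                       n_slices: int = DEFAULT_N_SLICES,
                       comparison: str = "") -> SliceCorrelationTable:
    """Per-slice Pearson correlation between two difference images.

    Both images must already be cropped to the same rectangle.  Slices in
    which either vector has zero variance are flagged undefined (NaN)
    rather than reported as 0.
    """
    if diff_a.shape != diff_b.shape:
        raise ValueError("difference images differ in dimensions")
    va = slice_vectors(diff_a, n_slices)
    vb = slice_vectors(diff_b, n_slices)
    r = np.full(n_slices, np.nan)
    defined = np.zeros(n_slices, dtype=bool)
    for k in range(n_slices):
        a, b = va[k], vb[k]
        if a.std() == 0.0 or b.std() == 0.0:
            continue
        rk = float(np.corrcoef(a, b)[0, 1])
        r[k] = max(-1.0, min(1.0, rk))
        defined[k] = True
    return SliceCorrelationTable(
        slice_index=np.arange(1, n_slices + 1),
        r=r,
        defined=defined,
        n_pixels=int(va[0].size),
        comparison=comparison,
    )


def find_notch(table: SliceCorrelationTable) -> int:
    """1-based index of the slice with the minimum defined correlation.

    Ties are broken toward the smaller (upper) slice index.
    """
    if not table.defined.any():
        raise ValueError("all slices undefined; no notch")
    r = np.where(table.defined, table.r, np.inf)
    return int(table.slice_index[int(np.argmin(r))])
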