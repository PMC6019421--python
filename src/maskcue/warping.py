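"""Landmark alignment and piecewise-affine texture warping.

Shape normalization follows the standard morphometric recipe: generalized
Procrustes analysis (translation, rotation, isotropic scale) yields a mean
landmark shape; each image is then warped onto that shape with a
piecewise-affine map — Delaunay triangulation of the target points, one
affine transform per triangle, bilinear texture sampling.  Eight fixed
frame-border anchor points are appended before triangulation so the warp
is defined over the whole output frame.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial import Delaunay

from .types import LandmarkSet, StimulusImage

GPA_TOLERANCE = 1e-6
_MAX_GPA_ITER = 100


def _centroid_size(pts: np.ndarray) -> float:
    c = pts.mean(axis=0)
    return float(np.sqrt(((pts - c) ** 2).sum()))


def _rotation_to(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Best pure rotation (no reflection) mapping centered a onto centered b."""
    u, _, vt = np.linalg.svd(a.T @ b)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return r


def mean_shape(shapes: Sequence[LandmarkSet],
               tol: float = GPA_TOLERANCE
               ) -> Tuple[LandmarkSet, List[np.ndarray]]:
    """Generalized Procrustes mean of two or more landmark sets.

    Iteratively removes translation, rotation and isotropic scale, updating
    the consensus until its change falls below ``tol``.  The returned mean
    is rescaled to the output frame: its centroid and centroid size are set
    to the averages of the input shapes, so it lives in the same pixel
    coordinates as the inputs.  Also returns the aligned copies (in the
    same frame) in input order.
    """
    if len(shapes) < 2:
        raise ValueError("need at least 2 landmark sets")
    schema = shapes[0].schema
    for s in shapes:
        if s.schema != schema:
            raise ValueError("landmark schema mismatch")
    raw = [s.points.astype(float) for s in shapes]
    sizes = [_centroid_size(p) for p in raw]
    if min(sizes) <= 0:
        raise ValueError("degenerate landmark configuration (zero size)")
    centered = [(p - p.mean(axis=0)) / s for p, s in zip(raw, sizes)]
    for p in centered:
        if np.linalg.matrix_rank(p) < 2:
            raise ValueError("degenerate (collinear) landmark configuration")

    ref = centered[0]
    aligned = centered
    for _ in range(_MAX_GPA_ITER):
        aligned = [p @ _rotation_to(p, ref) for p in centered]
        new_ref = np.mean(aligned, axis=0)
        new_ref = new_ref / _centroid_size(new_ref)
        if np.abs(new_ref - ref).max() < tol:
            ref = new_ref
            break
        ref = new_ref

    out_centroid = np.mean([p.mean(axis=0) for p in raw], axis=0)
    out_size = float(np.mean(sizes))
    mean_pts = ref * out_size + out_centroid
    aligned_frame = [p * out_size + out_centroid for p in aligned]
    return LandmarkSet(points=mean_pts, schema=schema), aligned_frame


def border_anchors(height: int, width: int) -> np.ndarray:
    """Eight fixed frame anchors: corners plus edge midpoints, (x, y)."""
    x1, y1 = width - 1.0, height - 1.0
    return np.array([
        [0.0, 0.0], [x1 / 2, 0.0], [x1, 0.0],
        [0.0, y1 / 2], [x1, y1 / 2],
        [0.0, y1], [x1 / 2, y1], [x1, y1],
    ])


class PiecewiseAffineWarper:
    """Warp images onto a fixed target shape.

    The Delaunay triangulation of the target points (plus border anchors)
    and the per-pixel barycentric coordinates are computed once, so warping
    many source images onto the same target is cheap: for each output pixel
    the source position is the barycentric combination of the matching
    source triangle's vertices, and the source texture is sampled
    bilinearly.  Pixels outside every triangle are set to 0 (with border
    anchors the triangulation covers the full frame, so none arise in
    practice).
    """

    def __init__(self, target: LandmarkSet, frame: Tuple[int, int]):
        self.schema = target.schema
        self.frame = frame
        h, w = frame
        anchors = border_anchors(h, w)
        tgt = np.vstack([target.points, anchors])
        self._n_landmarks = len(target)
        self._anchors = anchors
        try:
            self._tri = Delaunay(tgt)
        except Exception as exc:  # qhull failure on degenerate points
            raise ValueError(f"triangulation failed on degenerate points: {exc}")
        gy, gx = np.mgrid[0:h, 0:w]
        pix = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)
        # tol keeps frame-border pixels, numerically on the hull edge, inside
        simplex = self._tri.find_simplex(pix, tol=1e-8)
        self._inside = simplex >= 0
        s = np.where(self._inside, simplex, 0)
        # Barycentric coordinates of every pixel in its containing triangle.
        trans = self._tri.transform[s]
        b = np.einsum("ijk,ik->ij", trans[:, :2, :], pix - trans[:, 2, :])
        self._bary = np.column_stack([b, 1.0 - b.sum(axis=1)])  # (npix, 3)
        self._vertices = self._tri.simplices[s]  # (npix, 3)

    def warp(self, pixels: np.ndarray, source: LandmarkSet) -> np.ndarray:
        """Map one source image into the target frame (float output)."""
        if source.schema != self.schema:
            raise ValueError("landmark schema mismatch")
        h, w = self.frame
        src = np.vstack([source.points.astype(float), self._anchors])
        src_xy = np.einsum("ij,ijk->ik", self._bary, src[self._vertices])
        # guard against one-ulp overshoot past the source frame edge
        np.clip(src_xy[:, 0], 0.0, np.asarray(pixels).shape[1] - 1.0,
                out=src_xy[:, 0])
        np.clip(src_xy[:, 1], 0.0, np.asarray(pixels).shape[0] - 1.0,
                out=src_xy[:, 1])
        vals = map_coordinates(
            np.asarray(pixels, dtype=float),
            [src_xy[:, 1], src_xy[:, 0]],  # (row, col)
            order=1, mode="constant", cval=0.0,
        )
        vals[~self._inside] = 0.0
        return vals.reshape(h, w)


def warp_to_shape(image: StimulusImage, target: LandmarkSet) -> np.ndarray:
    """Warp a stimulus onto a target landmark shape (one-off convenience)."""
    warper = PiecewiseAffineWarper(target, image.shape)
    return warper.warp(image.pixels, image.landmarks)
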