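"""Rasterization of stylus polylines into binary masks.

Filled masks give the delineated *region* (used for area/volume and
overlap measures); boundary masks give the drawn *stroke* (used for the
contour-saliency score). Both close the polyline by joining the last
vertex back to the first.
"""

from __future__ import annotations

import warnings

import numpy as np
from skimage.draw import line as _bresenham_line

from .datamodel import BinaryMask, Delineation, ObserverRecord

__all__ = [
    "rasterize_filled",
    "rasterize_boundary",
    "observer_slice_mask",
]


def _points_in_polygon(vertices: np.ndarray, width: int, height: int) -> BinaryMask:
    """Even-odd (crossing-number) test of every pixel center against a polygon.

    A pixel (x, y) is inside when a ray from its center crosses the
    closed polygon an odd number of times. Vectorized over the whole
    raster; vertices are (x, y) pixel coordinates.
    """
    xs = np.arange(width, dtype=float)
    ys = np.arange(height, dtype=float)
    px, py = np.meshgrid(xs, ys)  # (height, width)
    inside = np.zeros((height, width), dtype=bool)
    v = np.asarray(vertices, dtype=float)
    n = len(v)
    for i in range(n):
        x1, y1 = v[i]
        x2, y2 = v[(i + 1) % n]
        if y1 == y2:
            continue  # horizontal edges never toggle a horizontal ray
        crosses = (y1 > py) != (y2 > py)
        with np.errstate(invalid="ignore"):
            x_at = (x2 - x1) * (py - y1) / (y2 - y1) + x1
        inside ^= crosses & (px < x_at)
    return inside


def _collapse_retracing(vertices: np.ndarray) -> np.ndarray:
    """Reduce an exactly periodic vertex list to a single cycle.

    A stylus trace that goes around the same closed curve k times is
    the same curve; left as-is, the duplicated edges would cancel under
    the even-odd parity rule and empty the interior.
    """
    v = np.asarray(vertices, dtype=float)
    n = len(v)
    for p in range(3, n // 2 + 1):
        if n % p == 0 and np.array_equal(v, np.tile(v[:p], (n // p, 1))):
            return v[:p]
    return v


def _is_degenerate(vertices: np.ndarray) -> bool:
    """All vertices identical, or exactly collinear (zero enclosed area)."""
    v = np.asarray(vertices, dtype=float)
    if np.allclose(v, v[0]):
        return True
    d = v - v[0]
    # rank of the displacement cloud: 1 => collinear
    return bool(np.linalg.matrix_rank(d, tol=1e-9) < 2)


def rasterize_boundary(delin: Delineation, width: int, height: int) -> BinaryMask:
    """Rasterize the drawn stroke: 8-connected Bresenham segments joining
    consecutive vertices, including the closing segment.
    """
    mask = np.zeros((height, width), dtype=bool)
    v = np.rint(np.asarray(delin.vertices, dtype=float)).astype(int)
    v[:, 0] = np.clip(v[:, 0], 0, width - 1)
    v[:, 1] = np.clip(v[:, 1], 0, height - 1)
    n = len(v)
    for i in range(n):
        x1, y1 = v[i]
        x2, y2 = v[(i + 1) % n]
        if (x2, y2) < (x1, y1):  # canonical direction: pixel set is then
            x1, y1, x2, y2 = x2, y2, x1, y1  # invariant to traversal order
        rr, cc = _bresenham_line(y1, x1, y2, x2)
        mask[rr, cc] = True
    return mask


def rasterize_filled(delin: Delineation, width: int, height: int) -> BinaryMask:
    """Rasterize the delineated region: even-odd interior plus the stroke.

    The polyline is auto-closed; the interior is filled under the
    even-odd rule (robust to self-intersection), testing each pixel by
    its center; the stroke pixels themselves are always included, so
    the boundary mask is a subset of the filled mask. A degenerate
    polyline (all vertices identical or collinear) yields its stroke
    pixels only, with a warning.
    """
    boundary = rasterize_boundary(delin, width, height)
    if _is_degenerate(delin.vertices):
        warnings.warn(
            f"degenerate polyline for observer {delin.observer_id!r} "
            f"(set {delin.set_id!r}, slice {delin.slice_index}): zero-area fill",
            stacklevel=2,
        )
        return boundary
    interior = _points_in_polygon(_collapse_retracing(delin.vertices), width, height)
    return interior | boundary


def observer_slice_mask(
    observer: ObserverRecord,
    set_id: str,
    slice_index: int,
    width: int,
    height: int,
    mode: str = "filled",
) -> BinaryMask:
    """Pixelwise union of all of one observer's delineations on one slice.

    ``mode`` is "filled" or "boundary". Returns an all-false mask when
    the observer drew nothing on that slice.
    """
    if mode not in ("filled", "boundary"):
        raise ValueError(f"mode must be 'filled' or 'boundary', got {mode!r}")
    rasterize = rasterize_filled if mode == "filled" else rasterize_boundary
    mask = np.zeros((height, width), dtype=bool)
    for d in observer.delineations:
        if d.set_id == set_id and d.slice_index == slice_index:
            mask |= rasterize(d, width, height)
    return mask
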