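"""Boundary polygons from binary silhouettes (iso-level tracing at 0.5)."""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter1d
from skimage import measure

from .dots import MaskSequence

#: circular moving-average window applied to traced polygons; marching
#: squares on binary data produces 45-degree staircases that inflate the
#: perimeter of smooth shapes by ~7%, which the smoothing removes
SMOOTH_WINDOW = 5


def polygon_signed_area(poly: np.ndarray) -> float:
    """Shoelace signed area of a closed (x, y) polygon.

    With x right / y down, a positive signed area is the package's
    "counter-clockwise" orientation convention for outer contours.
    """
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_perimeter(poly: np.ndarray) -> float:
    d = np.diff(np.vstack([poly, poly[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def contours_from_mask(mask: np.ndarray, smooth_window: int = SMOOTH_WINDOW) -> list[np.ndarray]:
    """Closed boundary polygons of one binary frame, as (x, y) arrays.

    Uses marching squares at level 0.5 on a zero-padded frame so that
    blobs touching the border are still closed, followed by a circular
    moving average of ``smooth_window`` vertices (0 disables).  Outer
    polygons (material on the inside) are oriented with positive signed
    area; hole polygons negative.  An empty frame yields an empty list.
    """
    mask = np.asarray(mask).astype(float)
    if mask.sum() == 0:
        return []
    padded = np.pad(mask, 1, mode="constant")
    # with 'low' orientation and the x=col / y=row axes, outer boundaries
    # come out with positive shoelace area and holes negative
    raw = measure.find_contours(padded, 0.5, positive_orientation="low")
    out = []
    for c in raw:
        # find_contours returns (row, col); convert to (x, y) and un-pad
        poly = np.column_stack([c[:, 1] - 1.0, c[:, 0] - 1.0])
        if np.allclose(poly[0], poly[-1]):
            poly = poly[:-1]
        if len(poly) < 3:
            continue
        if smooth_window > 1 and len(poly) > 2 * smooth_window:
            poly = uniform_filter1d(poly, smooth_window, axis=0, mode="wrap")
        out.append(poly)
    # largest outer first
    out.sort(key=lambda p: -polygon_signed_area(p))
    return out


def contours_from_masks(m: MaskSequence) -> list[list[np.ndarray]]:
    """Per-frame lists of closed boundary polygons for a mask sequence."""
    return [contours_from_mask(frame) for frame in m.masks]
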