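"""Per-frame silhouette shape statistics (20 features).

The feature families follow the usual silhouette-descriptor repertoire:
boundary curvature moments, moment-based orientation/eccentricity,
spatial-distribution measures, and overall geometry (area, perimeter,
compactness, convexity, solidity, topology).  The exact 20-item list is
fixed here and versioned; it is isolated behind :data:`SHAPE_FEATURE_NAMES`
so an alternate list can be swapped without touching downstream stages.

Conventions: curvature statistics use the largest outer contour only
(multi-component frames: the largest-area component for features 1-8, the
global mask for 9-20).  Empty frames return an all-zero vector carrying a
``valid=False`` flag; downstream z-scoring ignores flagged rows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint
from skimage import measure

from .contours import contours_from_mask, polygon_perimeter, polygon_signed_area
from .dots import MaskSequence
from .materials import TrajectorySet
from .stats import moments

SHAPE_FEATURE_NAMES = (
    "curvature_mean",
    "curvature_sd",
    "curvature_skew",
    "curvature_kurt",
    "orientation",
    "eccentricity",
    "normal_circular_variance",
    "moment_anisotropy",
    "centroid_x",
    "centroid_y",
    "bbox_width",
    "bbox_height",
    "area_fraction",
    "perimeter",
    "compactness",
    "convexity",
    "solidity",
    "n_components",
    "n_holes",
    "bbox_aspect",
)


def resample_contour(poly: np.ndarray, n: int = 200) -> np.ndarray:
    """Resample a closed polygon to ``n`` vertices at uniform arc-length spacing."""
    closed = np.vstack([poly, poly[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate (zero-length) contour")
    targets = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(targets, s, closed[:, 0])
    y = np.interp(targets, s, closed[:, 1])
    return np.column_stack([x, y])


def contour_curvature(poly: np.ndarray, n_resample: int = 200) -> np.ndarray:
    """Signed curvature per vertex of a uniformly resampled closed contour.

    Curvature is the turning angle at each vertex divided by the local arc
    length; the sign is positive for convex turns of a counter-clockwise
    (positive signed area) polygon.  The input is re-oriented CCW first.
    """
    if len(poly) < 4:
        raise ValueError("polygon needs at least 4 vertices")
    if polygon_signed_area(poly) < 0:
        poly = poly[::-1]
    p = resample_contour(poly, n_resample)
    e_prev = p - np.roll(p, 1, axis=0)
    e_next = np.roll(p, -1, axis=0) - p
    cross = e_prev[:, 0] * e_next[:, 1] - e_prev[:, 1] * e_next[:, 0]
    dot = (e_prev * e_next).sum(axis=1)
    turn = np.arctan2(cross, dot)
    ds = 0.5 * (np.hypot(*e_prev.T) + np.hypot(*e_next.T))
    if np.any(ds == 0):
        raise ValueError("degenerate zero-length edge after resampling")
    return turn / ds


def total_turning(poly: np.ndarray, n_resample: int = 200) -> float:
    """Integral of curvature along the closed contour (2*pi for simple CCW)."""
    if polygon_signed_area(poly) < 0:
        poly = poly[::-1]
    p = resample_contour(poly, n_resample)
    e_prev = p - np.roll(p, 1, axis=0)
    e_next = np.roll(p, -1, axis=0) - p
    cross = e_prev[:, 0] * e_next[:, 1] - e_prev[:, 1] * e_next[:, 0]
    dot = (e_prev * e_next).sum(axis=1)
    return float(np.arctan2(cross, dot).sum())


def _boundary_normal_circular_variance(poly: np.ndarray) -> float:
    """Circular variance (1 - mean resultant length) of outward-normal directions."""
    p = resample_contour(poly, 200)
    e = np.roll(p, -1, axis=0) - p
    # rotate tangents by -90 deg to get outward normals of a CCW contour
    normals = np.column_stack([e[:, 1], -e[:, 0]])
    norm = np.hypot(*normals.T)
    ok = norm > 0
    unit = normals[ok] / norm[ok, None]
    r = np.hypot(unit[:, 0].mean(), unit[:, 1].mean())
    return float(1.0 - r)


def _count_holes(mask: np.ndarray) -> int:
    """Components of the complement that do not touch the border."""
    inv = ~mask
    lab, n = measure.label(inv, connectivity=1, return_num=True)
    border = np.unique(
        np.concatenate([lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]])
    )
    border = set(border.tolist()) - {0}
    return int(n - len(border))


def shape_descriptors(mask: np.ndarray, contours: list[np.ndarray] | None = None):
    """20-feature vector for one binary frame, plus a validity flag.

    Returns ``(vector, valid)``; an empty frame gives zeros and ``False``.
    """
    mask = np.asarray(mask).astype(bool)
    h, w = mask.shape
    if mask.sum() == 0:
        return np.zeros(len(SHAPE_FEATURE_NAMES)), False
    if contours is None:
        contours = contours_from_mask(mask)

    lab = measure.label(mask, connectivity=2)
    props = measure.regionprops(lab)
    n_components = len(props)
    largest = max(props, key=lambda p: p.area)

    # 1-4: curvature moments on the largest outer contour
    outer = [c for c in contours if polygon_signed_area(c) > 0]
    if outer:
        main = max(outer, key=polygon_signed_area)
        kappa = contour_curvature(main)
        curv = moments(kappa)
        circ_var = _boundary_normal_circular_variance(main)
    else:  # sub-pixel blob: no traceable contour
        curv = np.zeros(4)
        circ_var = 0.0

    # 5-8: moment-based orientation / eccentricity / anisotropy (largest component)
    orientation = float(largest.orientation)
    if orientation <= -np.pi / 2:
        orientation += np.pi
    eigs = largest.inertia_tensor_eigvals  # major first
    anis = float(eigs[1] / eigs[0]) if eigs[0] > 0 else 1.0  # minor/major in [0,1]

    # 9-13: spatial distribution (global mask)
    rows, cols = np.nonzero(mask)
    centroid_x = cols.mean() / w
    centroid_y = rows.mean() / h
    bbox_w = (cols.max() - cols.min() + 1) / w
    bbox_h = (rows.max() - rows.min() + 1) / h
    area = float(mask.sum())
    area_fraction = area / (h * w)

    # 14-17: overall geometry, measured on the traced sub-pixel boundary so
    # that perimeter, enclosed area and hull are mutually consistent
    perim = sum(polygon_perimeter(c) for c in contours)
    poly_area = sum(polygon_signed_area(c) for c in contours)  # holes subtract
    diag = float(np.hypot(h, w))
    compactness = 4.0 * np.pi * poly_area / perim**2 if perim > 0 else 0.0
    hull_pts = np.vstack(contours) if contours else np.column_stack([cols, rows])
    hull = MultiPoint([tuple(p) for p in hull_pts]).convex_hull
    hull_perim = float(hull.length)
    hull_area = float(getattr(hull, "area", 0.0))
    convexity = hull_perim / perim if perim > 0 else 1.0
    solidity = poly_area / hull_area if hull_area > 0 else 1.0

    n_holes = _count_holes(mask)
    bbox_aspect = bbox_w * w / (bbox_h * h)

    vec = np.array(
        [
            curv[0],
            curv[1],
            curv[2],
            curv[3],
            orientation,
            float(largest.eccentricity),
            circ_var,
            anis,
            centroid_x,
            centroid_y,
            bbox_w,
            bbox_h,
            area_fraction,
            perim / diag,
            compactness,
            convexity,
            solidity,
            float(n_components),
            float(n_holes),
            bbox_aspect,
        ]
    )
    return vec, True


def shape_feature_matrix(m: MaskSequence) -> pd.DataFrame:
    """48 x 20 shape-feature matrix (one row per frame) with a ``valid`` column."""
    rows = np.zeros((m.n_frames, len(SHAPE_FEATURE_NAMES)))
    valid = np.zeros(m.n_frames, dtype=bool)
    for f in range(m.n_frames):
        rows[f], valid[f] = shape_descriptors(m.masks[f])
    out = pd.DataFrame(rows, columns=list(SHAPE_FEATURE_NAMES))
    out["valid"] = valid
    return out


def shape_features_for_videos(
    videos: list[TrajectorySet],
    mask_fn,
) -> pd.DataFrame:
    """Tidy frame-level shape features for many videos.

    ``mask_fn`` maps a :class:`TrajectorySet` to a :class:`MaskSequence`
    (typically :func:`matperc.dots.masks_from_points` with fixed raster
    settings).
    """
    frames = []
    for v in videos:
        tab = shape_feature_matrix(mask_fn(v))
        tab.insert(0, "frame", np.arange(len(tab)))
        tab.insert(0, "video_id", v.video_id)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)
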