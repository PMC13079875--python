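"""Rasterization of point stimuli and the dot-count sampling rule.

Masks use raster convention: row-major arrays indexed ``[frame, row, col]``
with the origin at the top-left, x to the right (columns) and y down (rows).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.morphology import closing, dilation, disk

from .materials import TrajectorySet


@dataclass(frozen=True)
class DotSamplingRule:
    """Dot-count rule: round(P75(area fraction series) * multiplier)."""

    multiplier: float = 2000.0
    percentile: float = 75.0

    def __post_init__(self) -> None:
        if self.multiplier <= 0:
            raise ValueError("multiplier must be positive")
        if not (0.0 < self.percentile <= 100.0):
            raise ValueError("percentile must be in (0, 100]")


@dataclass
class MaskSequence:
    """Binary silhouette stack (frames x height x width) plus pixel scale."""

    masks: np.ndarray
    pixel_size: float = 1.0  # scene units per pixel
    origin: tuple[float, float] = (0.0, 0.0)  # scene coords of pixel (0, 0) centre

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks)
        if self.masks.ndim != 3:
            raise ValueError("masks must have shape (frames, height, width)")
        if not np.isin(self.masks, (0, 1)).all():
            raise ValueError("masks must be binary")
        self.masks = self.masks.astype(bool)

    @property
    def n_frames(self) -> int:
        return self.masks.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.masks.shape[1:]


def trajectory_bounds(t: TrajectorySet, margin: float = 0.0) -> tuple[float, float, float, float]:
    """(xmin, xmax, ymin, ymax) over all frames, padded by ``margin``."""
    xy = t.positions.reshape(-1, 2)
    return (
        float(xy[:, 0].min() - margin),
        float(xy[:, 0].max() + margin),
        float(xy[:, 1].min() - margin),
        float(xy[:, 1].max() + margin),
    )


def masks_from_points(
    t: TrajectorySet,
    *,
    grid_shape: tuple[int, int] = (128, 128),
    bounds: tuple[float, float, float, float] | None = None,
    radius: int = 3,
    closing_radius: int = 2,
) -> MaskSequence:
    """Render per-frame binary silhouettes as unions of discs at point locations.

    Each frame stamps a disc of ``radius`` pixels at every (pixel-rounded)
    point location, then applies a morphological closing with a disc of
    ``closing_radius`` to bridge small gaps between neighbouring points.

    If ``bounds`` is given and any point falls outside the grid after
    scaling, a ValueError lists the offending frames.  Without ``bounds``
    the grid is fitted to the trajectory with enough margin for the discs.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    h, w = grid_shape
    if t.n_points == 0:
        return MaskSequence(np.zeros((t.n_frames, h, w), dtype=bool))

    if bounds is None:
        pad_frac = 0.02
        xmin, xmax, ymin, ymax = trajectory_bounds(t)
        span = max(xmax - xmin, ymax - ymin, 1e-9)
        pixel_size = span / (min(h, w) - 2 * (radius + closing_radius + 2))
        pad = (radius + closing_radius + 2) * pixel_size + pad_frac * span
        xmin, xmax = xmin - pad, xmax + pad
        ymin, ymax = ymin - pad, ymax + pad
    else:
        xmin, xmax, ymin, ymax = bounds
    sx = (w - 1) / max(xmax - xmin, 1e-12)
    sy = (h - 1) / max(ymax - ymin, 1e-12)
    scale = min(sx, sy)  # isotropic pixels

    cols = np.round((t.positions[:, :, 0] - xmin) * scale).astype(int)
    rows = np.round((t.positions[:, :, 1] - ymin) * scale).astype(int)
    bad = ((cols < 0) | (cols >= w) | (rows < 0) | (rows >= h)).any(axis=1)
    if bad.any():
        frames = np.nonzero(bad)[0].tolist()
        raise ValueError(f"points outside grid after scaling in frames {frames}")

    selem = disk(radius)
    close_selem = disk(closing_radius) if closing_radius > 0 else None
    masks = np.zeros((t.n_frames, h, w), dtype=bool)
    for f in range(t.n_frames):
        canvas = np.zeros((h, w), dtype=bool)
        canvas[rows[f], cols[f]] = True
        canvas = dilation(canvas, selem)
        if close_selem is not None:
            canvas = closing(canvas, close_selem)
        masks[f] = canvas.astype(bool)
    return MaskSequence(masks, pixel_size=1.0 / scale, origin=(xmin, ymin))


def area_fraction_series(m: MaskSequence) -> np.ndarray:
    """Per-frame ratio of on-pixels to off-pixels.

    Note this follows the on/off *ratio* (not the on/total fraction); the
    two differ appreciably at large coverage.  A frame that is entirely on
    has a zero denominator and raises.
    """
    on = m.masks.reshape(m.n_frames, -1).sum(axis=1).astype(float)
    total = m.masks.shape[1] * m.masks.shape[2]
    off = total - on
    if (off == 0).any():
        frames = np.nonzero(off == 0)[0].tolist()
        raise ValueError(f"frames entirely on (zero off-pixel denominator): {frames}")
    return on / off


def n_dots(series: np.ndarray, rule: DotSamplingRule = DotSamplingRule()) -> int:
    """Dot count from an area-fraction series.

    Percentile uses linear interpolation between closest order statistics
    (numpy's default, R type 7); the product is rounded half away from zero.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("series must be nonempty")
    if (series < 0).any():
        raise ValueError("series values must be >= 0")
    p = np.percentile(series, rule.percentile)  # linear interpolation
    x = p * rule.multiplier
    return int(np.floor(x + 0.5))


def sample_dots(t: TrajectorySet, n: int, seed: int = 0) -> TrajectorySet:
    """Keep a uniform without-replacement sample of ``n`` point indices.

    The same indices are kept across all frames; deterministic given seed.
    """
    if not (0 <= n <= t.n_points):
        raise ValueError(f"n must be in [0, {t.n_points}], got {n}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(t.n_points, size=n, replace=False)
    return TrajectorySet(
        positions=t.positions[:, idx, :],
        video_id=t.video_id,
        material=t.material,
        exemplar=t.exemplar,
        view=t.view,
        fps=t.fps,
    )
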