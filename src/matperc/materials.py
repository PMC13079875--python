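"""Synthetic point-trajectory animations for five material classes.

Experiments of this kind typically render full physics simulations (soft
bodies, fluids, smoke, cloth, fracturing rigid bodies).  Here each class
is a minimal parametric point-cloud dynamic chosen so that it has a
*distinct and analytically checkable* kinematic signature:

``jelly``
    points in a disc carrying a damped angular standing wave,
    r(theta, t) = r0 * (1 + A * exp(-lam*t) * sin(k*theta) * cos(omega*t)).
``liquid``
    downward advection with a horizontal velocity shear and lateral
    Brownian diffusion.
``smoke``
    isotropic expansion about the centroid, upward drift, Brownian jitter
    (dispersion grows over time; mean divergence is positive).
``fabric``
    a point sheet carrying a transverse travelling wave,
    dy = A * sin(kappa*x - omega*t).
``rigid_breakable``
    a single rigid translation until ``t_break``, then fragments that each
    move as independent rigid bodies (translation + rotation).

Coordinates are scene units, x to the right and y *down* (matching the
raster convention used for masks).  "Down" for falling materials is +y,
"up" for smoke is -y.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

MATERIAL_CLASSES = ("jelly", "liquid", "smoke", "fabric", "rigid_breakable")

#: attribute archetype ordering used throughout the package
ATTRIBUTES = ("dense", "flexible", "wobbly", "fluid", "airy")

DEFAULT_EXEMPLARS_PER_CLASS: Mapping[str, int] = {
    "jelly": 4,
    "liquid": 3,
    "smoke": 3,
    "fabric": 4,
    "rigid_breakable": 4,
}

#: per-exemplar view counts; smoke exemplars get 8 views, the rest 6,
#: so the default design yields 15*6 + 3*8 = 114 videos over 18 exemplars.
DEFAULT_VIEWS_PER_CLASS: Mapping[str, int] = {
    "jelly": 6,
    "liquid": 6,
    "smoke": 8,
    "fabric": 6,
    "rigid_breakable": 6,
}


@dataclass(frozen=True)
class StimulusDesign:
    """Layout of the synthetic stimulus set."""

    exemplars_per_class: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_EXEMPLARS_PER_CLASS)
    )
    views_per_class: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_VIEWS_PER_CLASS)
    )
    n_frames: int = 48
    fps: float = 24.0
    n_points: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.n_points < 1:
            raise ValueError("n_points must be positive")
        for cls, n in self.exemplars_per_class.items():
            if cls not in MATERIAL_CLASSES:
                raise ValueError(f"unknown material class {cls!r}")
            if n < 1:
                raise ValueError(f"exemplar count for {cls!r} must be positive")
        for cls, n in self.views_per_class.items():
            if n < 1:
                raise ValueError(f"view count for {cls!r} must be positive")

    @property
    def n_exemplars(self) -> int:
        return sum(self.exemplars_per_class.values())

    @property
    def n_videos(self) -> int:
        return sum(
            self.exemplars_per_class[c] * self.views_per_class[c]
            for c in self.exemplars_per_class
        )


@dataclass
class TrajectorySet:
    """Per-video 2D point positions over frames (frames x points x 2)."""

    positions: np.ndarray
    video_id: str
    material: str
    exemplar: str
    view: int = 0
    fps: float = 24.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError("positions must have shape (frames, points, 2)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_points(self) -> int:
        return self.positions.shape[1]


DEFAULT_PARAMS: dict[str, dict[str, float]] = {
    "jelly": {"radius": 1.0, "amplitude": 0.15, "decay": 0.5, "k": 3.0,
              "omega": 2.0 * np.pi * 1.5},
    "liquid": {"radius": 0.5, "v0": 0.6, "shear": 0.5, "diffusion": 0.05},
    "smoke": {"radius": 0.3, "expansion": 0.8, "drift": 0.4, "jitter": 0.08},
    "fabric": {"half_width": 1.0, "half_height": 0.2, "amplitude": 0.2,
               "kappa": 3.1, "omega": 2.0 * np.pi * 1.2},
    "rigid_breakable": {"radius": 0.6, "v_fall": 0.8, "t_break": 1.0,
                        "n_fragments": 4, "fragment_speed": 0.4,
                        "spin": 3.0},
}


def _check_params(params: Mapping[str, float]) -> None:
    for key, val in params.items():
        if not np.all(np.isfinite(val)):
            raise ValueError(f"parameter {key!r} must be finite")


def simulate_material(
    material: str,
    *,
    n_frames: int = 48,
    n_points: int = 400,
    fps: float = 24.0,
    params: Mapping[str, float] | None = None,
    seed: int = 0,
    video_id: str | None = None,
    exemplar: str | None = None,
    view: int = 0,
) -> TrajectorySet:
    """Simulate one material animation as a point trajectory set.

    Deterministic given ``seed``.  ``params`` override the class defaults in
    :data:`DEFAULT_PARAMS`.
    """
    if material not in MATERIAL_CLASSES:
        raise ValueError(f"unknown material class {material!r}")
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    p = dict(DEFAULT_PARAMS[material])
    if params:
        p.update(params)
    _check_params(p)
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) / fps
    dt = 1.0 / fps

    if material == "jelly":
        pos = _simulate_jelly(rng, n_frames, n_points, t, p)
    elif material == "liquid":
        pos = _simulate_liquid(rng, n_frames, n_points, dt, p)
    elif material == "smoke":
        pos = _simulate_smoke(rng, n_frames, n_points, dt, p)
    elif material == "fabric":
        pos = _simulate_fabric(rng, n_frames, n_points, t, p)
    else:
        pos = _simulate_rigid_breakable(rng, n_frames, n_points, t, dt, p)

    return TrajectorySet(
        positions=pos,
        video_id=video_id or f"{material}-e0-v{view}",
        material=material,
        exemplar=exemplar or f"{material}-e0",
        view=view,
        fps=fps,
    )


def _disc_sample(rng: np.random.Generator, n: int, radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Uniform sample in a disc, returned as (rho, theta)."""
    rho = radius * np.sqrt(rng.uniform(0.0, 1.0, n))
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    return rho, theta


def _simulate_jelly(rng, n_frames, n_points, t, p):
    rho, theta = _disc_sample(rng, n_points, p["radius"])
    # radial standing-wave modulation; A=0 gives a perfectly static disc
    factor = 1.0 + (
        p["amplitude"]
        * np.exp(-p["decay"] * t)[:, None]
        * np.sin(p["k"] * theta)[None, :]
        * np.cos(p["omega"] * t)[:, None]
    )
    r = rho[None, :] * factor
    return np.stack([r * np.cos(theta)[None, :], r * np.sin(theta)[None, :]], axis=-1)


def _simulate_liquid(rng, n_frames, n_points, dt, p):
    rho, theta = _disc_sample(rng, n_points, p["radius"])
    x = rho * np.cos(theta)
    y = rho * np.sin(theta)
    pos = np.empty((n_frames, n_points, 2))
    pos[0, :, 0], pos[0, :, 1] = x, y
    for f in range(1, n_frames):
        x = x + rng.normal(0.0, p["diffusion"] * np.sqrt(dt), n_points)
        vy = p["v0"] * (1.0 + p["shear"] * (x - x.mean()))
        y = y + vy * dt
        pos[f, :, 0], pos[f, :, 1] = x, y
    return pos


def _simulate_smoke(rng, n_frames, n_points, dt, p):
    rho, theta = _disc_sample(rng, n_points, p["radius"])
    xy = np.stack([rho * np.cos(theta), rho * np.sin(theta)], axis=-1)
    centroid = np.zeros(2)
    pos = np.empty((n_frames, n_points, 2))
    pos[0] = xy
    for f in range(1, n_frames):
        centroid = centroid + np.array([0.0, -p["drift"] * dt])
        rel = xy - xy.mean(axis=0)
        xy = centroid + rel * (1.0 + p["expansion"] * dt)
        xy = xy + rng.normal(0.0, p["jitter"] * np.sqrt(dt), (n_points, 2))
        pos[f] = xy
    return pos


def _simulate_fabric(rng, n_frames, n_points, t, p):
    x = rng.uniform(-p["half_width"], p["half_width"], n_points)
    y0 = rng.uniform(-p["half_height"], p["half_height"], n_points)
    phase = p["kappa"] * x[None, :] - p["omega"] * t[:, None]
    dy = p["amplitude"] * np.sin(phase)
    pos = np.empty((len(t), n_points, 2))
    pos[:, :, 0] = x[None, :]
    pos[:, :, 1] = y0[None, :] + dy
    return pos


def _simulate_rigid_breakable(rng, n_frames, n_points, t, dt, p):
    rho, theta = _disc_sample(rng, n_points, p["radius"])
    xy0 = np.stack([rho * np.cos(theta), rho * np.sin(theta)], axis=-1)
    m = int(p["n_fragments"])
    # fragment membership by angular sector about the centroid
    sector = np.floor((theta % (2 * np.pi)) / (2 * np.pi / m)).astype(int)
    sector = np.clip(sector, 0, m - 1)
    v_fall = np.array([0.0, p["v_fall"]])
    frag_dir = rng.uniform(0.0, 2.0 * np.pi, m)
    frag_v = (
        p["fragment_speed"]
        * np.stack([np.cos(frag_dir), np.sin(frag_dir)], axis=-1)
    )
    frag_spin = rng.uniform(-p["spin"], p["spin"], m)

    pos = np.empty((n_frames, n_points, 2))
    for f, tf in enumerate(t):
        if tf <= p["t_break"]:
            pos[f] = xy0 + v_fall * tf
        else:
            tau = tf - p["t_break"]
            base = xy0 + v_fall * p["t_break"]
            out = np.empty_like(xy0)
            for j in range(m):
                idx = sector == j
                c = base[idx].mean(axis=0)
                ang = frag_spin[j] * tau
                rot = np.array(
                    [[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]]
                )
                shift = c + (v_fall + frag_v[j]) * tau
                out[idx] = (base[idx] - c) @ rot.T + shift
            pos[f] = out
    return pos


def latent_attributes_for_exemplar(
    material: str, exemplar_seed: int, jitter_sd: float, archetypes: Mapping[str, np.ndarray]
) -> np.ndarray:
    """Planted 5-vector for an exemplar: class archetype + seeded jitter, clipped to [0,1]."""
    rng = np.random.default_rng(exemplar_seed)
    base = np.asarray(archetypes[material], dtype=float)
    return np.clip(base + rng.normal(0.0, jitter_sd, base.shape), 0.0, 1.0)


def generate_stimulus_set(design: StimulusDesign) -> list[TrajectorySet]:
    """Generate the full stimulus set for a design.

    Exemplars within a class differ by seeded parameter jitter; views of an
    exemplar differ by an in-plane rotation plus a mild scale change
    (emulating camera angles of the same physical event).
    """
    master = np.random.default_rng(design.seed)
    videos: list[TrajectorySet] = []
    for material in MATERIAL_CLASSES:
        n_ex = design.exemplars_per_class.get(material, 0)
        n_views = design.views_per_class.get(material, 1)
        for e in range(n_ex):
            ex_rng = np.random.default_rng(master.integers(2**31))
            params = _jitter_params(material, ex_rng)
            base_seed = int(ex_rng.integers(2**31))
            exemplar_id = f"{material}-e{e}"
            base = simulate_material(
                material,
                n_frames=design.n_frames,
                n_points=design.n_points,
                fps=design.fps,
                params=params,
                seed=base_seed,
                exemplar=exemplar_id,
            )
            for v in range(n_views):
                ang = 2.0 * np.pi * v / n_views
                scale = 1.0 + 0.08 * np.cos(ang)
                rot = np.array(
                    [[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]]
                )
                pos = base.positions @ rot.T * scale
                videos.append(
                    TrajectorySet(
                        positions=pos,
                        video_id=f"{exemplar_id}-v{v}",
                        material=material,
                        exemplar=exemplar_id,
                        view=v,
                        fps=design.fps,
                    )
                )
    return videos


def _jitter_params(material: str, rng: np.random.Generator) -> dict[str, float]:
    """Multiplicative +-15% jitter on the class default parameters."""
    params = {}
    for key, val in DEFAULT_PARAMS[material].items():
        if key in ("n_fragments",):
            params[key] = val
        else:
            params[key] = float(val) * rng.uniform(0.85, 1.15)
    return params


def design_metadata(design: StimulusDesign):
    """Stimulus metadata table for a design without simulating trajectories."""
    import pandas as pd

    rows = []
    for material in MATERIAL_CLASSES:
        for e in range(design.exemplars_per_class.get(material, 0)):
            exemplar = f"{material}-e{e}"
            for v in range(design.views_per_class.get(material, 1)):
                rows.append((f"{exemplar}-v{v}", material, exemplar, v))
    return pd.DataFrame(rows, columns=["video_id", "material", "exemplar", "view"])


def video_metadata(videos: list[TrajectorySet]):
    """Tidy metadata table (video_id, material, exemplar, view) for a stimulus set."""
    import pandas as pd

    return pd.DataFrame(
        {
            "video_id": [v.video_id for v in videos],
            "material": [v.material for v in videos],
            "exemplar": [v.exemplar for v in videos],
            "view": [v.view for v in videos],
        }
    )
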