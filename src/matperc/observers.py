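"""Synthetic observers: attribute ratings and triplet similarity choices.

Each material class carries a 5-vector archetype over the attributes
(dense, flexible, wobbly, fluid, airy).  An exemplar's planted latent
vector is the archetype plus seeded jitter.  Ratings add per-observer bias
and response noise and pass through an "extremity" transform — a logistic
push toward the scale endpoints that reproduces the strongly bimodal
pooled rating histograms typical of categorical material impressions.

Triplet choices follow a softmax on negative Euclidean distances in the
latent space, with a lapse rate for occasional uniform guesses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .materials import ATTRIBUTES, MATERIAL_CLASSES

#: class archetypes over (dense, flexible, wobbly, fluid, airy)
DEFAULT_ARCHETYPES: Mapping[str, tuple[float, ...]] = {
    "jelly": (0.55, 0.75, 0.95, 0.25, 0.10),
    "liquid": (0.50, 0.60, 0.45, 0.95, 0.30),
    "smoke": (0.05, 0.30, 0.10, 0.55, 0.95),
    "fabric": (0.25, 0.95, 0.55, 0.35, 0.55),
    "rigid_breakable": (0.90, 0.05, 0.05, 0.05, 0.05),
}


@dataclass(frozen=True)
class ObserverModel:
    """Generative parameters for synthetic raters and triplet choosers."""

    archetypes: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPES)
    )
    exemplar_jitter_sd: float = 0.05
    observer_bias_sd: float = 0.05
    response_noise_sd: float = 0.08
    extremity: float = 8.0
    choice_temperature: float = 0.15
    lapse_rate: float = 0.02
    rt_median_ms: float = 1500.0
    rt_log_sd: float = 0.4

    def __post_init__(self) -> None:
        for name in ("exemplar_jitter_sd", "observer_bias_sd", "response_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.lapse_rate <= 1.0):
            raise ValueError("lapse_rate must be in [0, 1]")
        for cls, arch in self.archetypes.items():
            a = np.asarray(arch, dtype=float)
            if a.shape != (len(ATTRIBUTES),):
                raise ValueError(f"archetype for {cls!r} must have 5 entries")
            if ((a < 0) | (a > 1)).any():
                raise ValueError(f"archetype for {cls!r} must lie in [0, 1]")


def extremity_transform(v: np.ndarray, gain: float) -> np.ndarray:
    """Logistic push toward {0, 1}: sigma(g*(v-1/2)) rescaled to [0, 1].

    ``gain = 0`` is the identity; ``gain -> inf`` saturates to a step.
    """
    v = np.asarray(v, dtype=float)
    if gain == 0:
        return v.copy()
    lo = 1.0 / (1.0 + np.exp(gain / 2.0))
    hi = 1.0 / (1.0 + np.exp(-gain / 2.0))
    s = 1.0 / (1.0 + np.exp(-gain * (v - 0.5)))
    return (s - lo) / (hi - lo)


def latent_attribute_table(
    stimuli: pd.DataFrame, model: ObserverModel, seed: int
) -> pd.DataFrame:
    """Planted per-exemplar latent 5-vectors (archetype + seeded jitter).

    ``stimuli`` needs columns ``video_id``, ``material``, ``exemplar``.
    Jitter is keyed to the exemplar so all views share one latent vector.
    Returns one row per exemplar with attribute columns in [0, 1].
    """
    rng = np.random.default_rng(seed)
    rows = []
    for exemplar, grp in stimuli.groupby("exemplar", sort=True):
        material = grp["material"].iloc[0]
        base = np.asarray(model.archetypes[material], dtype=float)
        latent = np.clip(
            base + rng.normal(0.0, model.exemplar_jitter_sd, base.shape), 0.0, 1.0
        )
        rows.append({"exemplar": exemplar, "material": material,
                     **dict(zip(ATTRIBUTES, latent))})
    return pd.DataFrame(rows)


def simulate_ratings(
    stimuli: pd.DataFrame,
    model: ObserverModel = ObserverModel(),
    n_observers: int = 20,
    seed: int = 0,
    condition: str = "line",
    noise_scale: float = 1.0,
    structured: bool = True,
) -> pd.DataFrame:
    """Tidy RatingTable: one record per participant x video x attribute.

    rating = extremity(clip(latent + observer bias + noise, 0, 1)).
    ``noise_scale`` multiplies bias and noise SDs (degraded conditions);
    ``structured=False`` replaces the latent signal with uniform noise
    (pure-noise observers for null/difference tests).
    Deterministic given ``seed``.
    """
    if n_observers < 1:
        raise ValueError("n_observers must be >= 1")
    rng = np.random.default_rng(seed)
    latent = latent_attribute_table(stimuli, model, seed=int(rng.integers(2**31)))
    lat = latent.set_index("exemplar")[list(ATTRIBUTES)]
    videos = stimuli.sort_values("video_id").reset_index(drop=True)
    base = lat.loc[videos["exemplar"]].to_numpy()  # videos x 5

    n_videos = len(videos)
    records = []
    for o in range(n_observers):
        pid = f"{condition}-p{o:02d}"
        bias = rng.normal(0.0, model.observer_bias_sd * noise_scale, len(ATTRIBUTES))
        if structured:
            raw = base + bias[None, :]
        else:
            raw = rng.uniform(0.0, 1.0, (n_videos, len(ATTRIBUTES)))
        raw = raw + rng.normal(
            0.0, model.response_noise_sd * noise_scale, (n_videos, len(ATTRIBUTES))
        )
        vals = extremity_transform(np.clip(raw, 0.0, 1.0), model.extremity)
        for i in range(n_videos):
            for j, attr in enumerate(ATTRIBUTES):
                records.append(
                    (pid, videos["video_id"].iloc[i], condition, attr, vals[i, j])
                )
    return pd.DataFrame(
        records,
        columns=["participant_id", "video_id", "condition", "attribute", "rating"],
    )


def enumerate_triplet_plan(latent: pd.DataFrame) -> pd.DataFrame:
    """All (reference, test, test) exemplar triplets spanning three distinct classes."""
    by_class: dict[str, list[str]] = {}
    for _, row in latent.iterrows():
        by_class.setdefault(row["material"], []).append(row["exemplar"])
    plans = []
    for c1, c2, c3 in combinations(sorted(by_class), 3):
        for e1, e2, e3 in product(by_class[c1], by_class[c2], by_class[c3]):
            trio = (e1, e2, e3)
            for r in range(3):
                ref = trio[r]
                tests = tuple(t for k, t in enumerate(trio) if k != r)
                plans.append((ref, tests[0], tests[1]))
    return pd.DataFrame(plans, columns=["reference_id", "test_a", "test_b"])


def simulate_triplets(
    latent: pd.DataFrame,
    model: ObserverModel = ObserverModel(),
    n_observers: int = 20,
    trials_per_observer: int = 300,
    seed: int = 0,
    plan: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Tidy TripletTable of seeded softmax choices over latent distances.

    ``latent`` is the output of :func:`latent_attribute_table`.  The full
    cross-class triplet plan is enumerated and each observer sees a random
    subsample of ``trials_per_observer`` trials.  Choice probability for
    test x over y given reference r is softmax(-d(r,.)/T); with probability
    ``lapse_rate`` the choice is uniform.  RTs are log-normal.
    """
    rng = np.random.default_rng(seed)
    if plan is None:
        plan = enumerate_triplet_plan(latent)
    if plan.empty:
        raise ValueError("empty triplet plan")
    lat = latent.set_index("exemplar")
    cls = lat["material"]
    for _, row in plan.iterrows():
        ids = (row["reference_id"], row["test_a"], row["test_b"])
        if len({cls[i] for i in ids}) != 3:
            raise ValueError(f"triplet {ids} does not span three distinct classes")
    vecs = lat[list(ATTRIBUTES)]
    records = []
    n_plan = len(plan)
    for o in range(n_observers):
        pid = f"p{o:02d}"
        take = rng.choice(n_plan, size=min(trials_per_observer, n_plan), replace=False)
        for trial, k in enumerate(take):
            ref, ta, tb = plan.iloc[k]
            da = float(np.linalg.norm(vecs.loc[ref] - vecs.loc[ta]))
            db = float(np.linalg.norm(vecs.loc[ref] - vecs.loc[tb]))
            if model.choice_temperature <= 0:
                p_a = 0.5 if da == db else (1.0 if da < db else 0.0)
            else:
                z = np.clip((db - da) / model.choice_temperature, -500.0, 500.0)
                p_a = 1.0 / (1.0 + np.exp(-z))
            if rng.uniform() < model.lapse_rate:
                p_a = 0.5
            chosen = ta if rng.uniform() < p_a else tb
            if rng.uniform() < 0.5:
                left, right = ta, tb
            else:
                left, right = tb, ta
            side = "left" if chosen == left else "right"
            rt = float(
                model.rt_median_ms * np.exp(rng.normal(0.0, model.rt_log_sd))
            )
            records.append((pid, trial, ref, left, right, chosen, side, rt))
    return pd.DataFrame(
        records,
        columns=[
            "participant_id",
            "trial",
            "reference_id",
            "left_id",
            "right_id",
            "chosen_id",
            "chosen_side",
            "rt_ms",
        ],
    )
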