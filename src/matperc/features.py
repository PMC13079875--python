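"""Feature-space analysis: z-scoring, retained-variance PCA embedding,
distance-to-reference attribute predictors, regressions, feature RDMs, and
camera-angle resampling.

Motion (47-row) and shape (48-row) frame-level tables run through this
stage separately but identically: pool frames over videos, z-score each
feature column, PCA, retain the minimal number of components reaching 80%
cumulative variance, and average each video's frame scores into one
coordinate vector per video.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

from .materials import ATTRIBUTES
from .rsa import RDM, _rdm_from_vectors
from .stats import adjusted_r2, bh_adjust  # re-exported surface


@dataclass
class PCAEmbedding:
    loadings: np.ndarray  # features x retained components
    variance_ratios: np.ndarray  # all components
    n_retained: int
    video_scores: pd.DataFrame  # video_id + per-component mean scores
    feature_names: list[str]


@dataclass
class AttributePrediction:
    attribute: str
    reference_video_id: str
    predictors: pd.Series  # per video: distance to reference
    slope: float
    intercept: float
    r2: float
    adj_r2: float
    p: float
    p_bh: float | None = None


def zscore_columns(
    table: pd.DataFrame, feature_names: list[str]
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Z-score each feature column over valid rows, pooled across videos.

    Returns the standardized table plus the column means and SDs (n-1) so
    the transform can be reused.  A zero-variance column is an error naming
    the column.  Rows flagged ``valid == False`` are dropped first.
    """
    t = table
    if "valid" in t.columns:
        t = t[t["valid"]].copy()
    t = t.dropna(subset=feature_names)
    means = t[feature_names].mean()
    sds = t[feature_names].std(ddof=1)
    bad = sds[sds == 0].index.tolist()
    if bad:
        raise ValueError(f"zero-variance feature column(s): {bad}")
    out = t.copy()
    out[feature_names] = (t[feature_names] - means) / sds
    return out, means, sds


def fit_pca(
    standardized: pd.DataFrame,
    feature_names: list[str],
    variance_threshold: float = 0.80,
) -> PCAEmbedding:
    """PCA of the pooled frame-level table; retain the minimal component
    count whose cumulative variance ratio reaches the threshold; summarize
    each video by the mean of its frame scores over the retained space.
    """
    X = standardized[feature_names].to_numpy(dtype=float)
    if len(X) < 2:
        raise ValueError("PCA needs at least 2 rows")
    pca = PCA()
    scores = pca.fit_transform(X)
    ratios = pca.explained_variance_ratio_
    cum = np.cumsum(ratios)
    n_retained = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    cols = [f"pc{i + 1}" for i in range(n_retained)]
    sc = pd.DataFrame(scores[:, :n_retained], columns=cols)
    sc["video_id"] = standardized["video_id"].to_numpy()
    video_scores = sc.groupby("video_id", sort=True)[cols].mean().reset_index()
    return PCAEmbedding(
        loadings=pca.components_[:n_retained].T,
        variance_ratios=ratios,
        n_retained=n_retained,
        video_scores=video_scores,
        feature_names=list(feature_names),
    )


def mean_ratings_per_video(ratings: pd.DataFrame) -> pd.DataFrame:
    """Participant-averaged rating per video x attribute (wide)."""
    return ratings.pivot_table(
        index="video_id", columns="attribute", values="rating", aggfunc="mean"
    ).reindex(columns=list(ATTRIBUTES))


def attribute_predictor(
    embedding: PCAEmbedding, ratings: pd.DataFrame, attribute: str
) -> tuple[str, pd.Series]:
    """Distance-to-reference predictor for one attribute.

    The reference video is the one with the lowest participant-mean rating
    for the attribute (ties broken lexicographically by video_id); the
    predictor is each video's Euclidean distance to it in retained PCA
    space (0 at the reference).
    """
    mean_r = mean_ratings_per_video(ratings)
    vs = embedding.video_scores.set_index("video_id")
    missing = [v for v in vs.index if v not in mean_r.index]
    if missing:
        raise ValueError(f"ratings missing for embedded videos: {missing[:5]}")
    sub = mean_r.loc[vs.index, attribute]
    ref = sub[sub == sub.min()].index.sort_values()[0]
    coords = vs.to_numpy(dtype=float)
    ref_coord = vs.loc[ref].to_numpy(dtype=float)
    dist = np.linalg.norm(coords - ref_coord[None, :], axis=1)
    return ref, pd.Series(dist, index=vs.index, name=attribute)


def regress_attribute(y: pd.Series, predictor: pd.Series) -> dict:
    """OLS of participant-mean ratings on the distance predictor."""
    joined = pd.concat([y.rename("y"), predictor.rename("x")], axis=1).dropna()
    n = len(joined)
    if n < 3:
        raise ValueError("regression needs at least 3 videos")
    if joined["x"].nunique() == 1:
        raise ValueError("constant predictor")
    fit = sps.linregress(joined["x"], joined["y"])
    r2 = fit.rvalue**2
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r2": float(r2),
        "adj_r2": float(adjusted_r2(r2, n)),
        "p": float(fit.pvalue),
        "n": n,
        "slope_stderr": float(fit.stderr),
    }


def predict_attributes(
    embedding: PCAEmbedding, ratings: pd.DataFrame
) -> tuple[pd.DataFrame, list[AttributePrediction]]:
    """Distance predictors and regressions for all five attributes.

    Returns the per-video predicted-attribute table (5 columns) and the
    regression reports with BH-adjusted p-values across attributes.
    """
    mean_r = mean_ratings_per_video(ratings)
    preds = {}
    reports = []
    for attr in ATTRIBUTES:
        ref, d = attribute_predictor(embedding, ratings, attr)
        preds[attr] = d
        res = regress_attribute(mean_r.loc[d.index, attr], d)
        reports.append(
            AttributePrediction(
                attribute=attr,
                reference_video_id=ref,
                predictors=d,
                slope=res["slope"],
                intercept=res["intercept"],
                r2=res["r2"],
                adj_r2=res["adj_r2"],
                p=res["p"],
            )
        )
    p_bh = bh_adjust([r.p for r in reports])
    for r, adj in zip(reports, p_bh):
        r.p_bh = float(adj)
    return pd.DataFrame(preds), reports


def feature_rdm(predicted: pd.DataFrame) -> RDM:
    """1 - Spearman dissimilarities between items' 5 predicted attributes.

    Mirrors the construction used for the perceptual rating RDMs so the
    two are directly comparable by Mantel test.
    """
    if predicted.shape[1] != len(ATTRIBUTES):
        raise ValueError("need exactly 5 predicted attributes per item")
    return _rdm_from_vectors(list(predicted.index), predicted.to_numpy(dtype=float))


def camera_angle_resample(
    views_by_exemplar: dict[str, list[str]],
    analysis_fn,
    n_seeds: int = 100,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Rerun a full downstream analysis over random camera-angle choices.

    Per seed, one view is chosen uniformly per exemplar and
    ``analysis_fn(selected_video_ids, seed)`` (z-score -> PCA -> predictors
    -> regressions, and optional RDM comparisons) returns a flat dict of
    scalar outcomes.  The report stacks one row per seed.
    """
    for ex, views in views_by_exemplar.items():
        if len(views) == 0:
            raise ValueError(f"exemplar {ex!r} has no views")
    rows = []
    for s in range(n_seeds):
        seed = base_seed + s
        rng = np.random.default_rng(seed)
        selected = [
            views_by_exemplar[ex][rng.integers(len(views_by_exemplar[ex]))]
            for ex in sorted(views_by_exemplar)
        ]
        out = dict(analysis_fn(selected, seed))
        out["seed"] = seed
        rows.append(out)
    return pd.DataFrame(rows)
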