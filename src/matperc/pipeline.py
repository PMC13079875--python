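"""End-to-end pipeline tying the stages into one reproducible run.

Stages (in dependency order): ``simulate`` -> ``dots`` -> ``features`` ->
``observers`` -> ``rdms`` -> ``rsa`` -> ``embedding``.  Each stage pulls
its inputs from the in-memory artifact store and fails with an explicit
message when a required upstream artifact is missing.  Every report
carries the config hash; reruns with the same config are identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .config import RunConfig
from .dots import DotSamplingRule, area_fraction_series, masks_from_points, n_dots, sample_dots
from .efa import efa
from .features import feature_rdm, fit_pca, predict_attributes, zscore_columns
from .materials import generate_stimulus_set, video_metadata
from .motion import MOTION_COLUMNS, GridSpec, motion_features_for_videos
from .observers import latent_attribute_table, simulate_ratings, simulate_triplets
from .rsa import (
    cluster_agreement,
    interobserver_correlations,
    mantel_test,
    rating_rdm,
    triplet_rdm,
    ward_cluster,
)
from .shape import SHAPE_FEATURE_NAMES, shape_features_for_videos

log = logging.getLogger("matperc")

STAGES = ("simulate", "dots", "features", "observers", "rdms", "rsa", "embedding")


class PipelineError(RuntimeError):
    pass


def _need(artifacts: dict, key: str, stage: str):
    if key not in artifacts:
        raise PipelineError(
            f"stage {stage!r} requires missing artifact {key!r}; "
            f"run its producing stage first"
        )
    return artifacts[key]


def run_pipeline(
    config: RunConfig,
    stages: tuple[str, ...] | None = None,
    outdir: str | Path | None = None,
    artifacts: dict | None = None,
) -> dict:
    """Run the selected stages; returns the artifact store.

    ``artifacts['report']`` accumulates the scalar results; when ``outdir``
    is given, tables and reports are written there as CSV/JSON.
    """
    stages = tuple(stages) if stages is not None else STAGES
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stage(s): {sorted(unknown)}")
    art: dict = artifacts if artifacts is not None else {}
    report = art.setdefault("report", {})
    report["config_hash"] = config.config_hash()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    a = config.analysis

    if "simulate" in stages:
        log.info("simulating stimulus set")
        design = config.design
        art["videos"] = generate_stimulus_set(design)
        art["stimuli"] = video_metadata(art["videos"])
        if out is not None:
            art["stimuli"].to_csv(out / "stimuli.csv", index=False)

    if "dots" in stages:
        videos = _need(art, "videos", "dots")
        rule: DotSamplingRule = config.dot_rule
        rows = []
        dotted = []
        for v in videos:
            m = masks_from_points(
                v, grid_shape=(a.mask_grid, a.mask_grid), radius=a.dot_radius
            )
            series = area_fraction_series(m)
            k = min(n_dots(series, rule), v.n_points)
            rows.append({"video_id": v.video_id, "n_dots": k,
                         "p75_area_fraction": float(np.percentile(series, rule.percentile))})
            dotted.append(sample_dots(v, k, seed=config.seed_for(f"dots:{v.video_id}")))
        art["dot_videos"] = dotted
        art["dot_counts"] = pd.DataFrame(rows)
        if out is not None:
            art["dot_counts"].to_csv(out / "dot_counts.csv", index=False)

    if "features" in stages:
        videos = _need(art, "videos", "features")
        log.info("extracting motion and shape features")
        art["motion_features"] = motion_features_for_videos(
            videos, grid=GridSpec(shape=(a.flow_grid, a.flow_grid))
        )
        art["shape_features"] = shape_features_for_videos(
            videos,
            mask_fn=lambda t: masks_from_points(
                t, grid_shape=(a.mask_grid, a.mask_grid), radius=a.dot_radius
            ),
        )
        if out is not None:
            art["motion_features"].to_csv(out / "motion_features.csv", index=False)
            art["shape_features"].to_csv(out / "shape_features.csv", index=False)

    if "observers" in stages:
        stimuli = _need(art, "stimuli", "observers")
        model = config.observer
        art["ratings"] = simulate_ratings(
            stimuli, model, n_observers=a.n_observers,
            seed=config.seed_for("ratings"), condition="line",
        )
        latent = latent_attribute_table(
            stimuli, model,
            seed=np.random.default_rng(config.seed_for("ratings")).integers(2**31),
        )
        art["latent"] = latent
        art["triplets"] = simulate_triplets(
            latent, model, n_observers=a.n_observers,
            trials_per_observer=a.trials_per_observer,
            seed=config.seed_for("triplets"),
        )
        if out is not None:
            mio.write_ratings(art["ratings"], out / "ratings.csv")
            mio.write_triplets(art["triplets"], out / "triplets.csv")

    if "rdms" in stages:
        ratings = _need(art, "ratings", "rdms")
        stimuli = _need(art, "stimuli", "rdms")
        triplets = _need(art, "triplets", "rdms")
        art["rating_rdm"] = rating_rdm(ratings, stimuli, level="exemplar")
        art["triplet_rdm"] = triplet_rdm(triplets, level="exemplar")
        if out is not None:
            mio.write_rdm(art["rating_rdm"], out / "rating_rdm.csv")
            mio.write_rdm(art["triplet_rdm"], out / "triplet_rdm.csv")

    if "rsa" in stages:
        ratings = _need(art, "ratings", "rsa")
        stimuli = _need(art, "stimuli", "rsa")
        _, mean_io = interobserver_correlations(ratings)
        report["mean_interobserver_spearman"] = mean_io
        res = mantel_test(
            _need(art, "rating_rdm", "rsa"),
            _need(art, "triplet_rdm", "rsa"),
            n_perm=a.n_perm,
            seed=config.seed_for("mantel"),
        )
        report["mantel_rating_vs_triplet_r"] = res.r
        report["mantel_rating_vs_triplet_p"] = res.p
        fa = efa(ratings, stimuli, n_factors=a.n_factors)
        art["efa"] = fa
        report["two_factor_variance_pct"] = float(
            100.0 * fa.scree_ratios[: a.n_factors].sum()
        )
        ex = fa.exemplar_scores
        classes = (
            stimuli.drop_duplicates("exemplar").set_index("exemplar")["material"]
        )
        cl = ward_cluster(
            ex[[c for c in ex.columns if c.startswith("factor")]].to_numpy(),
            ids=ex["exemplar"].tolist(),
            k=a.k_clusters,
        )
        art["clusters"] = cl
        report["ward_ari_vs_classes"] = cluster_agreement(
            cl.labels, classes.loc[cl.ids].to_numpy()
        )
        if out is not None:
            mio.write_report(report, out / "rsa_report.json")

    if "embedding" in stages:
        ratings = _need(art, "ratings", "embedding")
        stimuli = _need(art, "stimuli", "embedding")
        perceptual_video_rdm = rating_rdm(ratings, stimuli, level="video")
        results = {}
        for name, feats in (
            ("motion", list(MOTION_COLUMNS)),
            ("shape", list(SHAPE_FEATURE_NAMES)),
        ):
            table = _need(art, f"{name}_features", "embedding")
            std, _, _ = zscore_columns(table, feats)
            emb = fit_pca(std, feats, variance_threshold=a.variance_threshold)
            predicted, reports = predict_attributes(emb, ratings)
            rdm = feature_rdm(predicted)
            res = mantel_test(
                rdm,
                perceptual_video_rdm,
                n_perm=a.n_perm,
                seed=config.seed_for(f"mantel:{name}"),
            )
            results[name] = {
                "n_retained": emb.n_retained,
                "mantel_vs_rating_r": res.r,
                "mantel_vs_rating_p": res.p,
                "regressions": {
                    r.attribute: {"adj_r2": r.adj_r2, "p": r.p, "p_bh": r.p_bh}
                    for r in reports
                },
            }
            art[f"{name}_embedding"] = emb
            art[f"{name}_feature_rdm"] = rdm
        report["feature_space"] = results
        if out is not None:
            mio.write_report(report, out / "pipeline_report.json")

    return art
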