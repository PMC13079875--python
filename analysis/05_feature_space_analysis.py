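"""Relate image statistics to perception: PCA embedding, distance
predictors, regressions with BH correction, and feature-vs-perception RSA.

Reads the frame-level motion/shape tables (02) and ratings (03).  Per
domain: z-score columns, retain PCA components to 80% cumulative
variance, average frame scores per video, build the lowest-rated-
reference distance predictor per attribute, regress participant-mean
ratings on it (adjusted R^2, BH-adjusted p), and compare the feature-
derived RDM to the rating RDM by Mantel test.  Writes
results/feature_space_report.json.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from matperc.config import RunConfig
from matperc.features import feature_rdm, fit_pca, predict_attributes, zscore_columns
from matperc.io import read_ratings, write_report
from matperc.materials import design_metadata
from matperc.motion import MOTION_COLUMNS
from matperc.rsa import mantel_test, rating_rdm
from matperc.shape import SHAPE_FEATURE_NAMES

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = RunConfig(master_seed=1)
    stimuli = design_metadata(cfg.design)
    ratings = read_ratings(OUT / "ratings.csv")
    report = {}
    for name, path, feats in (
        ("motion", OUT / "motion_features.csv", list(MOTION_COLUMNS)),
        ("shape", OUT / "shape_features.csv", list(SHAPE_FEATURE_NAMES)),
    ):
        table = pd.read_csv(path)
        std, _, _ = zscore_columns(table, feats)
        emb = fit_pca(std, feats, variance_threshold=cfg.analysis.variance_threshold)
        predicted, regs = predict_attributes(emb, ratings)
        print(f"{name}: {emb.n_retained} PCs retained "
              f"({100 * emb.variance_ratios[:emb.n_retained].sum():.1f}% variance)")
        for r in regs:
            star = "*" if r.p_bh <= 0.05 else " "
            print(f"  {r.attribute:10s} adj R2 = {r.adj_r2:5.2f}  p_BH = {r.p_bh:.4f} {star}")

        vids = sorted(predicted.index)
        ratings_sub = ratings[ratings["video_id"].isin(vids)]
        perc = rating_rdm(ratings_sub, stimuli, level="video")
        res = mantel_test(feature_rdm(predicted), perc, n_perm=cfg.analysis.n_perm,
                          seed=cfg.seed_for(f"mantel:{name}"))
        print(f"  Mantel {name}-RDM vs rating-RDM: r = {res.r:.3f}, p = {res.p:.3f}")
        report[name] = {
            "n_retained": emb.n_retained,
            "regressions": {
                r.attribute: {"adj_r2": r.adj_r2, "p": r.p, "p_bh": r.p_bh} for r in regs
            },
            "mantel_vs_rating": {"r": res.r, "p": res.p},
        }
    write_report(report, OUT / "feature_space_report.json")


if __name__ == "__main__":
    main()
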