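"""Perceptual battery: consistency, factor structure, clustering, RSA.

Reads the simulated ratings/triplets (03), computes inter-observer
Spearman consistency, the 2-factor ML/varimax solution with Ward
clustering of exemplar factor scores at k = 5, the rating and triplet
RDMs, and their Mantel correspondence at 999 permutations.  Writes
results/rating_rdm.csv, results/triplet_rdm.csv, results/rsa_report.json.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from matperc.config import RunConfig
from matperc.efa import efa
from matperc.io import read_ratings, read_triplets, write_rdm, write_report
from matperc.materials import design_metadata
from matperc.rsa import (
    cluster_agreement,
    interobserver_correlations,
    mantel_test,
    rating_rdm,
    triplet_rdm,
    ward_cluster,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = RunConfig(master_seed=1)
    stimuli = design_metadata(cfg.design)
    ratings = read_ratings(OUT / "ratings.csv")
    triplets = read_triplets(OUT / "triplets.csv")

    _, mean_io = interobserver_correlations(ratings)
    print(f"mean inter-observer Spearman: {mean_io:.3f}")

    fa = efa(ratings, stimuli, n_factors=cfg.analysis.n_factors)
    two = 100 * fa.scree_ratios[:2].sum()
    print(f"two-factor variance: {two:.1f}%")
    print("varimax loadings:")
    print(fa.loadings.round(2).to_string())

    cl = ward_cluster(
        fa.exemplar_scores[["factor1", "factor2"]].to_numpy(),
        fa.exemplar_scores["exemplar"].tolist(),
        k=cfg.analysis.k_clusters,
    )
    classes = stimuli.drop_duplicates("exemplar").set_index("exemplar")["material"]
    ari = cluster_agreement(cl.labels, classes.loc[cl.ids].to_numpy())
    print(f"Ward(k=5) ARI vs material classes: {ari:.2f}")

    r_rdm = rating_rdm(ratings, stimuli, level="exemplar")
    t_rdm = triplet_rdm(triplets, level="exemplar")
    write_rdm(r_rdm, OUT / "rating_rdm.csv")
    write_rdm(t_rdm, OUT / "triplet_rdm.csv")
    res = mantel_test(r_rdm, t_rdm, n_perm=cfg.analysis.n_perm, seed=cfg.seed_for("mantel"))
    print(f"Mantel rating vs triplet RDM: r = {res.r:.3f}, p = {res.p:.3f} "
          f"({res.n_perm} permutations, {res.n_pairs} pairs)")

    write_report(
        {
            "mean_interobserver_spearman": mean_io,
            "two_factor_variance_pct": two,
            "loadings": fa.loadings.to_dict(),
            "ward_ari": ari,
            "mantel_rating_vs_triplet": {"r": res.r, "p": res.p, "n_perm": res.n_perm},
        },
        OUT / "rsa_report.json",
    )


if __name__ == "__main__":
    main()
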