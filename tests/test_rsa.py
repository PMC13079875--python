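"""RDM construction, Mantel tests (incl. exhaustive oracle), clustering, QC."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from matperc import (
    RDM,
    cluster_agreement,
    detect_inattention,
    interobserver_correlations,
    mantel_difference_test,
    mantel_test,
    rating_rdm,
    simulate_ratings,
    triplet_rdm,
    ward_cluster,
)
from matperc.materials import ATTRIBUTES
from matperc.observers import ObserverModel


def _random_rdm(rng, n):
    m = rng.uniform(0.1, 1.0, (n, n))
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 0.0)
    return RDM([f"i{k}" for k in range(n)], m)


# --- RDM constructors -------------------------------------------------------

def test_rdm_validation():
    with pytest.raises(ValueError, match="symmetric"):
        RDM(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(ValueError, match="diagonal"):
        RDM(["a", "b"], np.array([[1.0, 1.0], [1.0, 0.0]]))


def _ratings_from_matrix(vals, items):
    """participant x item rating table from an items x 5 value matrix per pid."""
    rows = []
    for pid, mat in vals.items():
        for i, item in enumerate(items):
            for j, attr in enumerate(ATTRIBUTES):
                rows.append((pid, item, "line", attr, mat[i][j]))
    return pd.DataFrame(
        rows, columns=["participant_id", "video_id", "condition", "attribute", "rating"]
    )


def test_rating_rdm_identical_and_antiranked_items():
    items = ["a", "b", "c", "d"]
    base = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
    vals = {
        "p0": [base, base, base[::-1], [0.2, 0.4, 0.6, 0.8, 1.0]],
    }
    r = _ratings_from_matrix(vals, items)
    rdm = rating_rdm(r, level="video")
    f = rdm.to_frame()
    assert f.loc["a", "b"] == pytest.approx(0.0)  # identical ranks
    assert f.loc["a", "c"] == pytest.approx(2.0)  # exactly reversed ranks
    assert f.loc["a", "d"] == pytest.approx(0.0)  # equal ranks again
    assert ((f.to_numpy() >= 0) & (f.to_numpy() <= 2)).all()


def test_rating_rdm_printed_spearman_value():
    items = ["a", "b"]
    vals = {"p0": [[1, 2, 3, 4, 5], [2, 1, 3, 5, 4]]}
    rdm = rating_rdm(_ratings_from_matrix(vals, items), level="video")
    assert rdm.to_frame().loc["a", "b"] == pytest.approx(0.2)


def test_rating_rdm_constant_item_falls_back_to_one():
    items = ["a", "b"]
    vals = {"p0": [[0.5] * 5, [0.1, 0.2, 0.3, 0.4, 0.5]]}
    with pytest.warns(UserWarning, match="constant"):
        rdm = rating_rdm(_ratings_from_matrix(vals, items), level="video")
    assert rdm.to_frame().loc["a", "b"] == pytest.approx(1.0)


def test_interobserver_identical_and_reversed():
    items = ["a", "b", "c"]
    m1 = [[0.1, 0.2, 0.3, 0.4, 0.5], [0.2, 0.3, 0.4, 0.5, 0.6], [0.0, 0.1, 0.2, 0.3, 0.4]]
    flat = np.array(m1).ravel()
    reversed_ranks = (1.0 - flat).reshape(3, 5)
    r = _ratings_from_matrix({"p0": m1, "p1": m1, "p2": reversed_ranks}, items)
    corr, _ = interobserver_correlations(r)
    assert corr.loc["p0", "p1"] == pytest.approx(1.0)
    assert corr.loc["p0", "p2"] == pytest.approx(-1.0)


def test_interobserver_matches_bruteforce_oracle(rng):
    items = ["a", "b", "c"]
    vals = {f"p{i}": rng.uniform(0, 1, (3, 5)) for i in range(3)}
    r = _ratings_from_matrix(vals, items)
    corr, mean = interobserver_correlations(r)
    for pa, pb in itertools.combinations(sorted(vals), 2):
        rho = sps.spearmanr(np.ravel(vals[pa]), np.ravel(vals[pb])).statistic
        assert corr.loc[pa, pb] == pytest.approx(rho)
    off = [corr.loc[a, b] for a, b in itertools.combinations(sorted(vals), 2)]
    assert mean == pytest.approx(np.mean(off))


def test_triplet_rdm_counting():
    t = pd.DataFrame(
        {
            "participant_id": ["p0"] * 4,
            "reference_id": ["a", "a", "a", "b"],
            "left_id": ["b", "b", "c", "c"],
            "right_id": ["c", "c", "d", "d"],
            "chosen_id": ["b", "c", "c", "c"],
            "chosen_side": ["left", "right", "left", "left"],
            "rt_ms": [500.0] * 4,
        }
    )
    rdm = triplet_rdm(t, level="exemplar")
    f = rdm.to_frame()
    # (a,b): qualifying in 2 trials, grouped once -> dissimilarity 0.5
    assert f.loc["a", "b"] == pytest.approx(0.5)
    # (a,c): qualifying 3 times, grouped twice -> 1/3
    assert f.loc["a", "c"] == pytest.approx(1 - 2 / 3)
    # (b,c): grouped in its single qualifying trial -> 0
    assert f.loc["b", "c"] == pytest.approx(0.0)
    # (c,d): only ever co-occur as the two tests, never reference-test -> missing
    assert np.isnan(f.loc["c", "d"])
    # (a,d) and (b,d): qualifying once each, never grouped -> 1
    assert f.loc["a", "d"] == pytest.approx(1.0)
    assert f.loc["b", "d"] == pytest.approx(1.0)


# --- Mantel -----------------------------------------------------------------

def test_mantel_identical_rdms_r_one(rng):
    a = _random_rdm(rng, 8)
    res = mantel_test(a, a, n_perm=99, seed=0)
    assert res.r == pytest.approx(1.0)
    assert res.p == pytest.approx(1 / 100, abs=0.05)


def test_mantel_exact_matches_bruteforce_oracle(rng):
    """On 4 items the exhaustive permutation p equals a brute-force oracle."""
    a = _random_rdm(rng, 4)
    b = _random_rdm(rng, 4)
    res = mantel_test(a, b, exact=True)
    # independent oracle: enumerate all 24 relabelings with scipy.spearmanr
    il = np.tril_indices(4, k=-1)
    r_obs = sps.spearmanr(a.values[il], b.values[il]).statistic
    count = 0
    perms = list(itertools.permutations(range(4)))
    for p in perms:
        pa = a.values[np.ix_(p, p)]
        r_p = sps.spearmanr(pa[il], b.values[il]).statistic
        if r_p >= r_obs - 1e-12:
            count += 1
    assert res.p == pytest.approx(count / len(perms))
    assert res.r == pytest.approx(r_obs)


def test_mantel_relabeling_invariance(rng):
    a = _random_rdm(rng, 7)
    b = _random_rdm(rng, 7)
    perm = rng.permutation(7)
    ids = [a.ids[i] for i in perm]
    a2 = RDM(ids, a.values[np.ix_(perm, perm)])
    b2 = RDM(ids, b.values[np.ix_(perm, perm)])
    r1 = mantel_test(a, b, n_perm=49, seed=3).r
    r2 = mantel_test(a2, b2, n_perm=49, seed=3).r
    assert r1 == pytest.approx(r2)


def test_mantel_agrees_with_skbio_on_complete_matrices(rng):
    from skbio.stats.distance import DistanceMatrix, mantel as skbio_mantel

    a = _random_rdm(rng, 9)
    b = _random_rdm(rng, 9)
    res = mantel_test(a, b, n_perm=999, seed=1)
    r_ref, p_ref, _ = skbio_mantel(
        DistanceMatrix(a.values, a.ids),
        DistanceMatrix(b.values, b.ids),
        method="spearman",
        permutations=999,
        alternative="greater",
    )
    assert res.r == pytest.approx(float(r_ref), abs=1e-9)
    assert res.p == pytest.approx(float(p_ref), abs=0.05)


def test_mantel_small_matrix_rejected(rng):
    a = _random_rdm(rng, 3)
    with pytest.raises(ValueError):
        mantel_test(a, a)


def test_mantel_difference_identical_groups_zero(small_stimuli):
    model = ObserverModel()
    ra = simulate_ratings(small_stimuli, model, n_observers=4, seed=10, condition="a")
    ref = rating_rdm(ra, small_stimuli, level="exemplar")
    d, p = mantel_difference_test(ra, ra, ref, small_stimuli, n_perm=49, seed=0)
    assert d == pytest.approx(0.0, abs=1e-12)
    assert p > 0.5


def test_mantel_difference_planted_signal_detected(small_stimuli):
    model = ObserverModel()
    ra = simulate_ratings(small_stimuli, model, n_observers=10, seed=11, condition="a")
    rb = simulate_ratings(
        small_stimuli, model, n_observers=10, seed=12, condition="b", structured=False
    )
    ref = rating_rdm(
        simulate_ratings(small_stimuli, model, n_observers=10, seed=13, condition="full"),
        small_stimuli,
        level="exemplar",
    )
    d, p = mantel_difference_test(ra, rb, ref, small_stimuli, n_perm=199, seed=1)
    assert d > 0.3
    assert p <= 0.05


# --- clustering and QC ------------------------------------------------------

def test_ward_recovers_separated_clouds(rng):
    centers = np.array([[0, 0], [10, 0], [0, 10], [10, 10], [5, 20]], dtype=float)
    pts = np.vstack([c + rng.normal(0, 0.3, (6, 2)) for c in centers])
    ids = [f"x{i}" for i in range(len(pts))]
    res = ward_cluster(pts, ids, k=5)
    planted = np.repeat(np.arange(5), 6)
    assert cluster_agreement(res.labels, planted) == pytest.approx(1.0)


def test_ward_k_equals_n_and_duplicates(rng):
    pts = rng.normal(size=(6, 2))
    res = ward_cluster(pts, [f"x{i}" for i in range(6)], k=6)
    assert len(set(res.labels)) == 6
    dup = np.vstack([pts, pts[0]])
    res2 = ward_cluster(dup, [f"x{i}" for i in range(7)], k=6)
    assert res2.labels[0] == res2.labels[6]  # duplicates merge first
    with pytest.raises(ValueError):
        ward_cluster(pts[:3], ["a", "b", "c"], k=5)


def test_ari_examples_and_pair_counting_oracle(rng):
    assert cluster_agreement([1, 1, 2, 2], [5, 5, 6, 6]) == pytest.approx(1.0)
    assert cluster_agreement([1, 1, 1, 1], [1, 2, 3, 4]) == pytest.approx(0.0)

    def oracle_ari(x, y):
        # pair-counting: ARI = (sum_ij C(n_ij,2) - E) / (max - E)
        from math import comb

        x, y = np.asarray(x), np.asarray(y)
        n = len(x)
        cx = {v: (x == v).sum() for v in set(x)}
        cy = {v: (y == v).sum() for v in set(y)}
        nij = sum(
            comb(int(((x == a) & (y == b)).sum()), 2) for a in cx for b in cy
        )
        ai = sum(comb(int(v), 2) for v in cx.values())
        bj = sum(comb(int(v), 2) for v in cy.values())
        expected = ai * bj / comb(n, 2)
        maximum = 0.5 * (ai + bj)
        return (nij - expected) / (maximum - expected)

    for _ in range(5):
        x = rng.integers(0, 3, 12)
        y = rng.integers(0, 4, 12)
        if len(set(x.tolist())) < 2 or len(set(y.tolist())) < 2:
            continue
        assert cluster_agreement(x, y) == pytest.approx(oracle_ari(x, y), abs=1e-12)


def _qc_table(sides, rts):
    return pd.DataFrame(
        {
            "participant_id": ["p0"] * len(sides),
            "trial": range(len(sides)),
            "reference_id": ["a"] * len(sides),
            "left_id": ["b"] * len(sides),
            "right_id": ["c"] * len(sides),
            "chosen_id": ["b"] * len(sides),
            "chosen_side": sides,
            "rt_ms": rts,
        }
    )


def test_inattention_side_run_boundary():
    # 15 consecutive same-side choices -> flagged (threshold is "more than 14")
    flagged = detect_inattention(_qc_table(["left"] * 15, [800.0] * 15))
    assert flagged["flagged"].iloc[0]
    # 14 consecutive then alternation -> not flagged
    sides = ["left"] * 14 + ["right", "left", "right"]
    ok = detect_inattention(_qc_table(sides, [800.0] * len(sides)))
    assert not ok["flagged"].iloc[0]


def test_inattention_consistently_fast():
    fast = detect_inattention(_qc_table(["left", "right"] * 6, [300.0] * 12))
    assert fast["flagged"].iloc[0] and fast["flag_fast_window"].iloc[0]
    mixed_rts = [300.0 if i % 2 else 900.0 for i in range(12)]
    ok = detect_inattention(_qc_table(["left", "right"] * 6, mixed_rts))
    assert not ok["flagged"].iloc[0]
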