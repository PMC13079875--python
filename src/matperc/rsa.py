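"""Representational similarity analysis: RDM construction, Mantel tests,
inter-observer consistency, Ward clustering, and response-quality screening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import adjusted_rand_score

from .materials import ATTRIBUTES
from .stats import spearman, spearman_matrix


@dataclass
class RDM:
    """Symmetric zero-diagonal dissimilarity matrix over named items.

    Off-diagonal NaNs mark missing entries (pairs never observed); they are
    excluded pairwise from Mantel correlations.
    """

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("RDM shape must match item count")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("RDM diagonal must be zero")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("RDM must be symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def reordered(self, ids: list[str]) -> "RDM":
        idx = [self.ids.index(i) for i in ids]
        return RDM(list(ids), self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    seed: int | None
    tail: str
    n_items: int
    n_pairs: int


@dataclass
class ClusterResult:
    ids: list[str]
    labels: np.ndarray
    linkage: np.ndarray
    k: int


# ---------------------------------------------------------------------------
# rating-table plumbing

def _attach_items(ratings: pd.DataFrame, stimuli: pd.DataFrame | None, level: str) -> pd.DataFrame:
    r = ratings.copy()
    if level == "video":
        r["item"] = r["video_id"]
    elif level == "exemplar":
        if stimuli is None:
            raise ValueError("exemplar-level aggregation needs the stimuli table")
        mapping = stimuli.set_index("video_id")["exemplar"]
        r["item"] = r["video_id"].map(mapping)
        if r["item"].isna().any():
            raise ValueError("ratings contain video_ids absent from stimuli table")
    else:
        raise ValueError(f"unknown level {level!r}")
    return r


def _participant_blocks(
    ratings: pd.DataFrame, stimuli: pd.DataFrame | None = None, level: str = "exemplar"
) -> tuple[list[str], dict[str, np.ndarray]]:
    """Per-participant (items x 5 attributes) rating blocks in fixed item order.

    At exemplar level, ratings are first averaged over the views of each
    exemplar within participant.
    """
    r = _attach_items(ratings, stimuli, level)
    agg = (
        r.groupby(["participant_id", "item", "attribute"], sort=True)["rating"]
        .mean()
        .reset_index()
    )
    items = sorted(agg["item"].unique())
    blocks: dict[str, np.ndarray] = {}
    for pid, grp in agg.groupby("participant_id", sort=True):
        wide = grp.pivot(index="item", columns="attribute", values="rating")
        if wide.isna().any().any() or len(wide) != len(items):
            raise ValueError(f"participant {pid!r} has incomplete ratings")
        blocks[pid] = wide.reindex(index=items, columns=list(ATTRIBUTES)).to_numpy()
    return items, blocks


def interobserver_correlations(ratings: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Spearman correlations between participants' flattened rating vectors.

    Each participant's ratings over all videos x 5 attributes are flattened
    in a fixed (video, attribute) order.  Returns the symmetric correlation
    matrix and the mean over the off-diagonal upper triangle.
    """
    items, blocks = _participant_blocks(ratings, level="video")
    pids = sorted(blocks)
    mat = np.stack([blocks[p].ravel() for p in pids])
    corr = spearman_matrix(mat)
    out = pd.DataFrame(corr, index=pids, columns=pids)
    iu = np.triu_indices(len(pids), k=1)
    mean = float(np.nanmean(corr[iu])) if len(pids) > 1 else float("nan")
    return out, mean


def rating_rdm(
    ratings: pd.DataFrame,
    stimuli: pd.DataFrame | None = None,
    level: str = "exemplar",
    combine: str = "concat",
) -> RDM:
    """1 - Spearman rating dissimilarities between items (range [0, 2]).

    Each item's vector concatenates, participant by participant in a fixed
    order, its 5 attribute ratings (``combine='concat'``); ``'mean'``
    averages over participants first.  A constant item vector has an
    undefined rank correlation; its dissimilarities fall back to 1 with a
    warning.
    """
    items, blocks = _participant_blocks(ratings, stimuli, level)
    pids = sorted(blocks)
    if combine == "concat":
        mat = np.hstack([blocks[p] for p in pids])
    elif combine == "mean":
        mat = np.mean([blocks[p] for p in pids], axis=0)
    else:
        raise ValueError(f"unknown combine {combine!r}")
    return _rdm_from_vectors(items, mat)


def _rdm_from_vectors(items: list[str], mat: np.ndarray) -> RDM:
    corr = spearman_matrix(mat)
    if np.isnan(corr).any():
        warnings.warn(
            "constant item vector: undefined rank correlation, dissimilarity set to 1",
            stacklevel=2,
        )
        corr = np.where(np.isnan(corr), 0.0, corr)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)  # exact symmetry against float noise
    return RDM(list(items), d)


def triplet_rdm(
    triplets: pd.DataFrame,
    level: str = "exemplar",
    class_of: pd.Series | None = None,
) -> RDM:
    """Triplet-choice dissimilarities: 1 - P(grouped | could be grouped).

    A reference-test pair counts as "could be grouped" in every trial where
    one is the reference and the other a test; it "was grouped" when that
    test was chosen.  Pairs that never co-occur (e.g. same-class pairs,
    which never share a triplet) are NaN-flagged.  ``level='category'``
    aggregates to material classes via ``class_of``.
    """
    t = triplets.copy()
    cols = ["reference_id", "left_id", "right_id", "chosen_id"]
    if level == "category":
        if class_of is None:
            raise ValueError("category-level aggregation needs class_of mapping")
        for c in cols:
            t[c] = t[c].map(class_of)
    elif level != "exemplar":
        raise ValueError(f"unknown level {level!r}")
    items = sorted(set(t["reference_id"]) | set(t["left_id"]) | set(t["right_id"]))
    index = {it: i for i, it in enumerate(items)}
    n = len(items)
    could = np.zeros((n, n))
    did = np.zeros((n, n))
    for ref, left, right, chosen in t[cols].itertuples(index=False):
        i = index[ref]
        for test in (left, right):
            j = index[test]
            could[i, j] += 1
            could[j, i] += 1
            if test == chosen:
                did[i, j] += 1
                did[j, i] += 1
    with np.errstate(invalid="ignore"):
        sim = np.where(could > 0, did / np.where(could > 0, could, 1), np.nan)
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    return RDM(items, d)


# ---------------------------------------------------------------------------
# Mantel machinery

def _triangle(values: np.ndarray) -> np.ndarray:
    il = np.tril_indices(values.shape[0], k=-1)
    return values[il]


def rdm_correlation(a: RDM, b: RDM) -> float:
    """Spearman correlation between the lower triangles (NaN pairs excluded)."""
    b = b.reordered(a.ids) if a.ids != b.ids else b
    va, vb = _triangle(a.values), _triangle(b.values)
    ok = np.isfinite(va) & np.isfinite(vb)
    return spearman(va[ok], vb[ok])


def mantel_test(
    a: RDM,
    b: RDM,
    n_perm: int = 999,
    seed: int | None = 0,
    tail: str = "greater",
    exact: bool = False,
) -> MantelResult:
    """Mantel permutation test between two RDMs over the same items.

    The statistic is the Spearman correlation between lower triangles; the
    null jointly permutes the item labels (rows and columns) of the first
    matrix.  ``exact=True`` enumerates all n! relabelings (identity
    included) instead of sampling; otherwise p = (#{r_perm >= r_obs} + 1) /
    (n_perm + 1) for the 'greater' tail, with the analogous counts for
    'less' and 'two-sided'.
    """
    if set(a.ids) != set(b.ids):
        raise ValueError("RDMs must cover the same items")
    if a.n < 4:
        raise ValueError("Mantel test needs at least 4 items")
    b = b.reordered(a.ids)
    A, B = a.values, b.values
    n = a.n
    vb = _triangle(B)

    def corr_for(perm: np.ndarray) -> float:
        va = _triangle(A[np.ix_(perm, perm)])
        ok = np.isfinite(va) & np.isfinite(vb)
        return spearman(va[ok], vb[ok])

    r_obs = corr_for(np.arange(n))

    if exact:
        rs = np.array([corr_for(np.array(p)) for p in iter_permutations(range(n))])
        n_used = len(rs)
        if tail == "greater":
            count = np.sum(rs >= r_obs - 1e-12)
        elif tail == "less":
            count = np.sum(rs <= r_obs + 1e-12)
        elif tail == "two-sided":
            count = np.sum(np.abs(rs) >= abs(r_obs) - 1e-12)
        else:
            raise ValueError(f"unknown tail {tail!r}")
        p = count / n_used
        return MantelResult(r_obs, float(p), n_used, None, tail, n, len(vb))

    rng = np.random.default_rng(seed)
    rs = np.empty(n_perm)
    for i in range(n_perm):
        rs[i] = corr_for(rng.permutation(n))
    if tail == "greater":
        count = np.sum(rs >= r_obs - 1e-12)
    elif tail == "less":
        count = np.sum(rs <= r_obs + 1e-12)
    elif tail == "two-sided":
        count = np.sum(np.abs(rs) >= abs(r_obs) - 1e-12)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    p = (count + 1.0) / (n_perm + 1.0)
    return MantelResult(float(r_obs), float(p), n_perm, seed, tail, n, len(vb))


def mantel_difference_test(
    ratings_a: pd.DataFrame,
    ratings_b: pd.DataFrame,
    reference: RDM,
    stimuli: pd.DataFrame | None = None,
    level: str = "exemplar",
    n_perm: int = 999,
    seed: int | None = 0,
) -> tuple[float, float]:
    """Permutation test for a difference in Mantel correspondence.

    Observed statistic: delta_r = r(RDM_A, ref) - r(RDM_B, ref).  The null
    reassigns participants at random between the two groups (sizes
    preserved), rebuilds both RDMs and recomputes delta_r; the p-value is
    two-sided: (#{|delta_perm| >= |delta_obs|} + 1) / (n_perm + 1).
    """
    items_a, blocks_a = _participant_blocks(ratings_a, stimuli, level)
    items_b, blocks_b = _participant_blocks(ratings_b, stimuli, level)
    if items_a != items_b:
        raise ValueError("both groups must rate the same items")
    if len(blocks_a) < 2 or len(blocks_b) < 2:
        raise ValueError("each group needs at least 2 participants")
    ref = reference.reordered(items_a) if reference.ids != items_a else reference
    vref = _triangle(ref.values)
    ok_ref = np.isfinite(vref)

    pool = [blocks_a[p] for p in sorted(blocks_a)] + [
        blocks_b[p] for p in sorted(blocks_b)
    ]
    n_a = len(blocks_a)
    n_tot = len(pool)

    def delta_for(order: np.ndarray) -> float:
        ga = np.hstack([pool[i] for i in order[:n_a]])
        gb = np.hstack([pool[i] for i in order[n_a:]])
        ra = 1.0 - spearman_matrix(ga)
        rb = 1.0 - spearman_matrix(gb)
        va, vb2 = _triangle(ra), _triangle(rb)
        ok_a = ok_ref & np.isfinite(va)
        ok_b = ok_ref & np.isfinite(vb2)
        return spearman(va[ok_a], vref[ok_a]) - spearman(vb2[ok_b], vref[ok_b])

    d_obs = delta_for(np.arange(n_tot))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if abs(delta_for(rng.permutation(n_tot))) >= abs(d_obs) - 1e-12:
            count += 1
    p = (count + 1.0) / (n_perm + 1.0)
    return float(d_obs), float(p)


# ---------------------------------------------------------------------------
# clustering and QC

def ward_cluster(points: np.ndarray, ids: list[str], k: int = 5) -> ClusterResult:
    """Ward.D2 agglomeration on Euclidean distances, cut at ``k`` clusters."""
    points = np.asarray(points, dtype=float)
    if len(points) < k:
        raise ValueError("need at least k points")
    z = linkage(points, method="ward")
    labels = fcluster(z, t=k, criterion="maxclust")
    return ClusterResult(list(ids), labels, z, k)


def cluster_agreement(labels, reference_labels) -> float:
    """Adjusted Rand index between two partitions of the same items."""
    labels = np.asarray(labels)
    reference_labels = np.asarray(reference_labels)
    if labels.shape != reference_labels.shape:
        raise ValueError("partitions must cover the same items")
    return float(adjusted_rand_score(reference_labels, labels))


def detect_inattention(
    triplets: pd.DataFrame,
    run_threshold: int = 14,
    rt_threshold_ms: float = 350.0,
    rt_window: int = 10,
) -> pd.DataFrame:
    """Per-participant response-quality report for the triplet task.

    A participant is flagged when any same-side choice run exceeds
    ``run_threshold`` trials, or when every RT inside a sliding window of
    ``rt_window`` consecutive trials falls below ``rt_threshold_ms``
    ("consistently fast").  Trials are ordered by the ``trial`` column when
    present, otherwise by row order.
    """
    rows = []
    for pid, grp in triplets.groupby("participant_id", sort=True):
        if "trial" in grp.columns:
            grp = grp.sort_values("trial")
        sides = grp["chosen_side"].to_numpy()
        rts = grp["rt_ms"].to_numpy(dtype=float)
        max_run = run = 1
        for i in range(1, len(sides)):
            run = run + 1 if sides[i] == sides[i - 1] else 1
            max_run = max(max_run, run)
        fast = rts < rt_threshold_ms
        window_fast = False
        if len(fast) >= rt_window:
            csum = np.concatenate([[0], np.cumsum(fast)])
            window_fast = bool(
                np.any(csum[rt_window:] - csum[:-rt_window] == rt_window)
            )
        rows.append(
            {
                "participant_id": pid,
                "max_same_side_run": int(max_run),
                "n_fast": int(fast.sum()),
                "frac_fast": float(fast.mean()) if len(fast) else 0.0,
                "flag_side_run": bool(max_run > run_threshold),
                "flag_fast_window": window_fast,
                "flagged": bool(max_run > run_threshold or window_fast),
            }
        )
    return pd.DataFrame(rows)
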