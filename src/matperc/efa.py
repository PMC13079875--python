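"""Maximum-likelihood exploratory factor analysis with varimax rotation.

The model expresses the correlation matrix of the five attribute ratings
as ``Sigma = Lambda Lambda' + Psi`` with diagonal uniquenesses Psi.  The
fit follows the classic profile-likelihood approach: for fixed Psi the
conditional ML loadings come from the eigendecomposition of
``Psi^{-1/2} S Psi^{-1/2}``, leaving the discrepancy

    F(Psi) = sum_{j > k} (theta_j - log theta_j - 1)

over the trailing eigenvalues to be minimized over log-uniquenesses
(L-BFGS-B, with a Heywood floor of 0.005 on each uniqueness).  Varimax is
the standard Kaiser pairwise-rotation sweep; factor scores are Thomson
regression scores ``Z S^{-1} Lambda``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .materials import ATTRIBUTES

UNIQUENESS_FLOOR = 0.005


@dataclass
class EFAResult:
    loadings: pd.DataFrame  # attributes x factors (rotated)
    uniquenesses: pd.Series
    variance_explained: np.ndarray  # per rotated factor, fraction of total
    scree_ratios: np.ndarray  # eigenvalues of S / p
    rotation: str
    row_scores: pd.DataFrame  # per observation row: factor scores + metadata
    exemplar_scores: pd.DataFrame  # mean factor scores per exemplar
    objective_trace: list = field(default_factory=list)
    converged: bool = True

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    def communalities(self) -> pd.Series:
        return (self.loadings**2).sum(axis=1)


def _ml_discrepancy(psi: np.ndarray, S: np.ndarray, k: int) -> float:
    d = 1.0 / np.sqrt(psi)
    theta = np.linalg.eigvalsh(S * np.outer(d, d))[::-1]
    tail = np.clip(theta[k:], 1e-10, None)
    return float(np.sum(tail - np.log(tail) - 1.0))


def _conditional_loadings(psi: np.ndarray, S: np.ndarray, k: int) -> np.ndarray:
    d = 1.0 / np.sqrt(psi)
    theta, vecs = np.linalg.eigh(S * np.outer(d, d))
    order = np.argsort(theta)[::-1]
    theta, vecs = theta[order], vecs[:, order]
    gain = np.sqrt(np.clip(theta[:k] - 1.0, 0.0, None))
    return np.sqrt(psi)[:, None] * vecs[:, :k] * gain[None, :]


def fit_ml_factors(
    S: np.ndarray, n_factors: int, max_iter: int = 500
) -> tuple[np.ndarray, np.ndarray, list, bool]:
    """ML loadings and uniquenesses for a correlation matrix.

    Returns (loadings, uniquenesses, objective trace, converged).  The
    objective trace holds the discrepancy at each accepted optimizer
    iterate (monotone non-increasing, i.e. likelihood non-decreasing).
    Raises on non-convergence, carrying the last objective value.
    """
    p = S.shape[0]
    k = n_factors
    # standard start: psi proportional to 1/diag(S^{-1})
    start = np.clip(1.0 - 0.5 * k / p, 0.1, 0.9) * np.ones(p)
    trace: list[float] = []

    def objective(log_psi: np.ndarray) -> float:
        return _ml_discrepancy(np.exp(log_psi), S, k)

    def callback(xk: np.ndarray) -> None:
        trace.append(objective(xk))

    res = minimize(
        objective,
        np.log(start),
        method="L-BFGS-B",
        bounds=[(np.log(UNIQUENESS_FLOOR), 0.0)] * p,
        callback=callback,
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-10},
    )
    if not res.success and res.status != 0:
        # L-BFGS-B status 1 = maxiter; treat a tiny final gradient as converged
        if not np.all(np.abs(res.jac) < 1e-5):
            raise RuntimeError(
                f"ML factor extraction did not converge "
                f"(last objective {res.fun:.6g}): {res.message}"
            )
    psi = np.exp(res.x)
    import warnings

    if np.any(psi <= UNIQUENESS_FLOOR * (1 + 1e-6)):
        warnings.warn("Heywood case: uniqueness clipped at floor 0.005", stacklevel=2)
    loadings = _conditional_loadings(psi, S, k)
    return loadings, psi, trace, True


def varimax(loadings: np.ndarray, max_sweeps: int = 100, tol: float = 1e-10):
    """Kaiser varimax rotation by pairwise planar rotations.

    Returns (rotated loadings, rotation matrix, criterion trace).  The
    criterion (variance of squared loadings per factor, summed) is
    non-decreasing across sweeps.
    """
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    R = np.eye(k)

    def criterion(M: np.ndarray) -> float:
        sq = M**2
        return float(np.sum(sq.var(axis=0)))

    trace = [criterion(L)]
    if k < 2:
        return L, R, trace
    for _ in range(max_sweeps):
        for i in range(k - 1):
            for j in range(i + 1, k):
                x, y = L[:, i], L[:, j]
                u = x**2 - y**2
                v = 2.0 * x * y
                a = u.sum()
                b = v.sum()
                c = (u**2 - v**2).sum()
                d = 2.0 * (u * v).sum()
                num = d - 2.0 * a * b / p
                den = c - (a**2 - b**2) / p
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-14:
                    continue
                rot = np.array(
                    [[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]]
                )
                L[:, [i, j]] = L[:, [i, j]] @ rot
                R[:, [i, j]] = R[:, [i, j]] @ rot
        trace.append(criterion(L))
        if trace[-1] - trace[-2] < tol:
            break
    # sign convention: make the largest-magnitude loading of each factor positive
    signs = np.sign(L[np.abs(L).argmax(axis=0), np.arange(L.shape[1])])
    signs[signs == 0] = 1.0
    L *= signs
    R *= signs
    return L, R, trace


def efa(
    ratings: pd.DataFrame,
    stimuli: pd.DataFrame,
    n_factors: int = 2,
    rotation: str = "varimax",
) -> EFAResult:
    """Participant-level ML EFA of the five attribute ratings.

    Observation rows are participant x stimulus records over the five
    attributes (z-scored per attribute).  Loadings are extracted by ML,
    varimax-rotated, and summarized as Thomson regression scores per row
    and mean scores per exemplar.
    """
    wide = ratings.pivot_table(
        index=["participant_id", "video_id"], columns="attribute", values="rating"
    ).reindex(columns=list(ATTRIBUTES))
    if wide.isna().any().any():
        raise ValueError("incomplete ratings: every row needs all 5 attributes")
    if len(wide) < 30:
        raise ValueError("EFA needs at least 30 observation rows")
    X = wide.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [a for a, s in zip(ATTRIBUTES, sd) if s == 0]
        raise ValueError(f"zero-variance attribute(s): {bad}")
    Z = (X - mu) / sd
    S = np.corrcoef(Z, rowvar=False)

    L, psi, trace, converged = fit_ml_factors(S, n_factors)
    if rotation == "varimax" and n_factors > 1:
        L, _, _ = varimax(L)
    elif rotation not in ("varimax", "none"):
        raise ValueError(f"unknown rotation {rotation!r}")

    p = S.shape[0]
    var_explained = (L**2).sum(axis=0) / p
    scree = np.linalg.eigvalsh(S)[::-1] / p

    scores = Z @ np.linalg.solve(S, L)  # Thomson regression scores
    factor_cols = [f"factor{i + 1}" for i in range(n_factors)]
    row_scores = pd.DataFrame(scores, columns=factor_cols, index=wide.index).reset_index()
    mapping = stimuli.set_index("video_id")["exemplar"]
    row_scores["exemplar"] = row_scores["video_id"].map(mapping)
    exemplar_scores = (
        row_scores.groupby("exemplar", sort=True)[factor_cols].mean().reset_index()
    )

    return EFAResult(
        loadings=pd.DataFrame(L, index=list(ATTRIBUTES), columns=factor_cols),
        uniquenesses=pd.Series(psi, index=list(ATTRIBUTES)),
        variance_explained=var_explained,
        scree_ratios=scree,
        rotation=rotation,
        row_scores=row_scores,
        exemplar_scores=exemplar_scores,
        objective_trace=trace,
        converged=converged,
    )
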