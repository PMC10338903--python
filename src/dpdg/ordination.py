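"""Ordination diagnostics: 3D Kruskal nonmetric MDS and Procrustes
superimposition.

NMDS minimizes Kruskal's stress-1, sqrt(sum (dhat - d)^2 / sum d^2), over
low-dimensional configurations, where d are configuration distances and
dhat the isotonic regression of d on the rank order of the input
dissimilarities (pool-adjacent-violators; primary tie treatment).  The
optimizer is iterated majorization (SMACOF/Guttman transform) from several
random starts plus a classical-scaling warm start, reporting the best
configuration.  Stress below 0.15 is conventionally acceptable for
interpreting the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform
from sklearn.isotonic import IsotonicRegression

from .types import DataError, DistanceMatrix


@dataclass
class OrdinationResult:
    population_ids: list[str]
    coordinates: np.ndarray  # m x k
    stress: float
    n_restarts: int
    seed: int
    history: list[float] | None = None  # per-iteration stress of the best restart


def _classical_scaling(D: np.ndarray, k: int) -> np.ndarray:
    """Torgerson double-centering start (metric principal coordinates)."""
    m = D.shape[0]
    J = np.eye(m) - np.ones((m, m)) / m
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:k]
    w = np.clip(w[order], 0.0, None)
    return V[:, order] * np.sqrt(w)


def _stress1(d: np.ndarray, dhat: np.ndarray) -> float:
    denom = float((d**2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d - dhat) ** 2).sum() / denom))


def _isotonic_disparities(d: np.ndarray, order_primary: np.ndarray) -> np.ndarray:
    """Monotone (PAVA) fit of configuration distances to the dissimilarity
    rank order.  ``order_primary`` sorts by dissimilarity with ties broken
    by the current distances (Kruskal's primary approach: no constraint
    within tie blocks)."""
    iso = IsotonicRegression(increasing=True)
    fitted = iso.fit_transform(np.arange(len(d), dtype=float), d[order_primary])
    dhat = np.empty_like(d)
    dhat[order_primary] = fitted
    return dhat


def nmds(
    D: DistanceMatrix,
    n_components: int = 3,
    seed: int = 0,
    n_restarts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-7,
) -> OrdinationResult:
    """Best-of-restarts Kruskal NMDS of a distance matrix."""
    m = D.n
    if m < n_components + 2:
        raise DataError("too few populations for the requested dimensionality")
    delta = squareform(D.values, checks=False)
    npairs = len(delta)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    iu, ju = np.triu_indices(m, k=1)

    def run(X0: np.ndarray) -> tuple[np.ndarray, float, list[float]]:
        X = X0.copy()
        diff = X[iu] - X[ju]
        d = np.sqrt((diff**2).sum(axis=1))
        prev = np.inf
        stress = np.inf
        history: list[float] = []
        for _ in range(max_iter):
            order = np.lexsort((d, delta))
            dhat = _isotonic_disparities(d, order)
            # Kruskal's normalization keeps the disparity scale tied to the
            # configuration scale
            ssq = (dhat**2).sum()
            if ssq > 0:
                dhat = dhat * np.sqrt((d**2).sum() / ssq)
            stress = _stress1(d, dhat)
            history.append(stress)
            if prev - stress < tol:
                break
            prev = stress
            # Guttman transform
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(d > 0, dhat / d, 0.0)
            B = np.zeros((m, m))
            B[iu, ju] = -ratio
            B[ju, iu] = -ratio
            np.fill_diagonal(B, -B.sum(axis=1))
            X = B @ X / m
            X -= X.mean(axis=0)
            diff = X[iu] - X[ju]
            d = np.sqrt((diff**2).sum(axis=1))
        return X, stress, history

    best_X, best_stress, best_hist = run(_classical_scaling(D.values, n_components))
    for _ in range(n_restarts):
        X0 = rng.normal(size=(m, n_components))
        X, s, hist = run(X0)
        if s < best_stress:
            best_X, best_stress, best_hist = X, s, hist
    return OrdinationResult(
        list(D.ids), best_X, best_stress, n_restarts, seed, history=best_hist
    )


def nmds_3d(
    D: DistanceMatrix, seed: int = 0, n_restarts: int = 20, max_iter: int = 500, tol: float = 1e-7
) -> OrdinationResult:
    """Three-dimensional Kruskal NMDS (the standard visualization space)."""
    return nmds(D, n_components=3, seed=seed, n_restarts=n_restarts, max_iter=max_iter, tol=tol)


def stress_gate(result: OrdinationResult, threshold: float = 0.15) -> tuple[bool, str]:
    """Pass iff stress is strictly below the acceptability threshold."""
    ok = result.stress < threshold
    word = "below" if ok else "not below"
    return ok, (
        f"stress {result.stress:.4f} is {word} the acceptable threshold of {threshold}"
    )


def procrustes_superimpose(
    target: np.ndarray, source: np.ndarray
) -> tuple[np.ndarray, float]:
    """Least-squares superimposition of ``source`` onto ``target``.

    Centers both configurations, then finds the scale s and orthogonal
    matrix Q (rotations and reflections; NMDS axes have arbitrary
    chirality) minimizing ||target - s * source Q||^2.  Returns the
    transformed source (translated to the target centroid) and the residual
    sum of squares.
    """
    A = np.asarray(target, float)
    B = np.asarray(source, float)
    if A.shape != B.shape:
        raise DataError("configurations must share shape (same populations, same dimension)")
    muA = A.mean(axis=0)
    muB = B.mean(axis=0)
    Ac = A - muA
    Bc = B - muB
    M = Bc.T @ Ac
    U, svals, Vt = np.linalg.svd(M)
    Q = U @ Vt
    denom = float((Bc**2).sum())
    if denom == 0:
        raise DataError("source configuration is degenerate (all points equal)")
    scale = float(svals.sum()) / denom
    aligned = scale * Bc @ Q + muA
    rss = float(((Ac - scale * Bc @ Q) ** 2).sum())
    return aligned, rss
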