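"""Independent oracle implementations used only by the tests.

These are deliberately written as plain, loop-based transcriptions of the
underlying definitions (multi-allele variance components, exhaustive
nearest-neighbour search, closed-form partial correlation, grid-search
Procrustes) so they share no code path with the package.
"""

from __future__ import annotations

import numpy as np


def wc84_fst_locus_oracle(pop1, pop2) -> float:
    """Two-population, single-locus Weir-Cockerham F_ST via the general
    multi-allele variance components, summing components over both alleles.

    ``pop1``/``pop2`` are sequences of observed diploid genotypes coded as
    reference-allele counts (0/1/2).  Returns NaN when the estimate is
    undefined.
    """
    samples = [list(pop1), list(pop2)]
    r = 2
    n = [len(s) for s in samples]
    if min(n) < 1:
        raise ValueError("each population needs at least one genotype")
    nbar = sum(n) / r
    if nbar <= 1:
        return float("nan")
    nc = (sum(n) - sum(x * x for x in n) / sum(n)) / (r - 1)
    a_sum = 0.0
    d_sum = 0.0
    for allele in ("ref", "alt"):
        p, h = [], []
        for s in samples:
            g = np.asarray(s, float)
            p_ref = g.mean() / 2.0
            p.append(p_ref if allele == "ref" else 1.0 - p_ref)
            h.append(float(np.mean(g == 1)))
        pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
        s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
        hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
        a_sum += a
        d_sum += a + b + c
    if d_sum <= 0:
        return float("nan")
    return a_sum / d_sum


def pairwise_fst_loop_oracle(geno) -> np.ndarray:
    """Literal per-pair, per-locus loop over a GenotypeMatrix: average of
    defined per-locus oracle estimates."""
    pops = geno.populations
    idx = geno.pop_indices()
    K = len(pops)
    out = np.zeros((K, K))
    for i in range(K):
        for j in range(i + 1, K):
            vals = []
            for locus in range(geno.n_loci):
                g1 = [g for g in geno.genotypes[idx[pops[i]], locus] if g >= 0]
                g2 = [g for g in geno.genotypes[idx[pops[j]], locus] if g >= 0]
                if not g1 or not g2:
                    continue
                f = wc84_fst_locus_oracle(g1, g2)
                if not np.isnan(f):
                    vals.append(f)
            out[i, j] = out[j, i] = float(np.mean(vals))
    return out


def knn_impute_oracle(values: np.ndarray, k: int = 5) -> np.ndarray:
    """Exhaustive-search kNN imputation on a standardized copy.

    For each missing cell: candidates are other rows with that variable
    observed; distance is Euclidean over shared observed variables scaled
    by sqrt(n_vars / n_shared); the imputed value is the mean of the k
    nearest candidates' values (ties by row order).
    """
    x = np.array(values, float)
    mu = np.nanmean(x, axis=0)
    sd = np.nanstd(x, axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    z = (x - mu) / sd
    n, t = z.shape
    out = x.copy()
    for i in range(n):
        for j in range(t):
            if not np.isnan(x[i, j]):
                continue
            dists = []
            for other in range(n):
                if other == i or np.isnan(x[other, j]):
                    continue
                shared = ~np.isnan(z[i]) & ~np.isnan(z[other])
                if not shared.any():
                    continue
                d2 = ((z[i, shared] - z[other, shared]) ** 2).sum()
                dists.append((np.sqrt(t / shared.sum() * d2), other))
            dists.sort(key=lambda pair: pair[0])
            donors = [o for _, o in dists[:k]]
            out[i, j] = np.mean([z[o, j] for o in donors]) * sd[j] + mu[j]
    return out


def partial_corr_closed_form(x, y, z) -> float:
    """Textbook single-covariate partial correlation identity."""
    rxy = np.corrcoef(x, y)[0, 1]
    rxz = np.corrcoef(x, z)[0, 1]
    ryz = np.corrcoef(y, z)[0, 1]
    return (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))


def procrustes_2d_oracle(target: np.ndarray, source: np.ndarray) -> float:
    """Minimum residual sum of squares for superimposing a 2D source onto a
    2D target, by scanning the rotation angle (both chiralities) with
    golden-section refinement and solving the scale analytically."""
    from scipy.optimize import minimize_scalar

    A = target - target.mean(axis=0)
    B = source - source.mean(axis=0)
    bb = (B**2).sum()

    def rss(theta: float, reflect: bool) -> float:
        c, s = np.cos(theta), np.sin(theta)
        Q = np.array([[c, -s], [s, c]])
        if reflect:
            Q = Q @ np.array([[1.0, 0.0], [0.0, -1.0]])
        BQ = B @ Q
        scale = max((BQ * A).sum() / bb, 0.0)
        return float(((A - scale * BQ) ** 2).sum())

    best = np.inf
    for reflect in (False, True):
        coarse = min(
            np.linspace(0, 2 * np.pi, 721), key=lambda th: rss(th, reflect)
        )
        res = minimize_scalar(
            lambda th: rss(th, reflect),
            bounds=(coarse - 0.02, coarse + 0.02),
            method="bounded",
            options={"xatol": 1e-12},
        )
        best = min(best, res.fun)
    return best
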