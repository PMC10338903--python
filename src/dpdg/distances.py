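"""Between-population distance matrices.

Implements the six distances the neutrality comparison needs:

* Weir-Cockerham (1984) F_ST from biallelic SNP genotypes, estimated per
  locus from the method-of-moments variance components and averaged over
  loci for each population pair;
* metric Mahalanobis D^2 between per-variable geometric means, adjusted by
  a pooled within-population variance-covariance matrix;
* nonmetric Mahalanobis D^2 between probit thresholds of binary trait
  frequencies, adjusted by a pooled Pearson correlation matrix weighted by
  pairwise trait sample sizes;
* the combined craniodental D^2 (variable-count weighted average of block
  D^2 matrices);
* an optional model-bound P_ST;
* climate (Euclidean over five temperature variables) and geodesic
  (haversine great-circle) distances between population environments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .preprocess import TraitFrequencyTable, trait_frequencies
from .types import (
    GENO_MISSING,
    MODE_BINARY,
    MODE_METRIC,
    DataError,
    DistanceMatrix,
    GenotypeMatrix,
    PhenotypeTable,
    PopulationMetadata,
)

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST


@dataclass
class AlleleStats:
    """Per-population, per-locus sufficient statistics for WC84.

    ``n``: diploid sample sizes (genotyped individuals), ``p``: reference
    allele frequencies, ``h``: observed heterozygote frequencies; all arrays
    are populations x loci.  Supports O(loci) removal of single individuals,
    which the resampler uses to avoid re-aggregating the genotype matrix on
    every jackknife iteration.
    """

    populations: list[str]
    n: np.ndarray
    allele_sum: np.ndarray
    het_count: np.ndarray

    @classmethod
    def from_genotypes(cls, geno: GenotypeMatrix) -> "AlleleStats":
        g = geno.genotypes
        observed = g != GENO_MISSING
        gvals = np.where(observed, g, 0)
        het = g == 1
        pops = geno.populations
        idx = geno.pop_indices()
        K, L = len(pops), geno.n_loci
        n = np.empty((K, L))
        s = np.empty((K, L))
        h = np.empty((K, L))
        for k, p in enumerate(pops):
            rows = idx[p]
            n[k] = observed[rows].sum(axis=0)
            s[k] = gvals[rows].sum(axis=0)
            h[k] = het[rows].sum(axis=0)
        return cls(pops, n, s, h)

    def drop(self, pop_rows: dict[str, np.ndarray], geno: GenotypeMatrix) -> "AlleleStats":
        """Return stats with the given individual rows (grouped by their
        population) subtracted from the aggregates."""
        n = self.n.copy()
        s = self.allele_sum.copy()
        h = self.het_count.copy()
        g = geno.genotypes
        for pop, rows in pop_rows.items():
            k = self.populations.index(pop)
            for r in np.atleast_1d(rows):
                row = g[r]
                obs = row != GENO_MISSING
                n[k] -= obs
                s[k] -= np.where(obs, row, 0)
                h[k] -= row == 1
        return AlleleStats(list(self.populations), n, s, h)

    def select(self, pops: list[str], loci: np.ndarray | None = None) -> "AlleleStats":
        rows = [self.populations.index(p) for p in pops]
        cols = slice(None) if loci is None else np.asarray(loci)
        return AlleleStats(
            list(pops),
            self.n[rows][:, cols],
            self.allele_sum[rows][:, cols],
            self.het_count[rows][:, cols],
        )


def _wc_components(n1, p1, h1, n2, p2, h2):
    """WC84 variance components a, b, c for two samples at biallelic loci.

    Vectorised over loci (or pairs x loci).  Entries where either sample has
    no genotyped individuals, or where nbar <= 1, are returned as NaN.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        nbar = (n1 + n2) / 2.0
        r = 2.0
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        inner = pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2
        a = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (inner - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0
    invalid = (n1 < 1) | (n2 < 1) | (nbar <= 1) | ~np.isfinite(nc) | (nc <= 0)
    for arr in (a, b, c):
        arr[invalid] = np.nan
    return a, b, c


def wc_fst_locus(geno: GenotypeMatrix, locus: str) -> float:
    """Single-locus Weir-Cockerham F_ST between exactly two populations.

    Returns ``a / (a + b + c)``; NaN flags an undefined estimate (both
    samples monomorphic, or too few genotyped individuals).
    """
    pops = geno.populations
    if len(pops) != 2:
        raise DataError("wc_fst_locus expects exactly two populations")
    stats = AlleleStats.from_genotypes(geno)
    j = geno.locus_ids.index(locus)
    n = stats.n[:, j]
    if (n < 1).any():
        raise DataError(f"a population has zero genotyped individuals at locus {locus!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        p = stats.allele_sum[:, j] / (2.0 * n)
        h = stats.het_count[:, j] / n
    a, b, c = _wc_components(
        np.array([n[0]]), np.array([p[0]]), np.array([h[0]]),
        np.array([n[1]]), np.array([p[1]]), np.array([h[1]]),
    )
    denom = a + b + c
    if not np.isfinite(denom[0]) or denom[0] <= 0:
        return float("nan")
    return float(a[0] / denom[0])


def pairwise_fst_from_stats(
    stats: AlleleStats, aggregation: str = "average_of_ratios"
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise multi-locus F_ST from allele statistics.

    Returns ``(fst, excluded)`` where ``fst[i, j]`` is the per-pair average
    over loci with a defined estimate and ``excluded[i, j]`` counts the loci
    excluded for that pair (monomorphic / undersampled).  ``aggregation``
    is ``"average_of_ratios"`` (mean of per-locus a/(a+b+c), the default) or
    ``"ratio_of_sums"`` (sum a / sum (a+b+c), for sensitivity analysis).
    """
    if aggregation not in ("average_of_ratios", "ratio_of_sums"):
        raise DataError(f"unknown F_ST aggregation {aggregation!r}")
    K, L = stats.n.shape
    with np.errstate(divide="ignore", invalid="ignore"):
        p = stats.allele_sum / (2.0 * stats.n)
        h = stats.het_count / stats.n
    iu, ju = np.triu_indices(K, k=1)
    a, b, c = _wc_components(
        stats.n[iu], p[iu], h[iu], stats.n[ju], p[ju], h[ju]
    )
    denom = a + b + c
    defined = np.isfinite(denom) & (denom > 0)
    fst_pair = np.full(len(iu), np.nan)
    n_def = defined.sum(axis=1)
    if aggregation == "average_of_ratios":
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(defined, a / denom, 0.0)
        ok = n_def > 0
        fst_pair[ok] = ratio[ok].sum(axis=1) / n_def[ok]
    else:
        num = np.where(defined, a, 0.0).sum(axis=1)
        den = np.where(defined, denom, 0.0).sum(axis=1)
        ok = (n_def > 0) & (den > 0)
        fst_pair[ok] = num[ok] / den[ok]
    fst = np.zeros((K, K))
    excl = np.zeros((K, K), dtype=int)
    fst[iu, ju] = fst_pair
    fst[ju, iu] = fst_pair
    excl[iu, ju] = L - n_def
    excl[ju, iu] = L - n_def
    return fst, excl


def wc_fst_matrix(
    geno: GenotypeMatrix,
    aggregation: str = "average_of_ratios",
    return_excluded: bool = False,
):
    """Pairwise Weir-Cockerham F_ST matrix, averaged over loci per pair."""
    pops = geno.populations
    if len(pops) < 2:
        raise DataError("F_ST needs at least two populations")
    stats = AlleleStats.from_genotypes(geno)
    fst, excl = pairwise_fst_from_stats(stats, aggregation=aggregation)
    iu, ju = np.triu_indices(len(pops), k=1)
    if np.isnan(fst[iu, ju]).any():
        i = int(iu[np.isnan(fst[iu, ju])][0])
        j = int(ju[np.isnan(fst[iu, ju])][0])
        raise DataError(
            f"no defined locus for population pair ({pops[i]}, {pops[j]})"
        )
    D = DistanceMatrix(pops, fst, is_fst=True)
    if return_excluded:
        return D, pd.DataFrame(excl, index=pops, columns=pops)
    return D


# ---------------------------------------------------------------------------
# Mahalanobis D^2


def mahalanobis_matrix(means: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Pairwise quadratic form (X_i - X_j)' S^-1 (X_i - X_j).

    Raises :class:`DataError` when S is singular (no silent regularisation).
    """
    S = np.asarray(S, float)
    means = np.asarray(means, float)
    try:
        L = np.linalg.cholesky(S)
    except np.linalg.LinAlgError as exc:
        raise DataError(
            "pooled scatter matrix is singular; reduce the number of variables"
        ) from exc
    w = np.linalg.eigvalsh(S)
    if w[0] <= 1e-12 * max(w[-1], 1.0):
        raise DataError(
            "pooled scatter matrix is numerically singular; reduce the number of variables"
        )
    Y = np.linalg.solve(L, means.T).T  # whitened means
    diff = Y[:, None, :] - Y[None, :, :]
    D2 = np.einsum("ijk,ijk->ij", diff, diff)
    D2 = (D2 + D2.T) / 2.0
    np.fill_diagonal(D2, 0.0)
    return D2


def _gmean_by_population(table: PhenotypeTable) -> tuple[np.ndarray, np.ndarray, list[str]]:
    vals = table.data.to_numpy(float)
    if np.isnan(vals).any():
        raise DataError("metric D^2 requires a complete (imputed) table")
    if (vals <= 0).any():
        raise DataError("metric D^2 requires strictly positive measurements")
    pops = table.populations
    idx = table.pop_indices()
    gm = np.empty((len(pops), vals.shape[1]))
    n = np.empty(len(pops), dtype=int)
    logs = np.log(vals)
    for k, p in enumerate(pops):
        rows = idx[p]
        gm[k] = np.exp(logs[rows].mean(axis=0))
        n[k] = len(rows)
    return gm, n, pops


def metric_d2(table: PhenotypeTable) -> DistanceMatrix:
    """Mahalanobis D^2 for metric data.

    Population mean vectors are per-variable geometric means; the pooled
    within-population scatter S is the sample-size weighted average of the
    per-population covariance matrices, with n_i - 1 weights (each S_i is
    the unbiased per-population covariance).
    """
    if table.mode != MODE_METRIC:
        raise DataError("metric_d2 expects a metric table")
    gm, n, pops = _gmean_by_population(table)
    vals = table.data.to_numpy(float)
    idx = table.pop_indices()
    T = vals.shape[1]
    if int(n.sum()) <= T:
        raise DataError("total sample size must exceed the number of variables")
    S = np.zeros((T, T))
    wsum = 0.0
    for p in pops:
        rows = idx[p]
        if len(rows) < 2:
            continue
        x = vals[rows]
        S += (len(rows) - 1) * np.cov(x, rowvar=False, ddof=1)
        wsum += len(rows) - 1
    if wsum <= 0:
        raise DataError("no population with at least two individuals")
    S /= wsum
    return DistanceMatrix(pops, mahalanobis_matrix(gm, S))


def _pairwise_corr_with_missing(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation matrix over columns, pairwise-complete, plus the
    pairwise complete-observation counts.  Zero-variance pairs give NaN."""
    m = ~np.isnan(x)
    xz = np.where(m, x, 0.0)
    n = m.T.astype(float) @ m.astype(float)
    sx = xz.T @ m.astype(float)
    sxx = (xz**2).T @ m.astype(float)
    sxy = xz.T @ xz
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_x = sx / n
        mean_y = mean_x.T
        cov = sxy / n - mean_x * mean_y
        var_x = sxx / n - mean_x**2
        var_y = var_x.T
        r = cov / np.sqrt(var_x * var_y)
    r[~np.isfinite(r)] = np.nan
    return r, n


def pooled_binary_correlation(binary: PhenotypeTable) -> np.ndarray:
    """Pooled Pearson correlation matrix of binary trait indicators.

    Entry (j, k) is the average of the per-population correlations weighted
    by that population's pairwise complete-observation count n_jk.
    Populations where a trait has zero variance contribute nothing to the
    entries involving that trait.  The diagonal is 1 by definition.
    """
    T = len(binary.variable_ids)
    num = np.zeros((T, T))
    wsum = np.zeros((T, T))
    vals = binary.data.to_numpy(float)
    idx = binary.pop_indices()
    for p in binary.populations:
        x = vals[idx[p]]
        r, n = _pairwise_corr_with_missing(x)
        ok = np.isfinite(r)
        num[ok] += (r * n)[ok]
        wsum[ok] += n[ok]
    with np.errstate(divide="ignore", invalid="ignore"):
        S = num / wsum
    S[~np.isfinite(S)] = 0.0
    np.fill_diagonal(S, 1.0)
    S = (S + S.T) / 2.0
    return S


def probit_thresholds(freqs: TraitFrequencyTable) -> np.ndarray:
    """Standard-normal quantiles of trait frequencies.

    The Anscombe-style continuity adjustment p~ = (n p + 0.5) / (n + 1) is
    applied only where p is exactly 0 or 1, keeping thresholds finite while
    converging to p as n grows.
    """
    p = freqs.p.copy()
    n = freqs.n.astype(float)
    if np.isnan(p).any():
        k, t = np.argwhere(np.isnan(p))[0]
        raise DataError(
            f"trait {freqs.traits[t]!r} unobserved in population {freqs.populations[k]!r}"
        )
    edge = (p == 0.0) | (p == 1.0)
    p = np.where(edge, (n * p + 0.5) / (n + 1.0), p)
    return norm.ppf(p)


def nonmetric_d2(freqs: TraitFrequencyTable, binary: PhenotypeTable) -> DistanceMatrix:
    """Probit-threshold Mahalanobis D^2 for nonmetric (binary) traits.

    Mean vectors are probit thresholds of trait frequencies; S is the pooled
    Pearson correlation matrix of the binary indicators weighted by pairwise
    sample sizes.
    """
    if binary.mode != MODE_BINARY:
        raise DataError("nonmetric_d2 expects a binary table for S")
    observed_pops = (freqs.n > 0).sum(axis=0)
    few = np.flatnonzero(observed_pops < 2)
    if few.size:
        raise DataError(f"trait {freqs.traits[few[0]]!r} observed in fewer than two populations")
    X = probit_thresholds(freqs)
    S = pooled_binary_correlation(binary)
    return DistanceMatrix(list(freqs.populations), mahalanobis_matrix(X, S))


def block_d2(table: PhenotypeTable) -> DistanceMatrix:
    """D^2 for one phenotype block, dispatching on its mode."""
    if table.mode == MODE_METRIC:
        return metric_d2(table)
    if table.mode == MODE_BINARY:
        return nonmetric_d2(trait_frequencies(table), table)
    raise DataError("block_d2 expects a metric or binary table (dichotomize first)")


def combined_d2(matrices: list[DistanceMatrix], n_vars: list[int]) -> DistanceMatrix:
    """Element-wise weighted average of block D^2 matrices.

    Weights are the per-block variable counts; matrices are aligned by label
    to the first matrix's population order.
    """
    if len(matrices) != len(n_vars) or not matrices:
        raise DataError("need one weight per distance matrix")
    if any(w <= 0 for w in n_vars):
        raise DataError("variable counts must be positive")
    order = matrices[0].ids
    total = np.zeros((len(order), len(order)))
    for D, w in zip(matrices, n_vars):
        if set(D.ids) != set(order):
            raise DataError("combined_d2: population labels differ between matrices")
        total += w * D.align(order).values
    return DistanceMatrix(list(order), total / float(sum(n_vars)))


# ---------------------------------------------------------------------------
# P_ST (optional, model-bound)


@dataclass
class PstConfig:
    """Heritability and relative effective sizes for model-bound P_ST."""

    h2: float = 1.0
    relative_ne: dict[str, float] | None = None

    def weight(self, pop: str) -> float:
        if self.relative_ne is None:
            return 1.0
        return float(self.relative_ne[pop])


def pst_matrix(table: PhenotypeTable, config: PstConfig) -> DistanceMatrix:
    """Model-bound P_ST = sigma2_B / (sigma2_B + 2 h2 sigma2_W), averaged
    over traits.

    sigma2_B is the between-pair variance of the two population means
    (weighted by relative N_e), sigma2_W the pooled within-population
    variance.  This is a documented standard P_ST formulation and is flagged
    provisional: model-bound comparisons additionally require externally
    validated N_e and h2 estimates.
    """
    if not 0 < config.h2 <= 1:
        raise DataError("P_ST heritability must be in (0, 1]")
    vals = table.data.to_numpy(float)
    if np.isnan(vals).any():
        raise DataError("P_ST requires a complete table")
    pops = table.populations
    idx = table.pop_indices()
    means = np.array([vals[idx[p]].mean(axis=0) for p in pops])
    ssw = 0.0
    dof = 0
    for p in pops:
        x = vals[idx[p]]
        if len(x) >= 2:
            ssw += ((x - x.mean(axis=0)) ** 2).sum(axis=0)
            dof += len(x) - 1
    sw2 = ssw / max(dof, 1)
    w = np.array([config.weight(p) for p in pops], float)
    if (w <= 0).any():
        raise DataError("relative N_e weights must be positive")
    K = len(pops)
    out = np.zeros((K, K))
    for i in range(K):
        for j in range(i + 1, K):
            wi, wj = w[i], w[j]
            mbar = (wi * means[i] + wj * means[j]) / (wi + wj)
            s2b = (wi * (means[i] - mbar) ** 2 + wj * (means[j] - mbar) ** 2) / (wi + wj)
            with np.errstate(divide="ignore", invalid="ignore"):
                pst = s2b / (s2b + 2.0 * config.h2 * sw2)
            pst = np.where(s2b + sw2 > 0, pst, 0.0)
            out[i, j] = out[j, i] = float(np.mean(pst))
    return DistanceMatrix(pops, out)


# ---------------------------------------------------------------------------
# climate and geography


def climate_distance(meta: PopulationMetadata, standardize: bool = False) -> DistanceMatrix:
    """Euclidean distance over the five temperature variables (raw degrees C
    by default; all five share units)."""
    x = meta.climate()
    if standardize:
        x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)
    diff = x[:, None, :] - x[None, :, :]
    d = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    return DistanceMatrix(meta.populations, d)


def geodesic_distance(meta: PopulationMetadata) -> DistanceMatrix:
    """Great-circle distance in km (haversine, spherical Earth R=6371 km)."""
    coords = np.radians(meta.coordinates())
    lat, lon = coords[:, 0], coords[:, 1]
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(meta.populations, d)
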