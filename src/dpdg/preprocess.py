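"""Phenotype preprocessing.

The standard craniodental cleaning sequence: drop individuals with more
than half of their variables missing, impute the remaining gaps with k
nearest neighbours, convert metric measurements to scale-free shape
variables by dividing each individual by its geometric mean (which also
absorbs size-related sexual dimorphism), merge bilateral nonmetric scores
by taking the side with the highest expression, dichotomize graded scores
at established breakpoints, and tabulate per-population trait frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .types import (
    MODE_BINARY,
    MODE_GRADED,
    MODE_METRIC,
    DataError,
    PhenotypeTable,
)


@dataclass
class PreprocessReport:
    dropped_individuals: list[str]
    n_imputed_cells: int
    imputed_fraction: float


def remove_sparse_individuals(
    table: PhenotypeTable, max_missing_frac: float = 0.5
) -> tuple[PhenotypeTable, list[str]]:
    """Drop rows with strictly more than ``max_missing_frac`` missing.

    A row with exactly half of its variables missing is retained ("more than
    half" is a strict inequality).  Returns the filtered table and the ids
    of the dropped individuals.
    """
    frac = table.data.isna().mean(axis=1)
    dropped = list(table.data.index[frac > max_missing_frac])
    if len(dropped) == len(table.data):
        raise DataError("all individuals exceed the missingness threshold")
    keep = table.data.index[frac <= max_missing_frac]
    return table.subset_individuals(keep), dropped


def knn_impute(table: PhenotypeTable, k: int = 5, standardize: bool = True) -> PhenotypeTable:
    """Replace each missing cell by the mean of the k most similar individuals.

    Similarity is Euclidean distance over the variables both individuals
    share, scaled up by the fraction of shared variables (so sparsely
    overlapping pairs are not spuriously close), computed after per-variable
    standardization.  Observed cells are never altered.
    """
    if k < 1:
        raise DataError("k must be >= 1")
    x = table.data.to_numpy(float)
    if not np.isnan(x).any():
        return table
    all_missing = np.isnan(x).all(axis=0)
    if all_missing.any():
        var = table.data.columns[np.flatnonzero(all_missing)[0]]
        raise DataError(f"variable {var!r} is missing in every individual")
    if standardize:
        mu = np.nanmean(x, axis=0)
        sd = np.nanstd(x, axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
    else:
        mu = np.zeros(x.shape[1])
        sd = np.ones(x.shape[1])
    z = (x - mu) / sd
    imputer = KNNImputer(n_neighbors=k, weights="uniform", metric="nan_euclidean")
    z_imp = imputer.fit_transform(z)
    if z_imp.shape[1] != x.shape[1]:
        raise DataError("imputer dropped a variable (all-missing column)")
    filled = z_imp * sd + mu
    out = np.where(np.isnan(x), filled, x)
    return replace(table, data=pd.DataFrame(out, index=table.data.index, columns=table.data.columns))


def size_correct(table: PhenotypeTable) -> PhenotypeTable:
    """Divide each individual's measurements by their geometric mean.

    Yields scale-free shape variables: every output row has geometric mean
    exactly 1 (to rounding), and the output is invariant to per-row
    rescaling of the input.
    """
    if table.mode != MODE_METRIC:
        raise DataError("size correction applies to metric tables")
    x = table.data.to_numpy(float)
    if np.isnan(x).any():
        i, j = np.argwhere(np.isnan(x))[0]
        raise DataError(
            f"size correction requires a complete table (missing at "
            f"{table.data.index[i]!r}/{table.data.columns[j]!r})"
        )
    bad = np.argwhere(x <= 0)
    if bad.size:
        i, j = bad[0]
        raise DataError(
            f"nonpositive measurement at {table.data.index[i]!r}/{table.data.columns[j]!r}"
        )
    gm = np.exp(np.log(x).mean(axis=1, keepdims=True))
    return replace(
        table, data=pd.DataFrame(x / gm, index=table.data.index, columns=table.data.columns)
    )


def merge_bilateral(left: pd.DataFrame, right: pd.DataFrame) -> pd.DataFrame:
    """Individual-count scoring of bilateral traits: per individual and
    trait, the side with the highest expression; missing only when both
    sides are missing."""
    if not left.index.equals(right.index) or list(left.columns) != list(right.columns):
        raise DataError("left and right score tables must share individuals and traits")
    return pd.DataFrame(
        np.fmax(left.to_numpy(float), right.to_numpy(float)),
        index=left.index,
        columns=left.columns,
    )


def dichotomize(table: PhenotypeTable, breakpoints: dict[str, float]) -> PhenotypeTable:
    """Collapse graded scores into presence/absence: grade >= breakpoint is
    present (1), below is absent (0); missing propagates."""
    if table.mode not in (MODE_GRADED, MODE_BINARY):
        raise DataError("dichotomize applies to nonmetric tables")
    missing_bp = [v for v in table.variable_ids if v not in breakpoints]
    if missing_bp:
        raise DataError(f"no breakpoint for variable {missing_bp[0]!r}")
    x = table.data.to_numpy(float)
    bp = np.array([breakpoints[v] for v in table.variable_ids], float)
    out = np.where(np.isnan(x), np.nan, (x >= bp).astype(float))
    return replace(
        table,
        data=pd.DataFrame(out, index=table.data.index, columns=table.data.columns),
        mode=MODE_BINARY,
    )


@dataclass
class TraitFrequencyTable:
    """Per-population binary trait frequencies and observation counts.

    ``p[k, t]``: frequency of presence (NaN where unobserved);
    ``n[k, t]``: number of scored individuals; ``n_pair[k, t, u]``: number
    of individuals scored for both traits t and u in population k (the
    pooled-correlation weights).
    """

    populations: list[str]
    traits: list[str]
    p: np.ndarray
    n: np.ndarray
    n_pair: np.ndarray


def trait_frequencies(binary: PhenotypeTable) -> TraitFrequencyTable:
    """Tabulate presence frequencies, counts and pairwise counts."""
    if binary.mode != MODE_BINARY:
        raise DataError("trait_frequencies expects a binary table")
    x = binary.data.to_numpy(float)
    obs = ~np.isnan(x)
    pops = binary.populations
    idx = binary.pop_indices()
    K, T = len(pops), x.shape[1]
    p = np.full((K, T), np.nan)
    n = np.zeros((K, T), dtype=int)
    n_pair = np.zeros((K, T, T), dtype=int)
    for k, pop in enumerate(pops):
        rows = idx[pop]
        o = obs[rows]
        cnt = o.sum(axis=0)
        n[k] = cnt
        with np.errstate(invalid="ignore"):
            pres = np.where(o, x[rows], 0.0).sum(axis=0)
            p[k] = np.where(cnt > 0, pres / np.maximum(cnt, 1), np.nan)
        n_pair[k] = o.T.astype(int) @ o.astype(int)
    return TraitFrequencyTable(pops, binary.variable_ids, p, n, n_pair)


def preprocess_metric(
    table: PhenotypeTable, k: int = 5, max_missing_frac: float = 0.5, apply_size_correction: bool = True
) -> tuple[PhenotypeTable, PreprocessReport]:
    """The full metric sequence: sparse removal -> kNN imputation -> size
    correction, in that order."""
    filtered, dropped = remove_sparse_individuals(table, max_missing_frac)
    n_missing = int(filtered.data.isna().sum().sum())
    imputed = knn_impute(filtered, k=k)
    corrected = size_correct(imputed) if apply_size_correction else imputed
    report = PreprocessReport(
        dropped, n_missing, n_missing / max(filtered.data.size, 1)
    )
    return corrected, report


def preprocess_nonmetric(
    table: PhenotypeTable, breakpoints: dict[str, float], max_missing_frac: float = 0.5
) -> tuple[PhenotypeTable, PreprocessReport]:
    """The nonmetric sequence: sparse removal -> dichotomization.  Missing
    scores stay missing; frequencies are computed on observed counts."""
    filtered, dropped = remove_sparse_individuals(table, max_missing_frac)
    binary = dichotomize(filtered, breakpoints)
    report = PreprocessReport(dropped, 0, 0.0)
    return binary, report
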