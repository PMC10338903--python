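"""Partial-correlation neutrality estimation with nested resampling.

The neutrality estimate r is the partial Pearson correlation between the
off-diagonals of a phenotypic distance matrix (D^2) and the genetic
distance matrix (F_ST), controlling for an environmental covariate matrix
(climate C or geography G): r is the correlation of the residuals from the
independent regressions D^2 ~ C and F_ST ~ C.

Three nested resampling schemes quantify the estimate's uncertainty:
population sampling (leave out one random population everywhere plus one
random individual per remaining population, drawn independently per data
set because samples are unpaired), phenotypic-variable undersampling to a
common count (default 24), and SNP-loci undersampling to the same count
(stochastic variation inherent to neutral evolution).  Per-iteration
sub-seeds are derived counter-based from the master seed, so iteration i
consumes identical population-drop and locus-subset draws across data
types: distributions produced under one master seed are paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .distances import (
    AlleleStats,
    block_d2,
    climate_distance,
    combined_d2,
    geodesic_distance,
    pairwise_fst_from_stats,
    wc_fst_matrix,
)
from .types import (
    COMBINED,
    DATA_TYPES,
    ConfigError,
    DataError,
    DistanceMatrix,
    GenotypeMatrix,
    PhenotypeTable,
    PopulationMetadata,
)

_MAX_LOCI_REDRAWS = 100


# ---------------------------------------------------------------------------
# correlation primitives


def offdiag_vector(D: DistanceMatrix, label_order) -> np.ndarray:
    """Strictly-lower-triangle entries of D in row-major order of
    ``label_order`` (length m(m-1)/2)."""
    sub = D.align(list(label_order))
    m = sub.n
    return sub.values[np.tril_indices(m, k=-1)]


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation with explicit degenerate-input errors."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("vectors must be one-dimensional and of equal length")
    if len(x) < 3:
        raise DataError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DataError("zero variance in correlation input")
    return float(np.corrcoef(x, y)[0, 1])


def _ols_residuals(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(len(x)), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def partial_pearson_r(dP: np.ndarray, dG: np.ndarray, dC: np.ndarray) -> float:
    """Residual-based partial correlation of dP and dG controlling for dC.

    Both variables are regressed on dC (ordinary least squares with
    intercept); the result is the Pearson correlation of the two residual
    vectors, identical to the closed-form single-covariate partial
    correlation.
    """
    dP = np.asarray(dP, float)
    dG = np.asarray(dG, float)
    dC = np.asarray(dC, float)
    if not (len(dP) == len(dG) == len(dC)) or len(dP) < 4:
        raise DataError("need equal-length vectors with at least 4 entries")
    if np.std(dC) == 0:
        raise DataError("covariate has zero variance; use pearson_r instead")
    rP = _ols_residuals(dP, dC)
    rG = _ols_residuals(dG, dC)
    scale = max(np.std(dP), np.std(dG), 1.0)
    if np.std(rP) <= 1e-12 * scale or np.std(rG) <= 1e-12 * scale:
        raise DataError("degenerate residual variance: a variable is collinear with the covariate")
    return pearson_r(rP, rG)


# ---------------------------------------------------------------------------
# schemes and distributions


@dataclass(frozen=True)
class ResamplingScheme:
    """Which sources of sampling uncertainty an experiment resamples."""

    n_iterations: int = 1000
    drop_random_population: bool = False
    drop_random_individual_per_population: bool = False
    n_variables_subsample: int | None = None
    n_loci_subsample: int | None = None
    covariate: str = "climate"
    master_seed: int = 0

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ConfigError("n_iterations must be >= 1")
        for v in (self.n_variables_subsample, self.n_loci_subsample):
            if v is not None and v < 2:
                raise ConfigError("subsample sizes must be >= 2")
        if self.covariate not in ("climate", "geography", "none"):
            raise ConfigError("covariate must be climate, geography or none")

    @property
    def any_random(self) -> bool:
        return bool(
            self.drop_random_population
            or self.drop_random_individual_per_population
            or self.n_variables_subsample
            or self.n_loci_subsample
        )


def scheme_point(covariate: str = "climate", master_seed: int = 0) -> ResamplingScheme:
    """Degenerate scheme: no resampling; every iteration equals the point
    estimate."""
    return ResamplingScheme(
        n_iterations=1000, covariate=covariate, master_seed=master_seed
    )


def scheme_population(
    n_iterations: int = 1000, covariate: str = "climate", master_seed: int = 0
) -> ResamplingScheme:
    """Population sampling bias correction: leave out one random population
    and one random individual per remaining population."""
    return ResamplingScheme(
        n_iterations=n_iterations,
        drop_random_population=True,
        drop_random_individual_per_population=True,
        covariate=covariate,
        master_seed=master_seed,
    )


def scheme_variables(
    n_iterations: int = 1000,
    n_variables: int = 24,
    covariate: str = "climate",
    master_seed: int = 0,
) -> ResamplingScheme:
    """Population plus phenotype sampling bias correction: additionally
    undersample the phenotypic variables to a common count."""
    return ResamplingScheme(
        n_iterations=n_iterations,
        drop_random_population=True,
        drop_random_individual_per_population=True,
        n_variables_subsample=n_variables,
        covariate=covariate,
        master_seed=master_seed,
    )


def scheme_loci(
    n_iterations: int = 1000,
    n_variables: int = 24,
    n_loci: int = 24,
    covariate: str = "climate",
    master_seed: int = 0,
) -> ResamplingScheme:
    """Population, phenotype and loci sampling bias correction: additionally
    undersample the SNP loci down to the number of phenotypic variables."""
    return ResamplingScheme(
        n_iterations=n_iterations,
        drop_random_population=True,
        drop_random_individual_per_population=True,
        n_variables_subsample=n_variables,
        n_loci_subsample=n_loci,
        covariate=covariate,
        master_seed=master_seed,
    )


@dataclass
class NeutralityDistribution:
    """Resampled neutrality estimates for one data type under one scheme."""

    data_type: str
    r_values: np.ndarray
    scheme: ResamplingScheme
    draw_log: list[dict] | None = None

    def __post_init__(self):
        self.r_values = np.asarray(self.r_values, float)
        if ((self.r_values < -1 - 1e-12) | (self.r_values > 1 + 1e-12)).any():
            raise DataError("correlation values outside [-1, 1]")

    @property
    def median(self) -> float:
        return float(np.median(self.r_values))

    @property
    def low(self) -> float:
        return float(np.percentile(self.r_values, 2.5))

    @property
    def high(self) -> float:
        return float(np.percentile(self.r_values, 97.5))


def summarize(dist: NeutralityDistribution) -> tuple[float, float, float]:
    """Median and 95% interpercentile bounds (2.5th/97.5th percentiles,
    linear interpolation between order statistics)."""
    return dist.median, dist.low, dist.high


# ---------------------------------------------------------------------------
# point estimate


def _covariate_matrix(metadata: PopulationMetadata, covariate: str) -> DistanceMatrix | None:
    if covariate == "climate":
        return climate_distance(metadata)
    if covariate == "geography":
        return geodesic_distance(metadata)
    if covariate == "none":
        return None
    raise ConfigError(f"unknown covariate {covariate!r}")


def _check_alignment(
    genotypes: GenotypeMatrix,
    blocks: dict[str, PhenotypeTable],
    metadata: PopulationMetadata,
) -> list[str]:
    pops = metadata.populations
    if set(genotypes.populations) != set(pops):
        raise DataError("genotype populations do not match metadata")
    for name, tab in blocks.items():
        if set(tab.populations) != set(pops):
            raise DataError(f"phenotype block {name!r} populations do not match metadata")
    return pops


def _data_type_d2(
    blocks: dict[str, PhenotypeTable], data_type: str, order: list[str]
) -> DistanceMatrix:
    if data_type == COMBINED:
        mats = [block_d2(tab) for tab in blocks.values()]
        sizes = [len(tab.variable_ids) for tab in blocks.values()]
        return combined_d2(mats, sizes).align(order)
    if data_type not in blocks:
        raise ConfigError(f"unknown data type {data_type!r}")
    return block_d2(blocks[data_type]).align(order)


def point_estimate(
    genotypes: GenotypeMatrix,
    blocks: dict[str, PhenotypeTable],
    metadata: PopulationMetadata,
    data_type: str,
    covariate: str = "climate",
) -> float:
    """Neutrality estimate on the full sample: partial (or plain) Pearson
    correlation between the selected D^2 and F_ST off-diagonals."""
    pops = _check_alignment(genotypes, blocks, metadata)
    fst = wc_fst_matrix(genotypes)
    D = _data_type_d2(blocks, data_type, pops)
    dP = offdiag_vector(D, pops)
    dG = offdiag_vector(fst, pops)
    cov = _covariate_matrix(metadata, covariate)
    if cov is None:
        return pearson_r(dP, dG)
    return partial_pearson_r(dP, dG, offdiag_vector(cov, pops))


# ---------------------------------------------------------------------------
# resampling


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=key)))


_STREAM_SHARED = 0
_STREAM_GENOMIC = 1
_STREAM_COMBINED = 30


def _block_stream(name: str, blocks: dict[str, PhenotypeTable]) -> int:
    if name in DATA_TYPES:
        return 10 + DATA_TYPES.index(name)
    return 20 + sorted(blocks).index(name)


def _drop_one_per_population(
    rng: np.random.Generator, pop_rows: dict[str, np.ndarray], retained: list[str]
) -> dict[str, np.ndarray]:
    out = {}
    for p in retained:
        rows = pop_rows[p]
        out[p] = np.array([rows[rng.integers(len(rows))]])
    return out


def _validate_scheme(
    scheme: ResamplingScheme,
    genotypes: GenotypeMatrix,
    blocks: dict[str, PhenotypeTable],
    data_types: list[str],
) -> None:
    pops = genotypes.populations
    if scheme.drop_random_population and len(pops) < 4:
        raise ConfigError("population dropping needs at least 4 populations")
    if scheme.drop_random_individual_per_population:
        geno_counts = {p: len(r) for p, r in genotypes.pop_indices().items()}
        if min(geno_counts.values()) < 3:
            raise ConfigError("each population needs >= 3 genomic individuals to drop one")
        for name, tab in blocks.items():
            if min(len(r) for r in tab.pop_indices().values()) < 3:
                raise ConfigError(
                    f"each population needs >= 3 phenotypic individuals in block {name!r}"
                )
    if scheme.n_loci_subsample is not None and scheme.n_loci_subsample > genotypes.n_loci:
        raise ConfigError("cannot undersample more loci than available")
    if scheme.n_variables_subsample is not None:
        for dt in data_types:
            avail = (
                sum(len(t.variable_ids) for t in blocks.values())
                if dt == COMBINED
                else len(blocks[dt].variable_ids)
            )
            if scheme.n_variables_subsample > avail:
                raise ConfigError(
                    f"cannot undersample {scheme.n_variables_subsample} variables "
                    f"from {avail} in data type {dt!r}"
                )


def resample_neutrality(
    genotypes: GenotypeMatrix,
    blocks: dict[str, PhenotypeTable],
    metadata: PopulationMetadata,
    scheme: ResamplingScheme,
    data_types: list[str] | None = None,
    log_draws: bool = False,
) -> dict[str, NeutralityDistribution]:
    """Run the resampling experiment for one or several data types at once.

    Per iteration, in order: (1) one population is dropped from all data
    sets; (2) one individual is dropped per remaining population,
    independently in the genomic set and in each phenotype block (samples
    are unpaired); (3) if active, variables are subsampled per block (the
    combined data type draws from the pooled variable list without block
    quotas); (4) if active, loci are subsampled without replacement (a draw
    leaving some population pair with no defined locus is redrawn and
    logged); (5) distances, the covariate and the partial correlation are
    recomputed on the retained populations.

    Running several data types together shares the population-drop, locus
    and genomic-individual draws per iteration, which both halves the work
    and establishes the pairing needed by :func:`paired_t_tests`.
    """
    pops = _check_alignment(genotypes, blocks, metadata)
    if data_types is None:
        data_types = list(blocks) + ([COMBINED] if len(blocks) > 1 else [])
    for dt in data_types:
        if dt != COMBINED and dt not in blocks:
            raise ConfigError(f"unknown data type {dt!r}")
    _validate_scheme(scheme, genotypes, blocks, data_types)
    seed = scheme.master_seed

    if not scheme.any_random:
        out = {}
        for dt in data_types:
            r0 = point_estimate(genotypes, blocks, metadata, dt, scheme.covariate)
            out[dt] = NeutralityDistribution(
                dt, np.full(scheme.n_iterations, r0), scheme,
                draw_log=[] if log_draws else None,
            )
        return out

    base_stats = AlleleStats.from_genotypes(genotypes)
    geno_rows = genotypes.pop_indices()
    block_rows = {name: tab.pop_indices() for name, tab in blocks.items()}
    cov_full = _covariate_matrix(metadata, scheme.covariate)
    n_loci = genotypes.n_loci
    pooled_vars = [(name, v) for name, tab in blocks.items() for v in tab.variable_ids]

    results: dict[str, list[float]] = {dt: [] for dt in data_types}
    logs: dict[str, list[dict]] = {dt: [] for dt in data_types}
    need_blocks = set(b for b in blocks if b in data_types)
    if COMBINED in data_types:
        need_blocks = set(blocks)

    for it in range(scheme.n_iterations):
        shared = _rng(seed, it, _STREAM_SHARED)
        dropped_pop = None
        retained = list(pops)
        if scheme.drop_random_population:
            dropped_pop = pops[shared.integers(len(pops))]
            retained = [p for p in pops if p != dropped_pop]

        loci_subset = None
        if scheme.n_loci_subsample is not None:
            loci_subset = np.sort(
                shared.choice(n_loci, size=scheme.n_loci_subsample, replace=False)
            )

        geno_drop: dict[str, np.ndarray] = {}
        if scheme.drop_random_individual_per_population:
            grng = _rng(seed, it, _STREAM_GENOMIC)
            geno_drop = _drop_one_per_population(grng, geno_rows, retained)

        stats_it = base_stats.drop(geno_drop, genotypes) if geno_drop else base_stats
        n_redraws = 0
        while True:
            sel = stats_it.select(retained, loci_subset)
            fst_vals, _ = pairwise_fst_from_stats(sel)
            off = fst_vals[np.tril_indices(len(retained), k=-1)]
            if not np.isnan(off).any():
                break
            if scheme.n_loci_subsample is None:
                raise DataError("a population pair has no defined locus")
            n_redraws += 1
            if n_redraws > _MAX_LOCI_REDRAWS:
                raise DataError("could not draw a usable locus subset")
            redraw = _rng(seed, it, _STREAM_SHARED, n_redraws)
            loci_subset = np.sort(
                redraw.choice(n_loci, size=scheme.n_loci_subsample, replace=False)
            )
        dG = off

        if cov_full is not None:
            dC = offdiag_vector(cov_full, retained)

        # per-block prepared tables (population drop + one individual per pop)
        prepared: dict[str, PhenotypeTable] = {}
        block_var_draw: dict[str, list[str] | None] = {}
        for name in blocks:
            if name not in need_blocks:
                continue
            brng = _rng(seed, it, _block_stream(name, blocks))
            tab = blocks[name]
            drop_rows: set[int] = set()
            if scheme.drop_random_individual_per_population:
                for p in retained:
                    rows = block_rows[name][p]
                    drop_rows.add(int(rows[brng.integers(len(rows))]))
            labels = tab.population_labels.to_numpy()
            keep = [
                i
                for i in range(len(labels))
                if labels[i] != dropped_pop and i not in drop_rows
            ]
            prepared[name] = tab.subset_individuals(tab.data.index[keep])
            if scheme.n_variables_subsample is not None and name in data_types:
                vids = tab.variable_ids
                pick = brng.choice(
                    len(vids), size=min(scheme.n_variables_subsample, len(vids)),
                    replace=False,
                )
                block_var_draw[name] = [vids[j] for j in np.sort(pick)]
            else:
                block_var_draw[name] = None

        for dt in data_types:
            if dt == COMBINED:
                if scheme.n_variables_subsample is not None:
                    crng = _rng(seed, it, _STREAM_COMBINED)
                    pick = crng.choice(
                        len(pooled_vars), size=scheme.n_variables_subsample, replace=False
                    )
                    chosen: dict[str, list[str]] = {}
                    for j in np.sort(pick):
                        bname, vid = pooled_vars[j]
                        chosen.setdefault(bname, []).append(vid)
                    mats, sizes = [], []
                    for bname, vids in chosen.items():
                        mats.append(block_d2(prepared[bname].subset_variables(vids)))
                        sizes.append(len(vids))
                    D = combined_d2(mats, sizes).align(retained)
                else:
                    mats = [block_d2(prepared[b]) for b in blocks]
                    sizes = [len(blocks[b].variable_ids) for b in blocks]
                    D = combined_d2(mats, sizes).align(retained)
                var_subset = sorted(v for vs in chosen.values() for v in vs) if (
                    scheme.n_variables_subsample is not None
                ) else None
            else:
                tab = prepared[dt]
                var_subset = block_var_draw[dt]
                if var_subset is not None:
                    tab = tab.subset_variables(var_subset)
                D = block_d2(tab).align(retained)
            dP = offdiag_vector(D, retained)
            r = (
                pearson_r(dP, dG)
                if cov_full is None
                else partial_pearson_r(dP, dG, dC)
            )
            results[dt].append(r)
            if log_draws:
                logs[dt].append(
                    {
                        "iteration": it,
                        "dropped_population": dropped_pop,
                        "loci_subset": None if loci_subset is None else loci_subset.tolist(),
                        "n_loci_redraws": n_redraws,
                        "variable_subset": var_subset,
                    }
                )

    return {
        dt: NeutralityDistribution(
            dt, np.array(results[dt]), scheme, draw_log=logs[dt] if log_draws else None
        )
        for dt in data_types
    }


# ---------------------------------------------------------------------------
# paired tests


_P_FLOOR = 5e-324  # smallest subnormal double: underflow-safe p bound


def paired_t_tests(distributions: dict[str, NeutralityDistribution]) -> pd.DataFrame:
    """Repeated-measures t-tests between all pairs of r distributions, with
    Bonferroni correction over the number of pairs.

    Distributions must come from the same scheme and master seed so that
    iteration i is paired across data types (shared population-drop and
    locus draws).
    """
    names = list(distributions)
    if len(names) < 2:
        raise ConfigError("need at least two distributions to compare")
    first = distributions[names[0]]
    for d in distributions.values():
        if len(d.r_values) != len(first.r_values) or d.scheme != first.scheme:
            raise DataError("distributions are not paired (scheme/seed/iterations differ)")
    pairs = list(combinations(names, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        diff = distributions[a].r_values - distributions[b].r_values
        sd = diff.std(ddof=1) if len(diff) > 1 else 0.0
        if sd == 0.0:
            if np.allclose(diff, 0.0):
                t, p = 0.0, 1.0
            else:
                t = np.inf if diff.mean() > 0 else -np.inf
                p = _P_FLOOR
        else:
            t, p = sps.ttest_rel(distributions[a].r_values, distributions[b].r_values)
            t, p = float(t), float(max(p, _P_FLOOR))
        rows.append(
            {
                "data_type_a": a,
                "data_type_b": b,
                "t": t,
                "p": p,
                "p_bonferroni": min(1.0, m * p),
            }
        )
    return pd.DataFrame(rows)
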