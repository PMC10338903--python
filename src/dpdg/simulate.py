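"""Synthetic genotype/phenotype/metadata generation with known ground truth.

The generator emulates the statistical structure the neutrality analysis
assumes: ~26 populations arranged along a serial path on the sphere with
divergence accumulating along the path (a serial-founder analogue of the
Balding-Nichols model), thousands of neutral biallelic loci, four phenotype
blocks (cranial/dental x metric/nonmetric) whose neutral components share
the genetic coancestry structure, a climate-driven non-neutral component
(the confound the partial correlation controls for), within-block genetic
integration through a small number of shared factors with independence
*between* blocks (the modularity hypothesis), MCAR missingness, and
unpaired genomic versus phenotypic individuals.

All generators are pure functions of (config, seed): reruns are
bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import io as io_mod
from .types import (
    CLIMATE_VARS,
    DATA_TYPES,
    MODE_GRADED,
    MODE_METRIC,
    ConfigError,
    DataError,
    GenotypeMatrix,
    PhenotypeTable,
    PopulationMetadata,
)


@dataclass(frozen=True)
class BlockSpec:
    """One phenotype block: name, number of variables, measurement mode,
    heritability of the neutral component and climate effect size."""

    name: str
    size: int
    mode: str  # "metric" or "nonmetric"
    h2: float = 0.8
    beta: float = 0.1

    def __post_init__(self):
        if self.size <= 0:
            raise ConfigError("block size must be positive")
        if not 0.0 <= self.h2 <= 1.0:
            raise ConfigError("heritability must be in [0, 1]")
        if self.mode not in ("metric", "nonmetric"):
            raise ConfigError("block mode must be 'metric' or 'nonmetric'")


def default_blocks(
    h2=(0.9, 0.2, 0.5, 0.8), beta=(0.1, 0.1, 0.1, 0.1)
) -> tuple[BlockSpec, ...]:
    """The four standard craniodental blocks (37/28/24/25 variables).

    Default heritabilities mirror quantitative-genetic expectations of
    high independent genetic information in cranial metrics and dental
    nonmetric traits, intermediate in cranial nonmetric traits and low in
    dental metrics."""
    sizes = (37, 28, 24, 25)
    modes = ("metric", "metric", "nonmetric", "nonmetric")
    return tuple(
        BlockSpec(name, s, m, h2=h, beta=b)
        for name, s, m, h, b in zip(DATA_TYPES, sizes, modes, h2, beta)
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic fixture.

    ``f_start``/``f_end`` are the cumulative divergence (coancestry-scale F)
    of the first and last population along the serial path; with
    ``divergence_mode="serial"`` each population's allele frequencies drift
    from the previous population's, with ``"star"`` each drifts
    independently from the ancestral frequency.
    """

    n_populations: int = 26
    n_loci: int = 2000
    n_genomic_per_population: int = 25
    n_phenotypic_per_population: int = 60
    f_start: float = 0.02
    f_end: float = 0.25
    divergence_mode: str = "serial"
    blocks: tuple[BlockSpec, ...] = field(default_factory=default_blocks)
    n_genetic_factors: int = 3
    metric_cv: float = 0.1
    missingness: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_populations < 3:
            raise ConfigError("need at least 3 populations")
        if not (0 < self.f_start <= self.f_end < 1):
            raise ConfigError("divergence F values must satisfy 0 < f_start <= f_end < 1")
        if self.divergence_mode not in ("serial", "star"):
            raise ConfigError("divergence_mode must be 'serial' or 'star'")
        if not 0 <= self.missingness < 1:
            raise ConfigError("missingness rate must be in [0, 1)")
        names = [b.name for b in self.blocks]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate block names")

    def divergence(self) -> np.ndarray:
        return np.linspace(self.f_start, self.f_end, self.n_populations)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["blocks"] = [dataclasses.asdict(b) for b in self.blocks]
        return d


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=key)))


# ---------------------------------------------------------------------------
# metadata


def simulate_metadata(config: SimulationConfig) -> PopulationMetadata:
    """Populations along a serial path on the sphere, with five temperature
    variables generated as smooth functions of latitude plus regional noise
    (continentality, altitude), so that climate distance correlates with
    geographic distance."""
    K = config.n_populations
    rng = _rng(config.seed, 0)
    lat = np.linspace(-10.0, 60.0, K) + rng.normal(0.0, 4.0, K)
    lat = np.clip(lat, -65.0, 75.0)
    lon = np.linspace(-170.0, 160.0, K) + rng.normal(0.0, 3.0, K)
    lon = np.clip(lon, -180.0, 180.0)
    noise = rng.normal(0.0, 5.0, (K, 5))
    tmean = 27.0 - 0.45 * np.abs(lat) + noise[:, 0]
    tmax = tmean + 7.0 + noise[:, 1]
    tmin = tmean - 12.0 - 0.10 * np.abs(lat) + noise[:, 2]
    twarm = tmax + 3.0 + np.abs(noise[:, 3]) * 0.5
    tcold = tmin - 4.0 - 0.10 * np.abs(lat) - np.abs(noise[:, 4]) * 0.5
    pops = [f"P{k + 1:02d}" for k in range(K)]
    table = pd.DataFrame(
        {
            "latitude": lat,
            "longitude": lon,
            CLIMATE_VARS[0]: tmin,
            CLIMATE_VARS[1]: tmax,
            CLIMATE_VARS[2]: tmean,
            CLIMATE_VARS[3]: twarm,
            CLIMATE_VARS[4]: tcold,
        },
        index=pd.Index(pops, name="population"),
    )
    return PopulationMetadata(table)


# ---------------------------------------------------------------------------
# genotypes


def coancestry_matrix(F: np.ndarray, mode: str = "serial") -> np.ndarray:
    """Between-population coancestry implied by the divergence profile.

    Serial mode: populations share drift along the path up to the earlier
    branch point, Theta[i, j] = F[min(i, j)] (Brownian-like covariance).
    Star mode: independent drift, Theta = diag(F).
    """
    F = np.asarray(F, float)
    if mode == "serial":
        return np.minimum.outer(F, F)
    if mode == "star":
        return np.diag(F)
    raise ConfigError("mode must be 'serial' or 'star'")


def _beta_around(rng: np.random.Generator, mean: np.ndarray, f: float) -> np.ndarray:
    """Beta draw with the given mean and variance f * mean * (1 - mean)."""
    mean = np.clip(mean, 1e-4, 1.0 - 1e-4)
    scale = (1.0 - f) / f
    return rng.beta(np.maximum(mean * scale, 1e-3), np.maximum((1.0 - mean) * scale, 1e-3))


def simulate_genotypes(
    config: SimulationConfig, metadata: PopulationMetadata
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Balding-Nichols genotypes along the divergence profile.

    Ancestral frequencies are uniform on [0.05, 0.95]; each population's
    frequency is a Beta draw whose variance is governed by its incremental
    divergence (serial mode: from the previous population on the path;
    star mode: from the ancestral frequency with its total F).  Genotypes
    are binomial(2, p_pop).  Returns the matrix and the cumulative
    divergence profile.
    """
    rng = _rng(config.seed, 1)
    K, L = config.n_populations, config.n_loci
    F = config.divergence()
    p0 = rng.uniform(0.05, 0.95, L)
    pmat = np.empty((K, L))
    if config.divergence_mode == "star":
        for k in range(K):
            pmat[k] = _beta_around(rng, p0, F[k])
    else:
        prev = p0
        f_prev = 0.0
        for k in range(K):
            f_step = (F[k] - f_prev) / (1.0 - f_prev)
            pmat[k] = _beta_around(rng, prev, f_step) if f_step > 1e-12 else prev
            prev = pmat[k]
            f_prev = F[k]
    pmat = np.clip(pmat, 1e-4, 1.0 - 1e-4)
    n_per = config.n_genomic_per_population
    ids, labels, rows = [], [], []
    for k, pop in enumerate(metadata.populations):
        g = rng.binomial(2, pmat[k], size=(n_per, L)).astype(np.int8)
        rows.append(g)
        ids.extend(f"{pop}_g{i + 1:03d}" for i in range(n_per))
        labels.extend([pop] * n_per)
    geno = GenotypeMatrix(ids, labels, [f"L{j + 1:05d}" for j in range(L)], np.vstack(rows))
    return geno, F


# ---------------------------------------------------------------------------
# phenotypes


@dataclass
class BlockTruth:
    """Ground truth for one simulated block: the latent population trait
    means (neutral drift plus climate component), the within-population
    correlation of the latent liabilities, and the dichotomization
    thresholds (nonmetric blocks only)."""

    latent_means: np.ndarray  # populations x traits
    within_corr: np.ndarray  # traits x traits
    thresholds: np.ndarray | None
    spec: BlockSpec


def _random_correlation(rng: np.random.Generator, T: int) -> np.ndarray:
    a = rng.normal(size=(T, T + 5))
    w = a @ a.T / (T + 5)
    d = np.sqrt(np.diag(w))
    return w / np.outer(d, d)


def _unit_columns(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    m = rng.normal(size=(rows, cols))
    return m / np.linalg.norm(m, axis=0, keepdims=True)


def _isotropic_loadings(rng: np.random.Generator, dims: int, traits: int) -> np.ndarray:
    """Loadings (dims x traits) whose rows are orthonormal directions, so the
    effect spans the source space evenly; scaled so the per-trait effect
    variance is 1 on average."""
    g = rng.normal(size=(traits, max(traits, dims)))
    q, _ = np.linalg.qr(g)
    w = q[:, :dims].T  # dims x traits, orthonormal rows
    return w * np.sqrt(traits / dims)


def simulate_phenotypes(
    config: SimulationConfig,
    metadata: PopulationMetadata,
    coancestry: np.ndarray,
) -> tuple[dict[str, PhenotypeTable], dict[str, float], dict[str, BlockTruth]]:
    """Generate the four phenotype blocks.

    Per block, population trait means are a low-rank draw: a handful of
    genetic factors with between-population covariance 2 h^2 Theta (shared
    drift, scaled by heritability) load onto the traits through unit-norm
    loadings, plus beta times standardized climate through independent
    unit-norm loadings.  Factors are drawn independently per block, making
    blocks genetically independent modules while traits within a block are
    pleiotropically integrated.  Individual values add within-population
    noise with a random unit-variance correlation structure.  Metric blocks
    are mapped to strictly positive measurements with an individual size
    factor (so size correction is exercised); nonmetric blocks are graded
    by liability thresholds chosen so baseline presence frequencies span
    roughly 0.15-0.85.  Returns (blocks, breakpoints, truth).
    """
    K = config.n_populations
    pops = metadata.populations
    z = metadata.climate()
    z = (z - z.mean(axis=0)) / z.std(axis=0, ddof=0)
    theta = np.asarray(coancestry, float)
    blocks: dict[str, PhenotypeTable] = {}
    breakpoints: dict[str, float] = {}
    truth: dict[str, BlockTruth] = {}
    n_per = config.n_phenotypic_per_population
    for b, spec in enumerate(config.blocks):
        rng = _rng(config.seed, 2, b)
        T = spec.size
        q = config.n_genetic_factors
        cov_b = 2.0 * spec.h2 * theta + 1e-10 * np.eye(K)
        Lc = np.linalg.cholesky(cov_b)
        factors = Lc @ rng.normal(size=(K, q))
        load = _unit_columns(rng, q, T)
        drift = factors @ load
        climate_load = _isotropic_loadings(rng, z.shape[1], T)
        M = drift + spec.beta * (z @ climate_load)
        corr = _random_correlation(rng, T)
        Lw = np.linalg.cholesky(corr + 1e-12 * np.eye(T))
        n_total = n_per * K
        eps = rng.normal(size=(n_total, T)) @ Lw.T
        pop_idx = np.repeat(np.arange(K), n_per)
        x = M[pop_idx] + eps
        ids = [f"{pops[k]}_{spec.name}_{i + 1:03d}" for k in range(K) for i in range(n_per)]
        labels = pd.Series(np.repeat(pops, n_per), index=ids)
        sex = pd.Series(
            rng.choice(["male", "female"], size=n_total, p=[0.55, 0.45]), index=ids
        )
        var_ids = [f"{spec.name}_v{t + 1:02d}" for t in range(T)]
        if spec.mode == "metric":
            base = np.exp(rng.uniform(2.3, 5.3, T))
            size_f = rng.normal(0.0, 0.10, n_total) + 0.06 * (sex.to_numpy() == "male")
            meas = rng.normal(0.0, 0.02, (n_total, T))
            vals = base * np.exp(config.metric_cv * x + size_f[:, None] + meas)
            table = PhenotypeTable(
                pd.DataFrame(vals, index=ids, columns=var_ids),
                labels,
                mode=MODE_METRIC,
                sex_labels=sex,
            )
            thresholds = None
        else:
            between_var = 2.0 * spec.h2 * float(np.mean(np.diag(theta))) + spec.beta**2
            s_marg = np.sqrt(1.0 + between_var)
            qt = rng.uniform(0.15, 0.85, T)
            thresholds = norm.ppf(qt) * s_marg
            step = 0.7 * s_marg
            grades = (
                (x > thresholds).astype(float)
                + (x > thresholds + step)
                + (x > thresholds + 2 * step)
            )
            table = PhenotypeTable(
                pd.DataFrame(grades, index=ids, columns=var_ids),
                labels,
                mode=MODE_GRADED,
                sex_labels=sex,
            )
            breakpoints.update({v: 1.0 for v in var_ids})
        blocks[spec.name] = table
        truth[spec.name] = BlockTruth(M, corr, thresholds, spec)
    return blocks, breakpoints, truth


def inject_missingness(table: PhenotypeTable, rate: float, seed: int) -> PhenotypeTable:
    """Missing-completely-at-random mask over the value cells."""
    if not 0.0 <= rate < 1.0:
        raise ConfigError("missingness rate must be in [0, 1)")
    if rate == 0.0:
        return table
    rng = _rng(seed, 9)
    mask = rng.random(table.data.shape) < rate
    data = table.data.mask(mask)
    return replace(table, data=data)


# ---------------------------------------------------------------------------
# full study


@dataclass
class SimulatedStudy:
    """A complete synthetic study with its generating truth."""

    config: SimulationConfig
    metadata: PopulationMetadata
    genotypes: GenotypeMatrix
    divergence: np.ndarray
    coancestry: np.ndarray
    blocks: dict[str, PhenotypeTable]
    breakpoints: dict[str, float]
    truth: dict[str, BlockTruth]


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate metadata, genotypes and the four phenotype blocks, then
    apply MCAR missingness at the configured rate.  Genomic and phenotypic
    individuals are independent draws given the population parameters
    (matched but unpaired samples)."""
    metadata = simulate_metadata(config)
    genotypes, F = simulate_genotypes(config, metadata)
    theta = coancestry_matrix(F, config.divergence_mode)
    blocks, breakpoints, truth = simulate_phenotypes(config, metadata, theta)
    if config.missingness > 0:
        blocks = {
            name: inject_missingness(tab, config.missingness, config.seed + 1000 + i)
            for i, (name, tab) in enumerate(blocks.items())
        }
    return SimulatedStudy(
        config, metadata, genotypes, F, theta, blocks, breakpoints, truth
    )


def true_signal_r(
    study: SimulatedStudy, data_type: str, covariate: str = "climate"
) -> float:
    """Per-seed ground-truth neutrality estimate: the partial correlation
    between the realized F_ST matrix and the D^2 of the *latent* population
    trait means (no individual sampling or scoring noise), controlling for
    the covariate.  Used as the reference against which estimated block
    orderings are judged."""
    from .distances import (
        climate_distance,
        combined_d2,
        geodesic_distance,
        mahalanobis_matrix,
        wc_fst_matrix,
    )
    from .neutrality import offdiag_vector, partial_pearson_r, pearson_r
    from .types import COMBINED, DistanceMatrix

    pops = study.metadata.populations
    if data_type == COMBINED:
        mats, sizes = [], []
        for name, tr in study.truth.items():
            mats.append(
                DistanceMatrix(pops, mahalanobis_matrix(tr.latent_means, tr.within_corr))
            )
            sizes.append(tr.spec.size)
        D = combined_d2(mats, sizes)
    else:
        tr = study.truth[data_type]
        D = DistanceMatrix(pops, mahalanobis_matrix(tr.latent_means, tr.within_corr))
    fst = wc_fst_matrix(study.genotypes)
    dP = offdiag_vector(D, pops)
    dG = offdiag_vector(fst, pops)
    if covariate == "none":
        return pearson_r(dP, dG)
    cov = climate_distance(study.metadata) if covariate == "climate" else geodesic_distance(study.metadata)
    return partial_pearson_r(dP, dG, offdiag_vector(cov, pops))


def write_fixture(study: SimulatedStudy, outdir) -> None:
    """Write the study as the file bundle the readers consume: a genepop
    file plus tabular genotypes, one CSV per phenotype block, metadata,
    breakpoints, and a manifest recording config and seed."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    io_mod.write_genepop(study.genotypes, out / "genotypes.gen")
    io_mod.write_genotypes_csv(study.genotypes, out / "genotypes.csv")
    io_mod.write_metadata(study.metadata, out / "metadata.csv")
    io_mod.write_breakpoints(study.breakpoints, out / "breakpoints.csv")
    for name, table in study.blocks.items():
        io_mod.write_phenotypes(table, out / f"phenotypes_{name}.csv")
    manifest = {"seed": study.config.seed, "config": study.config.to_dict()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
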