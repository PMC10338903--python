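"""Shared domain containers for the genotype-phenotype neutrality pipeline.

All downstream modules exchange data through the containers defined here:
genotype matrices (biallelic SNP counts with population labels), phenotype
tables (metric measurements or nonmetric grades/binary scores), population
metadata (coordinates plus five temperature variables), and labelled
symmetric distance matrices.  Containers validate their invariants at
construction so that readers and simulators fail loudly instead of
propagating malformed data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: sentinel for a missing diploid genotype
GENO_MISSING = -1

#: canonical order of the five temperature variables (all degrees Celsius)
CLIMATE_VARS = (
    "temp_annual_min",
    "temp_annual_max",
    "temp_annual_mean",
    "temp_warmest_month_max",
    "temp_coldest_month_min",
)

#: the four phenotype blocks, in canonical order
DATA_TYPES = (
    "cranial_metric",
    "dental_metric",
    "cranial_nonmetric",
    "dental_nonmetric",
)
COMBINED = "combined"

MODE_METRIC = "metric"
MODE_GRADED = "nonmetric-graded"
MODE_BINARY = "nonmetric-binary"
_MODES = (MODE_METRIC, MODE_GRADED, MODE_BINARY)


class DataError(ValueError):
    """Raised when input data violate a container or operation contract."""


class ConfigError(ValueError):
    """Raised for invalid configuration (schemes, run configs, CLI options)."""


def _ordered_unique(labels: Iterable[str]) -> list[str]:
    seen: dict[str, None] = {}
    for lab in labels:
        seen.setdefault(lab, None)
    return list(seen)


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic loci, coded as counts of the reference allele.

    ``genotypes`` holds values in {0, 1, 2} or :data:`GENO_MISSING`.
    Population labels are per individual; populations are ordered by first
    appearance.
    """

    individual_ids: list[str]
    population_labels: list[str]
    locus_ids: list[str]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n, m = self.genotypes.shape
        if len(self.individual_ids) != n:
            raise DataError("individual_ids length does not match genotype rows")
        if len(self.population_labels) != n:
            raise DataError("population label vector length must equal the number of individuals")
        if len(self.locus_ids) != m:
            raise DataError("locus_ids length does not match genotype columns")
        if len(set(self.individual_ids)) != n:
            raise DataError("individual ids must be unique")
        if len(set(self.locus_ids)) != m:
            raise DataError("locus ids must be unique")
        bad = ~np.isin(self.genotypes, (0, 1, 2, GENO_MISSING))
        if bad.any():
            raise DataError("genotype values must be in {0,1,2} or missing")
        if n == 0:
            raise DataError("genotype matrix has no individuals")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @property
    def populations(self) -> list[str]:
        return _ordered_unique(self.population_labels)

    def pop_indices(self) -> dict[str, np.ndarray]:
        """Row indices per population, in order of first appearance."""
        labels = np.asarray(self.population_labels)
        return {p: np.flatnonzero(labels == p) for p in self.populations}

    def subset_individuals(self, rows: np.ndarray) -> "GenotypeMatrix":
        rows = np.asarray(rows)
        return GenotypeMatrix(
            [self.individual_ids[i] for i in rows],
            [self.population_labels[i] for i in rows],
            list(self.locus_ids),
            self.genotypes[rows],
        )

    def subset_loci(self, cols: Sequence[int]) -> "GenotypeMatrix":
        cols = np.asarray(cols)
        return GenotypeMatrix(
            list(self.individual_ids),
            list(self.population_labels),
            [self.locus_ids[j] for j in cols],
            self.genotypes[:, cols],
        )

    def drop_populations(self, pops: Iterable[str]) -> "GenotypeMatrix":
        drop = set(pops)
        keep = np.array([p not in drop for p in self.population_labels])
        return self.subset_individuals(np.flatnonzero(keep))


@dataclass
class PhenotypeTable:
    """Individuals x phenotype variables, with population (and sex) labels.

    ``data`` is a float DataFrame indexed by individual id; NaN marks a
    missing observation.  ``mode`` determines the permissible value domain:
    continuous positive measurements (metric), ordered integer grades
    (nonmetric-graded), or 0/1 indicators (nonmetric-binary).
    """

    data: pd.DataFrame
    population_labels: pd.Series
    mode: str
    sex_labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise DataError(f"unknown phenotype mode {self.mode!r}")
        if not self.data.index.is_unique:
            raise DataError("duplicate individual ids in phenotype table")
        self.data = self.data.astype(float)
        self.population_labels = pd.Series(self.population_labels)
        if not self.data.index.equals(self.population_labels.index):
            self.population_labels = self.population_labels.reindex(self.data.index)
        if self.population_labels.isna().any():
            raise DataError("every individual needs a population label")
        if self.sex_labels is not None:
            self.sex_labels = pd.Series(self.sex_labels).reindex(self.data.index)
            bad = ~self.sex_labels.fillna("unknown").isin(["male", "female", "unknown"])
            if bad.any():
                raise DataError("sex labels must be male/female/unknown")
        if self.mode == MODE_BINARY:
            vals = self.data.to_numpy()
            ok = np.isnan(vals) | (vals == 0) | (vals == 1)
            if not ok.all():
                raise DataError("binary phenotype values must be 0, 1 or missing")

    @property
    def individual_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def variable_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def populations(self) -> list[str]:
        return _ordered_unique(self.population_labels)

    def subset_individuals(self, ids: Sequence) -> "PhenotypeTable":
        ids = list(ids)
        return replace(
            self,
            data=self.data.loc[ids],
            population_labels=self.population_labels.loc[ids],
            sex_labels=None if self.sex_labels is None else self.sex_labels.loc[ids],
        )

    def subset_variables(self, variables: Sequence[str]) -> "PhenotypeTable":
        return replace(self, data=self.data[list(variables)])

    def drop_populations(self, pops: Iterable[str]) -> "PhenotypeTable":
        drop = set(pops)
        keep = ~self.population_labels.isin(drop)
        return self.subset_individuals(self.data.index[keep])

    def pop_indices(self) -> dict[str, np.ndarray]:
        labels = self.population_labels.to_numpy()
        return {p: np.flatnonzero(labels == p) for p in self.populations}


@dataclass
class PopulationMetadata:
    """Per-population coordinates and the five temperature variables."""

    table: pd.DataFrame  # index: population id; columns: latitude, longitude, CLIMATE_VARS

    def __post_init__(self) -> None:
        required = ["latitude", "longitude", *CLIMATE_VARS]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise DataError(f"metadata missing columns: {missing}")
        if not self.table.index.is_unique:
            raise DataError("duplicate population ids in metadata")
        lat = self.table["latitude"]
        lon = self.table["longitude"]
        if ((lat < -90) | (lat > 90)).any():
            raise DataError("latitude out of [-90, 90]")
        if ((lon < -180) | (lon > 180)).any():
            raise DataError("longitude out of [-180, 180]")
        if self.table[list(CLIMATE_VARS)].isna().any().any():
            raise DataError("missing climate value in metadata")

    @property
    def populations(self) -> list[str]:
        return list(self.table.index)

    def climate(self) -> np.ndarray:
        return self.table[list(CLIMATE_VARS)].to_numpy(dtype=float)

    def coordinates(self) -> np.ndarray:
        return self.table[["latitude", "longitude"]].to_numpy(dtype=float)

    def subset(self, pops: Sequence[str]) -> "PopulationMetadata":
        return PopulationMetadata(self.table.loc[list(pops)])


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal.

    Entries must be nonnegative unless the matrix is flagged as an F_ST
    matrix (the Weir-Cockerham estimator can legitimately go negative).
    """

    ids: list[str]
    values: np.ndarray
    is_fst: bool = False

    _SYM_TOL = 1e-9

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise DataError("distance matrix must be square")
        if len(self.ids) != v.shape[0]:
            raise DataError("label count does not match matrix size")
        if len(set(self.ids)) != len(self.ids):
            raise DataError("distance matrix labels must be unique")
        if not np.isfinite(v).all():
            raise DataError("distance matrix entries must be finite")
        if np.abs(v - v.T).max(initial=0.0) > self._SYM_TOL:
            raise DataError("distance matrix is asymmetric beyond 1e-9")
        if np.abs(np.diag(v)).max(initial=0.0) > self._SYM_TOL:
            raise DataError("distance matrix diagonal must be zero")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        if not self.is_fst and (v < -self._SYM_TOL).any():
            raise DataError("distance matrix entries must be nonnegative")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)

    def align(self, order: Sequence[str]) -> "DistanceMatrix":
        """Reorder (or subset) rows/columns to the given label order."""
        order = list(order)
        missing = [p for p in order if p not in self.ids]
        if missing:
            raise DataError(f"labels not present in distance matrix: {missing}")
        idx = [self.ids.index(p) for p in order]
        return DistanceMatrix(order, self.values[np.ix_(idx, idx)], is_fst=self.is_fst)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)
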