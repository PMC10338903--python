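"""Readers and writers for the external file formats.

Supported formats: genepop genotype files (2- or 3-digit diploid allele
codes), a plain tabular genotype dialect (CSV), phenotype and population
metadata tables (CSV), breakpoint tables (CSV) and square labelled distance
matrices (CSV).  All CSVs are comma-separated UTF-8 with a mandatory header
row; missing values are empty cells or ``NA``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import (
    CLIMATE_VARS,
    GENO_MISSING,
    DataError,
    DistanceMatrix,
    GenotypeMatrix,
    PhenotypeTable,
    PopulationMetadata,
)

_NA_VALUES = ["", "NA"]


# ---------------------------------------------------------------------------
# genepop

def read_genepop(path, label_source: str = "last_id") -> GenotypeMatrix:
    """Parse a genepop file into a :class:`GenotypeMatrix`.

    Diploid two-allele codes are mapped to counts of the *reference* allele,
    defined as the lexicographically first allele code observed at that locus
    in file order.  ``0000``/``000000`` (or any code containing a zero
    allele) maps to missing.  Population labels come from the last individual
    identifier of each POP block (``label_source="last_id"``, the common
    genepop convention where samples carry their population's name) or are
    sequential indices (``label_source="sequential"``).  Because genepop
    sample names are population names rather than unique identifiers,
    individual ids are synthesised as ``<pop>_<ordinal>``.
    """
    if label_source not in ("last_id", "sequential"):
        raise DataError("label_source must be 'last_id' or 'sequential'")
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise DataError("genepop file too short")
    body = lines[1:]
    # locus names: one per line, or a single comma-separated line
    locus_ids: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        chunk = body[i].strip()
        if chunk:
            locus_ids.extend(s.strip() for s in chunk.split(",") if s.strip())
        i += 1
    if i == len(body):
        raise DataError("genepop file has no POP block")
    if not locus_ids:
        raise DataError("genepop file declares no loci")

    blocks: list[list[tuple[str, list[str], int]]] = []
    current: list[tuple[str, list[str], int]] = []
    for lineno, raw in enumerate(body[i:], start=i + 2):  # 1-based incl. title
        line = raw.strip()
        if not line:
            continue
        if line.lower() == "pop":
            if current:
                blocks.append(current)
            current = []
            continue
        if "," not in line:
            raise DataError(f"line {lineno}: expected '<id> , <genotypes>'")
        ind_id, _, rest = line.partition(",")
        tokens = rest.split()
        if len(tokens) != len(locus_ids):
            raise DataError(
                f"line {lineno}: expected {len(locus_ids)} genotype codes, got {len(tokens)}"
            )
        current.append((ind_id.strip(), tokens, lineno))
    if current:
        blocks.append(current)
    if not blocks or not all(blocks):
        raise DataError("genepop file contains an empty POP block")

    # decode alleles; establish per-locus reference allele by first appearance
    allele_map: list[dict[str, int]] = [dict() for _ in locus_ids]
    rows: list[list[int]] = []
    ind_ids: list[str] = []
    pop_labels: list[str] = []
    for b, block in enumerate(blocks):
        label = block[-1][0] if label_source == "last_id" else f"pop{b + 1}"
        for k, (_, tokens, lineno) in enumerate(block):
            row = []
            for j, tok in enumerate(tokens):
                if len(tok) not in (4, 6) or not tok.isdigit():
                    raise DataError(f"line {lineno}: malformed genotype code {tok!r}")
                w = len(tok) // 2
                a1, a2 = tok[:w], tok[w:]
                if int(a1) == 0 or int(a2) == 0:
                    row.append(GENO_MISSING)
                    continue
                count = 0
                for allele in (a1, a2):
                    amap = allele_map[j]
                    if allele not in amap:
                        if len(amap) >= 2:
                            raise DataError(
                                f"more than two alleles at locus {locus_ids[j]!r}"
                            )
                        amap[allele] = len(amap)
                    if amap[allele] == 0:
                        count += 1
                row.append(count)
            rows.append(row)
            ind_ids.append(f"{label}_{k + 1}")
            pop_labels.append(label)
    return GenotypeMatrix(ind_ids, pop_labels, locus_ids, np.array(rows, dtype=np.int8))


def write_genepop(geno: GenotypeMatrix, path, title: str = "dpdg export", digits: int = 2) -> None:
    """Write a :class:`GenotypeMatrix` as a genepop file (2- or 3-digit codes).

    The reference allele is written as code 1, the alternate as code 2;
    sample names within a POP block are the population label, so a reader
    using the last-id convention recovers the labels.
    """
    if digits not in (2, 3):
        raise DataError("genepop allele codes must use 2 or 3 digits")
    fmt = f"0{digits}d"
    miss = "0" * (2 * digits)
    code = {2: f"{1:{fmt}}{1:{fmt}}", 1: f"{1:{fmt}}{2:{fmt}}", 0: f"{2:{fmt}}{2:{fmt}}"}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(title + "\n")
        for loc in geno.locus_ids:
            fh.write(loc + "\n")
        for pop, rows in geno.pop_indices().items():
            fh.write("POP\n")
            for i in rows:
                tokens = [
                    miss if g == GENO_MISSING else code[int(g)] for g in geno.genotypes[i]
                ]
                fh.write(f"{pop} , " + " ".join(tokens) + "\n")


# ---------------------------------------------------------------------------
# tabular genotypes

def read_genotypes_csv(path) -> GenotypeMatrix:
    """Plain tabular genotype dialect: individual_id, population, then loci."""
    df = pd.read_csv(path, na_values=_NA_VALUES, keep_default_na=False, dtype={0: str, 1: str})
    if df.columns[0] != "individual_id" or df.columns[1] != "population":
        raise DataError("genotype CSV must start with individual_id,population columns")
    loci = list(df.columns[2:])
    vals = df[loci].to_numpy(dtype=float)
    geno = np.where(np.isnan(vals), GENO_MISSING, vals)
    if not np.isin(geno, (0, 1, 2, GENO_MISSING)).all():
        raise DataError("genotype CSV values must be 0/1/2 or missing")
    return GenotypeMatrix(
        list(df["individual_id"]), list(df["population"]), loci, geno.astype(np.int8)
    )


def write_genotypes_csv(geno: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(geno.genotypes, columns=geno.locus_ids).astype(object)
    df = df.mask(df == GENO_MISSING, "")
    df.insert(0, "population", geno.population_labels)
    df.insert(0, "individual_id", geno.individual_ids)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# phenotypes

def read_phenotypes(path, mode: str) -> PhenotypeTable:
    """Read a phenotype CSV (individual_id, population, [sex], variables...)."""
    df = pd.read_csv(path, na_values=_NA_VALUES, keep_default_na=False, dtype={0: str, 1: str})
    if df.columns[0] != "individual_id" or df.columns[1] != "population":
        raise DataError("phenotype CSV must start with individual_id,population columns")
    if df["individual_id"].duplicated().any():
        dup = df["individual_id"][df["individual_id"].duplicated()].iloc[0]
        raise DataError(f"duplicate individual id {dup!r}")
    df = df.set_index("individual_id")
    sex = None
    if "sex" in df.columns:
        sex = df["sex"].where(df["sex"].notna(), "unknown")
        df = df.drop(columns=["sex"])
    pops = df.pop("population")
    try:
        values = df.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError) as exc:
        raise DataError(f"non-numeric phenotype value: {exc}") from exc
    return PhenotypeTable(values, pops, mode=mode, sex_labels=sex)


def write_phenotypes(table: PhenotypeTable, path) -> None:
    out = table.data.copy()
    if table.sex_labels is not None:
        out.insert(0, "sex", table.sex_labels)
    out.insert(0, "population", table.population_labels)
    out.index.name = "individual_id"
    out.to_csv(path, float_format="%.17g")


# ---------------------------------------------------------------------------
# metadata

def read_metadata(path) -> PopulationMetadata:
    df = pd.read_csv(path, na_values=_NA_VALUES, keep_default_na=False, dtype={0: str})
    if df.columns[0] != "population":
        raise DataError("metadata CSV must start with a population column")
    return PopulationMetadata(df.set_index("population"))


def write_metadata(meta: PopulationMetadata, path) -> None:
    out = meta.table[["latitude", "longitude", *CLIMATE_VARS]].copy()
    out.index.name = "population"
    out.to_csv(path, float_format="%.17g")


# ---------------------------------------------------------------------------
# breakpoints

def read_breakpoints(path) -> dict[str, float]:
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["variable_id", "breakpoint"]:
        raise DataError("breakpoint CSV needs variable_id,breakpoint columns")
    if df["variable_id"].duplicated().any():
        raise DataError("duplicate variable in breakpoint table")
    return dict(zip(df["variable_id"].astype(str), df["breakpoint"].astype(float)))


def write_breakpoints(breakpoints: dict[str, float], path) -> None:
    pd.DataFrame(
        {"variable_id": list(breakpoints), "breakpoint": list(breakpoints.values())}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# distance matrices

def write_distance_matrix(D: DistanceMatrix, path) -> None:
    """Square labelled CSV; values at >=17 significant digits so that
    write-then-read is an identity well past 12 significant digits."""
    df = D.to_frame()
    df.index.name = "population"
    df.to_csv(path, float_format="%.17g")


def read_distance_matrix(path, is_fst: bool = False) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    idx = [str(x) for x in df.index]
    cols = [str(c) for c in df.columns]
    if idx != cols:
        raise DataError("distance matrix row and column labels differ")
    return DistanceMatrix(idx, df.to_numpy(dtype=float), is_fst=is_fst)
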