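"""End-to-end orchestration: simulate (or load) -> preprocess -> distances
-> neutrality -> ordination -> report.

Each stage reads its inputs from, and writes its outputs to, declared file
artifacts under the run directory, so the pipeline is resumable
stage-by-stage.  A run manifest records the config hash, seed, per-stage
counts and artifact checksums; reruns with the same config and seed are
checksum-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as io_mod
from . import __version__
from .distances import (
    PstConfig,
    block_d2,
    climate_distance,
    combined_d2,
    geodesic_distance,
    pst_matrix,
    wc_fst_matrix,
)
from .neutrality import (
    NeutralityDistribution,
    paired_t_tests,
    point_estimate,
    resample_neutrality,
    scheme_loci,
    scheme_population,
    scheme_variables,
    summarize,
)
from .ordination import nmds_3d, procrustes_superimpose, stress_gate
from .preprocess import preprocess_metric, preprocess_nonmetric
from .simulate import BlockSpec, SimulationConfig, simulate_study, write_fixture
from .types import (
    COMBINED,
    MODE_BINARY,
    MODE_GRADED,
    MODE_METRIC,
    ConfigError,
    DataError,
    GenotypeMatrix,
    PhenotypeTable,
    PopulationMetadata,
)

SCHEME_NAMES = ("population", "variables", "loci")


@dataclass
class RunConfig:
    """Everything a pipeline run needs; exactly one of ``simulation`` /
    ``input_dir`` supplies the data."""

    outdir: str
    seed: int = 0
    simulation: SimulationConfig | None = None
    input_dir: str | None = None
    knn_k: int = 5
    apply_size_correction: bool = True
    max_missing_frac: float = 0.5
    sex_filter: str | None = None
    min_n: int | None = None
    covariate: str = "climate"
    fst_aggregation: str = "average_of_ratios"
    n_iterations: int = 1000
    n_variables_subsample: int = 24
    n_loci_subsample: int = 24
    run_schemes: tuple[str, ...] = SCHEME_NAMES
    data_types: tuple[str, ...] | None = None  # None = all blocks + combined
    nmds_restarts: int = 8
    compute_pst: bool = False
    pst_h2: float = 0.5

    def __post_init__(self):
        if (self.simulation is None) == (self.input_dir is None):
            raise ConfigError("provide exactly one of simulation config or input_dir")
        bad = [s for s in self.run_schemes if s not in SCHEME_NAMES]
        if bad:
            raise ConfigError(f"unknown scheme(s) {bad}; valid: {SCHEME_NAMES}")
        if self.input_dir is not None and not Path(self.input_dir).exists():
            raise ConfigError(f"input_dir {self.input_dir!r} does not exist")

    def semantic_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("outdir")
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        d["run_schemes"] = list(self.run_schemes)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.semantic_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        sim = raw.pop("simulation", None)
        if sim is not None:
            blocks = sim.pop("blocks", None)
            if blocks is not None:
                sim["blocks"] = tuple(BlockSpec(**b) for b in blocks)
            sim = SimulationConfig(**sim)
        if "run_schemes" in raw:
            raw["run_schemes"] = tuple(raw["run_schemes"])
        if raw.get("data_types") is not None:
            raw["data_types"] = tuple(raw["data_types"])
        return cls(simulation=sim, **raw)


def fixture_config(outdir: str, seed: int = 0) -> RunConfig:
    """The packaged end-to-end fixture: a reduced synthetic study (12
    populations, 600 loci, 60 resampling iterations) exercising every
    stage in a few minutes on one CPU."""
    sim = SimulationConfig(
        n_populations=12,
        n_loci=600,
        n_genomic_per_population=15,
        n_phenotypic_per_population=30,
        seed=seed,
    )
    return RunConfig(
        outdir=outdir,
        seed=seed,
        simulation=sim,
        n_iterations=60,
        nmds_restarts=4,
    )


# ---------------------------------------------------------------------------
# manifest


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: dict = field(default_factory=dict)
    checksums: dict = field(default_factory=dict)
    started: float = 0.0
    finished: float = 0.0

    def write(self, outdir: Path) -> None:
        (outdir / "manifest.json").write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def artifact_checksums(outdir) -> dict[str, str]:
    """Checksums of every run artifact except the manifest itself (which
    carries timestamps)."""
    out = Path(outdir)
    return {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }


# ---------------------------------------------------------------------------
# data loading


def _block_mode(name: str) -> str:
    return MODE_GRADED if "nonmetric" in name else MODE_METRIC


def read_bundle(path) -> tuple[GenotypeMatrix, dict[str, PhenotypeTable], PopulationMetadata, dict]:
    """Read a fixture bundle directory (tabular genotypes preferred,
    genepop fallback)."""
    p = Path(path)
    if (p / "genotypes.csv").exists():
        geno = io_mod.read_genotypes_csv(p / "genotypes.csv")
    elif (p / "genotypes.gen").exists():
        geno = io_mod.read_genepop(p / "genotypes.gen")
    else:
        raise DataError(f"no genotypes found in {path}")
    metadata = io_mod.read_metadata(p / "metadata.csv")
    breakpoints = (
        io_mod.read_breakpoints(p / "breakpoints.csv")
        if (p / "breakpoints.csv").exists()
        else {}
    )
    blocks = {}
    for f in sorted(p.glob("phenotypes_*.csv")):
        name = f.stem.removeprefix("phenotypes_")
        blocks[name] = io_mod.read_phenotypes(f, mode=_block_mode(name))
    if not blocks:
        raise DataError(f"no phenotype tables found in {path}")
    return geno, blocks, metadata, breakpoints


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: RunConfig) -> dict:
    """Materialise the input data bundle under <outdir>/data."""
    out = Path(config.outdir)
    data_dir = out / "data"
    if config.simulation is not None:
        sim = replace(config.simulation, seed=config.seed)
        study = simulate_study(sim)
        write_fixture(study, data_dir)
        return {
            "source": "simulated",
            "n_populations": sim.n_populations,
            "n_loci": sim.n_loci,
        }
    geno, blocks, metadata, breakpoints = read_bundle(config.input_dir)
    data_dir.mkdir(parents=True, exist_ok=True)
    io_mod.write_genotypes_csv(geno, data_dir / "genotypes.csv")
    io_mod.write_metadata(metadata, data_dir / "metadata.csv")
    if breakpoints:
        io_mod.write_breakpoints(breakpoints, data_dir / "breakpoints.csv")
    for name, tab in blocks.items():
        io_mod.write_phenotypes(tab, data_dir / f"phenotypes_{name}.csv")
    return {"source": config.input_dir, "n_populations": len(metadata.populations)}


def stage_preprocess(config: RunConfig) -> dict:
    """Sparse removal, imputation, size correction / dichotomization."""
    out = Path(config.outdir)
    geno, blocks, metadata, breakpoints = read_bundle(out / "data")
    pre_dir = out / "preprocessed"
    pre_dir.mkdir(parents=True, exist_ok=True)
    counts = {}
    report_rows = []
    for name, tab in blocks.items():
        if config.sex_filter is not None and tab.sex_labels is not None:
            keep = tab.sex_labels == config.sex_filter
            tab = tab.subset_individuals(tab.data.index[keep])
        if tab.mode == MODE_METRIC:
            done, rep = preprocess_metric(
                tab,
                k=config.knn_k,
                max_missing_frac=config.max_missing_frac,
                apply_size_correction=config.apply_size_correction,
            )
        else:
            done, rep = preprocess_nonmetric(
                tab, breakpoints, max_missing_frac=config.max_missing_frac
            )
        io_mod.write_phenotypes(done, pre_dir / f"phenotypes_{name}.csv")
        counts[name] = {
            "n_individuals": len(done.individual_ids),
            "n_dropped": len(rep.dropped_individuals),
            "n_imputed_cells": rep.n_imputed_cells,
        }
        report_rows.append(
            {
                "block": name,
                "dropped_individuals": ";".join(rep.dropped_individuals),
                "n_imputed_cells": rep.n_imputed_cells,
                "imputed_fraction": rep.imputed_fraction,
            }
        )
    pd.DataFrame(report_rows).to_csv(pre_dir / "preprocess_report.csv", index=False)
    return counts


def _load_preprocessed(config: RunConfig):
    out = Path(config.outdir)
    geno, _, metadata, _ = read_bundle(out / "data")
    blocks = {}
    for f in sorted((out / "preprocessed").glob("phenotypes_*.csv")):
        name = f.stem.removeprefix("phenotypes_")
        mode = MODE_BINARY if "nonmetric" in name else MODE_METRIC
        blocks[name] = io_mod.read_phenotypes(f, mode=mode)
    return geno, blocks, metadata


def apply_min_n(
    geno: GenotypeMatrix,
    blocks: dict[str, PhenotypeTable],
    metadata: PopulationMetadata,
    min_n: int | None,
):
    """Subset to populations with at least ``min_n`` genomic and phenotypic
    individuals in every data set (applied before distances)."""
    if min_n is None:
        return geno, blocks, metadata, []
    counts = {p: len(r) for p, r in geno.pop_indices().items()}
    bad = {p for p, c in counts.items() if c < min_n}
    for tab in blocks.values():
        for p, rows in tab.pop_indices().items():
            if len(rows) < min_n:
                bad.add(p)
    keep = [p for p in metadata.populations if p not in bad]
    if len(keep) < 3:
        raise DataError(f"min_n={min_n} retains fewer than 3 populations")
    geno = geno.drop_populations(bad)
    blocks = {n: t.drop_populations(bad) for n, t in blocks.items()}
    return geno, blocks, metadata.subset(keep), sorted(bad)


def stage_distances(config: RunConfig) -> dict:
    out = Path(config.outdir)
    geno, blocks, metadata = _load_preprocessed(config)
    geno, blocks, metadata, excluded_pops = apply_min_n(
        geno, blocks, metadata, config.min_n
    )
    dist_dir = out / "distances"
    dist_dir.mkdir(parents=True, exist_ok=True)
    pops = metadata.populations
    fst, excl = wc_fst_matrix(geno, aggregation=config.fst_aggregation, return_excluded=True)
    io_mod.write_distance_matrix(fst.align(pops), dist_dir / "fst.csv")
    excl.to_csv(dist_dir / "fst_excluded_loci.csv")
    mats, sizes = [], []
    for name, tab in blocks.items():
        D = block_d2(tab).align(pops)
        io_mod.write_distance_matrix(D, dist_dir / f"d2_{name}.csv")
        mats.append(D)
        sizes.append(len(tab.variable_ids))
    if len(mats) > 1:
        io_mod.write_distance_matrix(
            combined_d2(mats, sizes), dist_dir / "d2_combined.csv"
        )
    io_mod.write_distance_matrix(climate_distance(metadata), dist_dir / "climate.csv")
    io_mod.write_distance_matrix(geodesic_distance(metadata), dist_dir / "geodesic.csv")
    if config.compute_pst:
        for name, tab in blocks.items():
            if tab.mode == MODE_METRIC:
                P = pst_matrix(tab, PstConfig(h2=config.pst_h2))
                io_mod.write_distance_matrix(P.align(pops), dist_dir / f"pst_{name}.csv")
    return {"n_populations": len(pops), "excluded_populations": excluded_pops}


def _make_scheme(name: str, config: RunConfig):
    if name == "population":
        return scheme_population(
            config.n_iterations, covariate=config.covariate, master_seed=config.seed
        )
    if name == "variables":
        return scheme_variables(
            config.n_iterations,
            n_variables=config.n_variables_subsample,
            covariate=config.covariate,
            master_seed=config.seed,
        )
    if name == "loci":
        return scheme_loci(
            config.n_iterations,
            n_variables=config.n_variables_subsample,
            n_loci=config.n_loci_subsample,
            covariate=config.covariate,
            master_seed=config.seed,
        )
    raise ConfigError(f"unknown scheme {name!r}")


def stage_neutrality(config: RunConfig) -> dict:
    out = Path(config.outdir)
    geno, blocks, metadata = _load_preprocessed(config)
    geno, blocks, metadata, _ = apply_min_n(geno, blocks, metadata, config.min_n)
    ndir = out / "neutrality"
    ndir.mkdir(parents=True, exist_ok=True)
    if config.data_types is not None:
        data_types = list(config.data_types)
    else:
        data_types = list(blocks) + ([COMBINED] if len(blocks) > 1 else [])
    points = {
        dt: point_estimate(geno, blocks, metadata, dt, config.covariate)
        for dt in data_types
    }
    pd.DataFrame(
        {"data_type": list(points), "r": list(points.values())}
    ).to_csv(ndir / "point_estimates.csv", index=False, float_format="%.17g")
    summary_rows = []
    for scheme_name in config.run_schemes:
        scheme = _make_scheme(scheme_name, config)
        dists = resample_neutrality(geno, blocks, metadata, scheme, data_types)
        long = pd.concat(
            [
                pd.DataFrame(
                    {
                        "data_type": dt,
                        "iteration": np.arange(len(d.r_values)),
                        "r": d.r_values,
                    }
                )
                for dt, d in dists.items()
            ]
        )
        long.to_csv(
            ndir / f"r_values_{scheme_name}.csv", index=False, float_format="%.17g"
        )
        paired_t_tests(dists).to_csv(
            ndir / f"paired_tests_{scheme_name}.csv", index=False, float_format="%.17g"
        )
        for dt, d in dists.items():
            med, lo, hi = summarize(d)
            summary_rows.append(
                {
                    "scheme": scheme_name,
                    "data_type": dt,
                    "median_r": med,
                    "low_2.5": lo,
                    "high_97.5": hi,
                }
            )
    pd.DataFrame(summary_rows).to_csv(
        ndir / "summary.csv", index=False, float_format="%.17g"
    )
    return {"n_data_types": len(data_types), "schemes": list(config.run_schemes)}


def stage_ordination(config: RunConfig) -> dict:
    out = Path(config.outdir)
    dist_dir = out / "distances"
    odir = out / "ordination"
    odir.mkdir(parents=True, exist_ok=True)
    fst = io_mod.read_distance_matrix(dist_dir / "fst.csv", is_fst=True)
    # NMDS needs a nonnegative dissimilarity; shift slightly negative F_ST
    # estimates up to zero (rank order of the informative entries preserved)
    vals = fst.values.copy()
    vals[vals < 0] = 0.0
    from .types import DistanceMatrix

    fst_nn = DistanceMatrix(fst.ids, vals)
    results = {}
    ref = nmds_3d(fst_nn, seed=config.seed, n_restarts=config.nmds_restarts)
    results["fst"] = ref
    stress_rows = [{"matrix": "fst", "stress": ref.stress, "passes_0.15": stress_gate(ref)[0]}]
    proc_rows = []
    for f in sorted(dist_dir.glob("d2_*.csv")):
        name = f.stem.removeprefix("d2_")
        D = io_mod.read_distance_matrix(f)
        res = nmds_3d(D, seed=config.seed, n_restarts=config.nmds_restarts)
        results[name] = res
        stress_rows.append(
            {"matrix": name, "stress": res.stress, "passes_0.15": stress_gate(res)[0]}
        )
        order = [res.population_ids.index(p) for p in ref.population_ids]
        aligned, rss = procrustes_superimpose(ref.coordinates, res.coordinates[order])
        proc_rows.append({"matrix": name, "procrustes_rss": rss})
        pd.DataFrame(
            aligned, index=ref.population_ids, columns=["axis1", "axis2", "axis3"]
        ).to_csv(odir / f"coords_{name}.csv", float_format="%.17g")
    pd.DataFrame(
        ref.coordinates, index=ref.population_ids, columns=["axis1", "axis2", "axis3"]
    ).to_csv(odir / "coords_fst.csv", float_format="%.17g")
    pd.DataFrame(stress_rows).to_csv(odir / "stress.csv", index=False, float_format="%.17g")
    pd.DataFrame(proc_rows).to_csv(odir / "procrustes.csv", index=False, float_format="%.17g")
    return {"n_ordinations": len(results)}


def report(outdir) -> str:
    """Assemble the run's headline tables into a plain-text summary (written
    to <outdir>/report.txt); missing stages appear as explicit gaps."""
    out = Path(outdir)
    lines = ["neutrality estimation run summary", "=" * 34]
    summary = out / "neutrality" / "summary.csv"
    if summary.exists():
        df = pd.read_csv(summary)
        lines.append("\nmedian r (95% interpercentile range) per data type and scheme:")
        for _, row in df.iterrows():
            lines.append(
                f"  {row['scheme']:<12} {row['data_type']:<20} "
                f"{row['median_r']:.3f} ({row['low_2.5']:.3f} to {row['high_97.5']:.3f})"
            )
        best = df.loc[df.groupby("scheme")["median_r"].idxmax()]
        for _, row in best.iterrows():
            lines.append(
                f"  best under {row['scheme']}: {row['data_type']}"
            )
    else:
        lines.append("\n[neutrality summary missing]")
    stress = out / "ordination" / "stress.csv"
    if stress.exists():
        df = pd.read_csv(stress)
        lines.append("\nNMDS stress (threshold 0.15):")
        for _, row in df.iterrows():
            verdict = "ok" if row["passes_0.15"] else "FAIL"
            lines.append(f"  {row['matrix']:<20} {row['stress']:.4f} {verdict}")
    else:
        lines.append("\n[ordination stress table missing]")
    text = "\n".join(lines) + "\n"
    (out / "report.txt").write_text(text)
    return text


def run_pipeline(config: RunConfig) -> RunManifest:
    """Run every stage and write the manifest.  Reruns with the same config
    and seed produce bit-identical artifacts."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config.config_hash(),
        seed=config.seed,
        version=__version__,
        started=time.time(),
    )
    manifest.write(out)
    stages = [
        ("simulate", stage_simulate),
        ("preprocess", stage_preprocess),
        ("distances", stage_distances),
        ("neutrality", stage_neutrality),
        ("ordination", stage_ordination),
    ]
    for name, fn in stages:
        try:
            manifest.stages[name] = fn(config)
        except (ConfigError, DataError) as exc:
            raise type(exc)(f"stage {name}: {exc}") from exc
    report(out)
    manifest.checksums = artifact_checksums(out)
    manifest.finished = time.time()
    manifest.write(out)
    return manifest
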