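import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm, spearmanr

from dpdg.distances import (
    PstConfig,
    climate_distance,
    combined_d2,
    geodesic_distance,
    mahalanobis_matrix,
    metric_d2,
    nonmetric_d2,
    pooled_binary_correlation,
    pst_matrix,
    wc_fst_locus,
    wc_fst_matrix,
)
from dpdg.neutrality import offdiag_vector
from dpdg.preprocess import TraitFrequencyTable, trait_frequencies
from dpdg.types import (
    CLIMATE_VARS,
    DataError,
    DistanceMatrix,
    GenotypeMatrix,
    PhenotypeTable,
    PopulationMetadata,
)
from oracles import pairwise_fst_loop_oracle, wc84_fst_locus_oracle


def _geno_two_pops(pop1, pop2, extra_locus=False):
    genos = list(pop1) + list(pop2)
    labels = ["A"] * len(pop1) + ["B"] * len(pop2)
    ids = [f"x{i}" for i in range(len(genos))]
    cols = np.array(genos, dtype=np.int8)[:, None]
    if extra_locus:
        cols = np.hstack([cols, np.ones_like(cols)])
    loci = [f"L{j}" for j in range(cols.shape[1])]
    return GenotypeMatrix(ids, labels, loci, cols)


def _metric_table(pop_values: dict[str, np.ndarray]) -> PhenotypeTable:
    rows, pops, idx = [], [], []
    for pop, vals in pop_values.items():
        for i, row in enumerate(np.atleast_2d(vals)):
            rows.append(row)
            pops.append(pop)
            idx.append(f"{pop}_{i}")
    data = pd.DataFrame(np.array(rows, float), index=idx)
    data.columns = [f"v{j}" for j in range(data.shape[1])]
    return PhenotypeTable(data, pd.Series(pops, index=idx), mode="metric")


class TestWcFst:
    def test_fixed_difference_is_exactly_one(self):
        geno = _geno_two_pops([2] * 10, [0] * 10)
        assert wc_fst_locus(geno, "L0") == 1.0
        assert wc_fst_matrix(geno).values[0, 1] == 1.0

    def test_shared_monomorphic_locus_is_undefined(self):
        geno = _geno_two_pops([2, 2, 2], [2, 2, 2])
        assert np.isnan(wc_fst_locus(geno, "L0"))

    def test_zero_genotyped_population_is_error(self):
        geno = _geno_two_pops([-1, -1], [0, 1])
        with pytest.raises(DataError, match="zero genotyped"):
            wc_fst_locus(geno, "L0")

    def test_toy_counts_match_component_oracle(self):
        pop1, pop2 = [2, 1, 1, 0], [2, 2, 1, 1]
        geno = _geno_two_pops(pop1, pop2)
        expected = wc84_fst_locus_oracle(pop1, pop2)
        assert wc_fst_locus(geno, "L0") == pytest.approx(expected, abs=1e-12)

    def test_exhaustive_small_samples_match_multiallele_oracle(self):
        """Every two-population genotype configuration with n <= 3 per
        population agrees with an independent per-allele WC84 component
        computation to 1e-12 (undefined estimates agree as NaN)."""
        for n1, n2 in itertools.product((1, 2, 3), repeat=2):
            for pop1 in itertools.product((0, 1, 2), repeat=n1):
                for pop2 in itertools.product((0, 1, 2), repeat=n2):
                    got = wc_fst_locus(_geno_two_pops(pop1, pop2), "L0")
                    want = wc84_fst_locus_oracle(pop1, pop2)
                    if np.isnan(want):
                        assert np.isnan(got)
                    else:
                        assert got == pytest.approx(want, abs=1e-12)

    def test_matrix_matches_per_locus_loop_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n_pops = rng.integers(2, 5)
            n_loci = rng.integers(1, 6)
            n_per = 4
            g = rng.integers(0, 3, size=(n_pops * n_per, n_loci)).astype(np.int8)
            g[rng.random(g.shape) < 0.1] = -1
            # guarantee a defined locus for every pair: every population
            # polymorphic at locus 0
            g[:, 0] = 0
            g[::n_per, 0] = 1
            geno = GenotypeMatrix(
                [f"i{k}" for k in range(len(g))],
                [f"p{k // n_per}" for k in range(len(g))],
                [f"L{j}" for j in range(n_loci)],
                g,
            )
            got = wc_fst_matrix(geno).values
            want = pairwise_fst_loop_oracle(geno)
            np.testing.assert_allclose(got, want, atol=1e-13)

    def test_locus_order_invariance(self, small_study):
        geno = small_study.genotypes
        perm = np.random.default_rng(0).permutation(geno.n_loci)
        np.testing.assert_allclose(
            wc_fst_matrix(geno).values,
            wc_fst_matrix(geno.subset_loci(perm)).values,
            atol=1e-12,
        )

    def test_matrix_shape_and_symmetry(self, small_study):
        D = wc_fst_matrix(small_study.genotypes)
        assert D.n == 10
        np.testing.assert_array_equal(D.values, D.values.T)
        np.testing.assert_array_equal(np.diag(D.values), 0.0)

    def test_ratio_of_sums_aggregation_available(self):
        geno = _geno_two_pops([2] * 5 + [1], [0] * 5 + [1], extra_locus=True)
        avg = wc_fst_matrix(geno, aggregation="average_of_ratios").values[0, 1]
        ros = wc_fst_matrix(geno, aggregation="ratio_of_sums").values[0, 1]
        assert np.isfinite(avg) and np.isfinite(ros)
        assert avg != ros  # the two estimators differ off the boundary


class TestMetricD2:
    def test_single_variable_scalar_formula(self):
        rng = np.random.default_rng(2)
        a = np.exp(rng.normal(0.18, 0.2, 40))  # gmeans around 1.2
        b = np.exp(rng.normal(0.0, 0.2, 40))
        table = _metric_table({"A": a[:, None], "B": b[:, None]})
        D = metric_d2(table)
        gma, gmb = np.exp(np.log(a).mean()), np.exp(np.log(b).mean())
        pooled = (39 * a.var(ddof=1) + 39 * b.var(ddof=1)) / 78
        assert D.values[0, 1] == pytest.approx((gma - gmb) ** 2 / pooled, abs=1e-12)

    def test_identical_populations_give_zero(self):
        rng = np.random.default_rng(3)
        x = np.exp(rng.normal(0, 0.1, (30, 4)))
        table = _metric_table({"A": x, "B": x})
        np.testing.assert_allclose(metric_d2(table).values, 0.0, atol=1e-10)

    def test_per_variable_rescaling_invariance(self):
        rng = np.random.default_rng(4)
        x = np.exp(rng.normal(0, 0.1, (60, 5)))
        pops = {"A": x[:30], "B": x[30:] * 1.05}
        base = metric_d2(_metric_table(pops)).values
        scale = np.array([10.0, 1.0, 0.1, 2.0, 1.0])
        scaled = metric_d2(
            _metric_table({k: v * scale for k, v in pops.items()})
        ).values
        np.testing.assert_allclose(base, scaled, rtol=1e-10, atol=1e-10)

    def test_identity_scatter_reduces_to_squared_euclidean(self):
        rng = np.random.default_rng(5)
        means = rng.normal(size=(4, 3))
        D2 = mahalanobis_matrix(means, np.eye(3))
        diff = means[:, None] - means[None, :]
        np.testing.assert_allclose(D2, (diff**2).sum(-1), atol=1e-12)

    def test_singular_scatter_is_error(self):
        rng = np.random.default_rng(6)
        x = np.exp(rng.normal(0, 0.1, (20, 2)))
        x = np.hstack([x, x[:, :1]])  # duplicated variable
        with pytest.raises(DataError, match="singular"):
            metric_d2(_metric_table({"A": x[:10], "B": x[10:]}))


def _binary_table(values, pops):
    values = np.asarray(values, float)
    idx = [f"i{k}" for k in range(len(values))]
    data = pd.DataFrame(values, index=idx)
    data.columns = [f"t{j}" for j in range(data.shape[1])]
    return PhenotypeTable(data, pd.Series(pops, index=idx), mode="nonmetric-binary")


class TestNonmetricD2:
    def test_single_trait_probit_distance(self):
        p2 = 0.8413447  # Phi(1)
        freqs = TraitFrequencyTable(
            ["A", "B"], ["t0"], np.array([[0.5], [p2]]), np.array([[50], [50]]),
            np.ones((2, 1, 1), dtype=int) * 50,
        )
        binary = _binary_table([[0], [1], [0], [1]], ["A", "A", "B", "B"])
        D = nonmetric_d2(freqs, binary)
        assert D.values[0, 1] == pytest.approx(norm.ppf(p2) ** 2, abs=1e-12)
        assert D.values[0, 1] == pytest.approx(1.0, abs=1e-4)

    def test_equal_frequencies_give_zero_matrix(self):
        rng = np.random.default_rng(7)
        x = rng.integers(0, 2, size=(30, 3)).astype(float)
        table = _binary_table(np.vstack([x, x]), ["A"] * 30 + ["B"] * 30)
        D = nonmetric_d2(trait_frequencies(table), table)
        np.testing.assert_allclose(D.values, 0.0, atol=1e-10)

    def test_presence_absence_relabelling_invariance(self):
        """Replacing p by 1-p flips every probit threshold's sign, which
        cancels in the quadratic form."""
        rng = np.random.default_rng(8)
        vals = (rng.random((90, 5)) < rng.uniform(0.2, 0.8, 5)).astype(float)
        vals[rng.random(vals.shape) < 0.05] = np.nan
        pops = ["A"] * 30 + ["B"] * 30 + ["C"] * 30
        t1 = _binary_table(vals, pops)
        t2 = _binary_table(1.0 - vals, pops)
        D1 = nonmetric_d2(trait_frequencies(t1), t1)
        D2 = nonmetric_d2(trait_frequencies(t2), t2)
        np.testing.assert_allclose(D1.values, D2.values, atol=1e-10)

    def test_boundary_frequency_continuity_keeps_thresholds_finite(self):
        vals = np.array([[1.0]] * 10 + [[0.0]] * 4 + [[1.0]] * 6)
        table = _binary_table(vals, ["A"] * 10 + ["B"] * 10)
        D = nonmetric_d2(trait_frequencies(table), table)
        assert np.isfinite(D.values).all()
        assert D.values[0, 1] > 0

    def test_pooled_correlation_weights_by_pair_counts(self):
        # population B contributes nothing to the (t0, t1) entry: disjoint observation
        a = np.array([[1, 1], [0, 0], [1, 1], [0, 0]], float)
        b = np.array([[1, np.nan], [np.nan, 1]], float)
        table = _binary_table(np.vstack([a, b]), ["A"] * 4 + ["B"] * 2)
        S = pooled_binary_correlation(table)
        assert S[0, 1] == pytest.approx(1.0)


class TestCombinedAndPst:
    def test_weighted_average_of_identical_matrices_is_identity(self):
        D = DistanceMatrix(["a", "b"], np.array([[0.0, 2.0], [2.0, 0.0]]))
        out = combined_d2([D, D, D, D], [37, 28, 24, 25])
        np.testing.assert_allclose(out.values, D.values)

    def test_two_matrix_weighting_arithmetic(self):
        zero = DistanceMatrix(["a", "b"], np.zeros((2, 2)))
        X = DistanceMatrix(["a", "b"], np.array([[0.0, 4.0], [4.0, 0.0]]))
        out = combined_d2([zero, X], [1, 3])
        assert out.values[0, 1] == pytest.approx(3.0)

    def test_label_mismatch_is_error(self):
        A = DistanceMatrix(["a", "b"], np.zeros((2, 2)))
        B = DistanceMatrix(["a", "c"], np.zeros((2, 2)))
        with pytest.raises(DataError, match="labels"):
            combined_d2([A, B], [1, 1])

    def test_pst_scalar_example(self):
        c = 1 / np.sqrt(2)
        table = _metric_table(
            {"A": np.array([[-c], [c]]) + 5, "B": np.array([[1 - c], [1 + c]]) + 5}
        )
        P = pst_matrix(table, PstConfig(h2=1.0))
        assert P.values[0, 1] == pytest.approx(0.25 / 2.25, abs=1e-12)

    def test_pst_monotone_in_inverse_heritability(self):
        rng = np.random.default_rng(9)
        table = _metric_table(
            {"A": rng.normal(5, 1, (12, 3)), "B": rng.normal(6, 1, (12, 3))}
        )
        full = pst_matrix(table, PstConfig(h2=1.0)).values[0, 1]
        half = pst_matrix(table, PstConfig(h2=0.5)).values[0, 1]
        assert half > full

    def test_pst_identical_populations_zero(self):
        x = np.random.default_rng(10).normal(5, 1, (10, 2))
        table = _metric_table({"A": x, "B": x})
        np.testing.assert_allclose(
            pst_matrix(table, PstConfig(h2=1.0)).values, 0.0, atol=1e-12
        )


def _meta(rows: dict[str, list[float]]) -> PopulationMetadata:
    cols = ["latitude", "longitude", *CLIMATE_VARS]
    return PopulationMetadata(
        pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    )


class TestEnvironmentDistances:
    def test_climate_euclidean_pythagorean(self):
        meta = _meta(
            {
                "A": [0, 0, 10, 20, 15, 25, 5],
                "B": [0, 0, 13, 24, 15, 25, 5],
                "C": [0, 0, 10, 20, 15, 25, 5],
            }
        )
        D = climate_distance(meta)
        assert D.values[0, 1] == pytest.approx(5.0)
        assert D.values[0, 2] == 0.0

    def test_climate_variable_permutation_invariance(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(15, 5, (4, 5))
        meta = _meta({f"P{i}": [0, 0, *vals[i]] for i in range(4)})
        perm = [2, 0, 4, 1, 3]
        meta_p = _meta({f"P{i}": [0, 0, *vals[i][perm]] for i in range(4)})
        np.testing.assert_allclose(
            climate_distance(meta).values, climate_distance(meta_p).values
        )

    def test_geodesic_closed_forms(self):
        meta = _meta(
            {
                "origin": [0, 0, 0, 0, 0, 0, 0],
                "antipode": [0, 180, 0, 0, 0, 0, 0],
                "quarter": [0, 90, 0, 0, 0, 0, 0],
            }
        )
        D = geodesic_distance(meta)
        assert D.values[0, 1] == pytest.approx(np.pi * 6371.0, abs=0.1)
        assert D.values[0, 2] == pytest.approx(np.pi * 6371.0 / 2, abs=0.1)
        assert D.values[0, 0] == 0.0


def test_d2_outputs_are_valid_distance_matrices(small_study, small_blocks):
    from dpdg.distances import block_d2

    for name, tab in small_blocks.items():
        D = block_d2(tab)
        assert (D.values >= 0).all()
        np.testing.assert_array_equal(D.values, D.values.T)
        np.testing.assert_array_equal(np.diag(D.values), 0.0)


def test_monotone_recovery_along_serial_path():
    """With divergence accumulating along the serial path, both F_ST and the
    neutral-phenotype D2 increase with path separation."""
    from dpdg.distances import block_d2, combined_d2
    from dpdg.simulate import SimulationConfig, default_blocks, simulate_study
    from conftest import prepare_blocks

    study = simulate_study(
        SimulationConfig(
            seed=3, missingness=0.0, blocks=default_blocks(h2=(1, 1, 1, 1), beta=(0, 0, 0, 0))
        )
    )
    pops = study.metadata.populations
    K = len(pops)
    sep = np.abs(np.arange(K)[:, None] - np.arange(K)[None, :])
    sep_off = sep[np.tril_indices(K, -1)]
    fst_off = offdiag_vector(wc_fst_matrix(study.genotypes), pops)
    blocks = prepare_blocks(study)
    mats = [block_d2(t) for t in blocks.values()]
    D = combined_d2(mats, [len(t.variable_ids) for t in blocks.values()])
    d2_off = offdiag_vector(D, pops)
    assert spearmanr(fst_off, sep_off).statistic > 0.8
    assert spearmanr(d2_off, sep_off).statistic > 0.8
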