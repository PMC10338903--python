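import numpy as np
import pytest

from dpdg.neutrality import (
    NeutralityDistribution,
    ResamplingScheme,
    offdiag_vector,
    paired_t_tests,
    partial_pearson_r,
    pearson_r,
    point_estimate,
    resample_neutrality,
    scheme_loci,
    scheme_point,
    scheme_population,
    scheme_variables,
    summarize,
)
from dpdg.types import COMBINED, ConfigError, DataError, DistanceMatrix
from oracles import partial_corr_closed_form


class TestOffdiag:
    def test_lengths(self):
        rng = np.random.default_rng(0)
        for m, expected in [(3, 3), (26, 325)]:
            v = rng.random((m, m))
            v = v + v.T
            np.fill_diagonal(v, 0)
            D = DistanceMatrix([f"p{i}" for i in range(m)], v)
            assert len(offdiag_vector(D, D.ids)) == expected

    def test_label_alignment_pairs_entries(self):
        v = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
        D = DistanceMatrix(["a", "b", "c"], v)
        # row-major lower triangle in (c, a, b) order: (a,c), (b,c), (b,a)
        np.testing.assert_allclose(offdiag_vector(D, ["c", "a", "b"]), [2.0, 3.0, 1.0])

    def test_missing_label_is_error(self):
        D = DistanceMatrix(["a", "b"], np.zeros((2, 2)))
        with pytest.raises(DataError):
            offdiag_vector(D, ["a", "z"])


class TestCorrelations:
    def test_pearson_exact_cases(self):
        x = np.array([1.0, 2.0, 3.0])
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)
        assert pearson_r(x, np.array([1.0, 3.0, 2.0])) == pytest.approx(0.5)

    def test_pearson_zero_variance_is_error(self):
        with pytest.raises(DataError, match="zero variance"):
            pearson_r(np.ones(5), np.arange(5.0))

    def test_partial_matches_closed_form_on_random_triples(self, rng):
        for _ in range(200):
            x, y, z = rng.normal(size=(3, 30))
            got = partial_pearson_r(x, y, z)
            assert got == pytest.approx(partial_corr_closed_form(x, y, z), abs=1e-10)

    def test_orthogonal_covariate_reduces_to_plain_pearson(self, rng):
        x = rng.normal(size=64)
        y = rng.normal(size=64)
        z = rng.normal(size=64)
        # project the covariate out of both variables, then the partial and
        # plain correlations coincide
        for v in (x, y):
            v -= np.polyval(np.polyfit(z, v, 1), z)
        assert partial_pearson_r(x, y, z) == pytest.approx(pearson_r(x, y), abs=1e-10)

    def test_variable_equal_to_covariate_is_degenerate(self):
        z = np.arange(10.0)
        with pytest.raises(DataError, match="degenerate residual"):
            partial_pearson_r(z.copy(), np.random.default_rng(1).normal(size=10), z)


class TestSummarize:
    def test_median_and_percentiles_linear_interpolation(self):
        dist = NeutralityDistribution("x", np.arange(1, 1001) / 1000.0, scheme_point())
        med, lo, hi = summarize(dist)
        assert med == pytest.approx(0.5005)
        assert lo * 1000 == pytest.approx(25.975, abs=1e-9)
        assert hi * 1000 == pytest.approx(975.025, abs=1e-9)

    def test_constant_vector(self):
        dist = NeutralityDistribution("x", np.full(100, 0.3), scheme_point())
        assert summarize(dist) == (0.3, 0.3, 0.3)


class TestPointEstimate:
    def test_covariate_none_equals_plain_pearson(self, small_study, small_blocks):
        from dpdg.distances import block_d2, wc_fst_matrix

        pops = small_study.metadata.populations
        r_none = point_estimate(
            small_study.genotypes, small_blocks, small_study.metadata,
            "cranial_metric", covariate="none",
        )
        dP = offdiag_vector(block_d2(small_blocks["cranial_metric"]), pops)
        dG = offdiag_vector(wc_fst_matrix(small_study.genotypes), pops)
        assert r_none == pytest.approx(pearson_r(dP, dG), abs=1e-14)

    def test_unknown_data_type_rejected(self, small_study, small_blocks):
        with pytest.raises(ConfigError):
            point_estimate(
                small_study.genotypes, small_blocks, small_study.metadata, "nope"
            )


class TestResampling:
    def test_degenerate_scheme_reproduces_point_estimate_bitwise(
        self, small_study, small_blocks
    ):
        scheme = ResamplingScheme(n_iterations=50, master_seed=3)
        out = resample_neutrality(
            small_study.genotypes, small_blocks, small_study.metadata, scheme
        )
        for dt, dist in out.items():
            r0 = point_estimate(
                small_study.genotypes, small_blocks, small_study.metadata, dt
            )
            assert (dist.r_values == r0).all()

    def test_rerun_is_bit_identical(self, small_study, small_blocks):
        scheme = scheme_population(n_iterations=8, master_seed=5)
        a = resample_neutrality(
            small_study.genotypes, small_blocks, small_study.metadata, scheme
        )
        b = resample_neutrality(
            small_study.genotypes, small_blocks, small_study.metadata, scheme
        )
        for dt in a:
            np.testing.assert_array_equal(a[dt].r_values, b[dt].r_values)

    def test_pairing_contract_across_separate_runs(self, small_study, small_blocks):
        """Iteration i consumes identical population-drop and locus-subset
        draws whether data types are resampled together or separately."""
        scheme = scheme_loci(n_iterations=6, n_variables=10, n_loci=40, master_seed=9)
        together = resample_neutrality(
            small_study.genotypes, small_blocks, small_study.metadata, scheme,
            data_types=["cranial_metric", "dental_nonmetric"], log_draws=True,
        )
        for dt in ("cranial_metric", "dental_nonmetric"):
            alone = resample_neutrality(
                small_study.genotypes, small_blocks, small_study.metadata, scheme,
                data_types=[dt], log_draws=True,
            )[dt]
            np.testing.assert_array_equal(alone.r_values, together[dt].r_values)
            drops_alone = [e["dropped_population"] for e in alone.draw_log]
            drops_together = [e["dropped_population"] for e in together[dt].draw_log]
            assert drops_alone == drops_together
        log_a = together["cranial_metric"].draw_log
        log_b = together["dental_nonmetric"].draw_log
        assert [e["loci_subset"] for e in log_a] == [e["loci_subset"] for e in log_b]
        assert [e["dropped_population"] for e in log_a] == [
            e["dropped_population"] for e in log_b
        ]

    def test_population_scheme_produces_spread_around_point_estimate(
        self, small_study, small_blocks
    ):
        scheme = scheme_population(n_iterations=40, master_seed=1)
        out = resample_neutrality(
            small_study.genotypes, small_blocks, small_study.metadata, scheme,
            data_types=[COMBINED],
        )[COMBINED]
        assert out.r_values.std() > 0
        assert np.abs(out.r_values).max() <= 1

    def test_scheme_validation_rejects_oversized_subsamples(
        self, small_study, small_blocks
    ):
        scheme = scheme_variables(n_iterations=2, n_variables=1000, master_seed=0)
        with pytest.raises(ConfigError, match="undersample"):
            resample_neutrality(
                small_study.genotypes, small_blocks, small_study.metadata, scheme
            )


class TestPairedTests:
    def _dist(self, values, scheme, name="x"):
        return NeutralityDistribution(name, np.asarray(values, float), scheme)

    def test_distribution_against_itself(self):
        scheme = scheme_point()
        rng = np.random.default_rng(2)
        vals = rng.uniform(-0.5, 0.5, 100)
        table = paired_t_tests({"a": self._dist(vals, scheme), "b": self._dist(vals, scheme)})
        assert table.loc[0, "t"] == 0.0
        assert table.loc[0, "p"] == 1.0

    def test_constant_offset_reports_underflow_safe_bound(self):
        scheme = scheme_point()
        vals = np.linspace(-0.2, 0.2, 50)
        table = paired_t_tests(
            {"a": self._dist(vals + 0.1, scheme), "b": self._dist(vals, scheme)}
        )
        assert table.loc[0, "p"] <= 5e-324
        assert table.loc[0, "p"] > 0 or table.loc[0, "p"] == 5e-324

    def test_five_types_give_ten_bonferroni_corrected_pairs(self):
        scheme = scheme_point()
        rng = np.random.default_rng(4)
        dists = {f"t{i}": self._dist(rng.uniform(-1, 1, 60), scheme) for i in range(5)}
        table = paired_t_tests(dists)
        assert len(table) == 10
        np.testing.assert_allclose(
            table["p_bonferroni"], np.minimum(1.0, 10 * table["p"])
        )

    def test_mismatched_iteration_counts_rejected(self):
        scheme = scheme_point()
        with pytest.raises(DataError, match="not paired"):
            paired_t_tests(
                {
                    "a": self._dist(np.zeros(10), scheme),
                    "b": self._dist(np.zeros(12), scheme),
                }
            )
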