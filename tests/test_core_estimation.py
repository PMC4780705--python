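import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mhto.core_estimation import (
    AlignmentError,
    DegenerateGenotypeError,
    GenotypeVector,
    PhenotypeMatrix,
    SingularCovarianceError,
    align_samples,
    fit_marginal_models,
    genotype_variance,
    residual_covariance,
    residualize_covariates,
    variance_components,
)
from conftest import make_dataset


def _gv(values):
    return GenotypeVector(np.asarray(values, float), [f"S{i}" for i in range(len(values))])


class TestGenotypeVariance:
    @pytest.mark.parametrize(
        "values,expected",
        [([0, 0, 2, 2], 1.0), ([1, 1, 1, 1], 0.0), ([0, 1, 2], 2.0 / 3.0)],
    )
    def test_population_denominator(self, values, expected):
        assert genotype_variance(_gv(values)) == pytest.approx(expected)

    def test_matches_hwe_binomial_variance(self):
        # 1e5 HWE draws at MAF 0.3: estimator concentrates on 2pq = 0.42
        rng = np.random.default_rng(1)
        g = _gv(rng.binomial(2, 0.3, 100_000))
        assert genotype_variance(g) == pytest.approx(0.42, abs=0.01)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            genotype_variance(GenotypeVector([1.0], ["a"]))


class TestMarginalFits:
    def test_exact_linear_relation_recovered(self):
        x = _gv([0, 1, 2, 0, 1, 2])
        y = PhenotypeMatrix(2.0 * x.values[:, None], x.sample_ids, ["t"])
        fit = fit_marginal_models(y, x)
        assert fit.slopes[0] == pytest.approx(2.0)
        assert np.allclose(fit.residuals, 0.0)

    def test_hand_computed_three_point_slope(self):
        # x=(0,1,2), y=(1,2,4): cov/var = 1.0/(2/3) = 1.5 under the 1/n convention
        x = _gv([0, 1, 2])
        y = PhenotypeMatrix(np.array([[1.0], [2.0], [4.0]]), x.sample_ids, ["t"])
        fit = fit_marginal_models(y, x)
        assert fit.slopes[0] == pytest.approx(1.5)

    def test_null_slope_is_small(self):
        p, g = make_dataset(n=10_000, k=1, seed=3, beta=0.0)
        fit = fit_marginal_models(p, g)
        se = 1.0 / np.sqrt(10_000 * genotype_variance(g))
        assert abs(fit.slopes[0]) < 4 * se

    def test_residual_orthogonality(self, small_dataset):
        p, g = small_dataset
        fit = fit_marginal_models(p, g)
        xc = g.values - g.values.mean()
        n = p.n_samples
        assert np.all(np.abs(fit.residuals.sum(axis=0)) < 1e-8 * n)
        assert np.all(np.abs(fit.residuals.T @ xc) < 1e-8 * n)

    def test_constant_genotype_rejected(self, small_dataset):
        p, _ = small_dataset
        g = GenotypeVector(np.ones(p.n_samples), p.sample_ids)
        with pytest.raises(DegenerateGenotypeError):
            fit_marginal_models(p, g)


class TestResidualCovariance:
    def test_matches_brute_force_double_loop(self, small_dataset):
        fit = fit_marginal_models(*small_dataset)
        vr = residual_covariance(fit)
        n, k = fit.residuals.shape
        brute = np.zeros((k, k))
        for j in range(k):
            for m in range(k):
                brute[j, m] = sum(fit.residuals[i, j] * fit.residuals[i, m] for i in range(n)) / n
        assert np.allclose(vr, brute, atol=1e-12)

    def test_duplicated_traits_give_equal_entries(self):
        p, g = make_dataset(n=100, k=1, seed=9, beta=0.2)
        dup = PhenotypeMatrix(
            np.repeat(p.values, 2, axis=1), p.sample_ids, ["a", "b"]
        )
        vr = residual_covariance(fit_marginal_models(dup, g))
        assert np.allclose(vr, vr[0, 0])

    def test_perfect_fit_zero_matrix(self):
        x = _gv([0.0, 1.0, 2.0, 1.0])
        y = PhenotypeMatrix(np.column_stack([3 * x.values, -x.values]), x.sample_ids, ["a", "b"])
        vr = residual_covariance(fit_marginal_models(y, x))
        assert np.allclose(vr, 0.0, atol=1e-12)


class TestVarianceComponents:
    def test_partition_identities(self, small_vc):
        vc = small_vc
        assert np.array_equal(vc.V_G, vc.var_x * np.outer(vc.beta, vc.beta))
        assert np.array_equal(vc.V_P, vc.V_G + vc.V_R)
        assert np.allclose(vc.V_R, vc.V_R.T)

    def test_vp_diagonal_is_total_trait_variance(self, small_dataset):
        # OLS sum-of-squares identity: V_P diag equals 1/n trait variance
        p, g = small_dataset
        vc = variance_components(p, g)
        total = np.var(p.values, axis=0)
        assert np.allclose(np.diag(vc.V_P), total, rtol=1e-10)

    def test_vp_positive_semidefinite(self):
        for seed in range(5):
            p, g = make_dataset(n=60, k=6, seed=seed, beta=0.1)
            vc = variance_components(p, g)
            assert np.linalg.eigvalsh(vc.V_P)[0] >= -1e-10

    def test_null_beta_means_vg_zero(self):
        x = _gv([0, 1, 2, 0, 1, 2, 0, 1])
        rng = np.random.default_rng(0)
        y0 = rng.standard_normal(8)
        y0 = y0 - np.polyval(np.polyfit(x.values, y0, 1), x.values)  # orthogonal to x
        p = PhenotypeMatrix(y0[:, None], x.sample_ids, ["t"])
        vc = variance_components(p, x)
        assert np.allclose(vc.V_G, 0.0, atol=1e-12)
        assert np.allclose(vc.V_P, vc.V_R)

    def test_duplicate_traits_raise_singularity(self):
        p, g = make_dataset(n=100, k=1, seed=5, beta=0.1)
        dup = PhenotypeMatrix(np.repeat(p.values, 2, axis=1), p.sample_ids, ["a", "b"])
        with pytest.raises(SingularCovarianceError):
            variance_components(dup, g)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        a=st.floats(0.1, 10.0),
        b=st.floats(-5.0, 5.0),
        seed=st.integers(0, 100),
    )
    def test_affine_equivariance(self, a, b, seed):
        """Rescaling trait k by a*y+b scales beta_k by a and row/col k of the matrices."""
        p, g = make_dataset(n=80, k=3, seed=seed, beta=0.2)
        vc = variance_components(p, g)
        y2 = p.values.copy()
        y2[:, 1] = a * y2[:, 1] + b
        vc2 = variance_components(
            PhenotypeMatrix(y2, p.sample_ids, p.trait_names), g
        )
        scale = np.ones(3)
        scale[1] = a
        assert np.allclose(vc2.beta, vc.beta * scale, rtol=1e-8)
        for m, m2 in [(vc.V_R, vc2.V_R), (vc.V_G, vc2.V_G), (vc.V_P, vc2.V_P)]:
            assert np.allclose(m2, np.outer(scale, scale) * m, rtol=1e-8, atol=1e-10)


class TestAlignment:
    def test_intersection_in_phenotype_order(self):
        p, g = make_dataset(n=10, k=2, seed=0)
        g_shuf = GenotypeVector(g.values[::-1], g.sample_ids[::-1])
        p2, g2 = align_samples(p, g_shuf)
        assert p2.sample_ids == p.sample_ids
        assert np.array_equal(g2.values, g.values)

    def test_disjoint_ids_raise(self):
        p, g = make_dataset(n=10, k=2, seed=0)
        g_bad = GenotypeVector(g.values, [f"X{i}" for i in range(10)])
        with pytest.raises(AlignmentError):
            align_samples(p, g_bad)

    def test_unaligned_inputs_rejected_by_fit(self):
        p, g = make_dataset(n=10, k=2, seed=0)
        g_bad = GenotypeVector(g.values, list(reversed(g.sample_ids)))
        with pytest.raises(AlignmentError):
            fit_marginal_models(p, g_bad)


class TestResidualizeCovariates:
    def test_no_covariates_centres_only(self, small_dataset):
        p, g = small_dataset
        p2, g2 = residualize_covariates(p, g, None)
        assert np.allclose(p2.values, p.values - p.values.mean(axis=0))
        assert np.allclose(g2.values, g.values - g.values.mean())

    def test_self_regression_degenerates_genotype(self, small_dataset):
        p, g = small_dataset
        p2, g2 = residualize_covariates(p, g, g.values[:, None])
        assert np.allclose(g2.values, 0.0, atol=1e-10)
        with pytest.raises(DegenerateGenotypeError):
            fit_marginal_models(p2, g2)

    def test_rank_deficient_covariates_raise(self, small_dataset):
        p, g = small_dataset
        c = np.ones((p.n_samples, 2))  # collinear with the intercept
        with pytest.raises(ValueError):
            residualize_covariates(p, g, c)

    def test_confounder_removal_restores_null(self):
        # trait and genotype share a confounder; raw slope is biased,
        # residualised slope is null
        rng = np.random.default_rng(7)
        n = 2000
        u = rng.standard_normal(n)
        x = rng.binomial(2, 0.3, n) + 0.8 * u
        y = 0.5 * u[:, None] + rng.standard_normal((n, 2))
        ids = [f"S{i}" for i in range(n)]
        p = PhenotypeMatrix(y, ids, ["a", "b"])
        g = GenotypeVector(x, ids)
        raw = fit_marginal_models(p, g).slopes
        p2, g2 = residualize_covariates(p, g, u[:, None])
        adj = fit_marginal_models(p2, g2).slopes
        se = 1.0 / np.sqrt(n * genotype_variance(g2))
        assert np.any(np.abs(raw) > 4 * se)
        assert np.all(np.abs(adj) < 4 * se)
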