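"""Group t-maps, seed regression, permutation FWE and dependent correlations."""

import numpy as np
import pytest
from scipy import stats

import latcov as lc


def lmaps_from_array(grid, Y):
    """Wrap an (n_subjects, nx, ny, nz) array as laterality maps."""
    return [
        lc.LateralityMap(grid=grid, values=Y[s], subject_id=f"s{s}")
        for s in range(Y.shape[0])
    ]


class TestGroupMean:
    def test_one_sample_t_hand_calculation(self, even_grid):
        # subject values 1, 2, 3: t = mean / (sd / sqrt(n)) = 2 / (1/sqrt(3))
        Y = np.zeros((3,) + even_grid.dims)
        Y[0, 0, 0, 0], Y[1, 0, 0, 0], Y[2, 0, 0, 0] = 1.0, 2.0, 3.0
        Y += np.random.default_rng(0).standard_normal(Y.shape) * 1e-12  # break zero variance elsewhere
        sm = lc.group_mean_laterality(lmaps_from_array(even_grid, Y))
        assert sm.t[0, 0, 0] == pytest.approx(2.0 * np.sqrt(3.0), rel=1e-9)
        assert sm.df == 2

    def test_zero_variance_voxels_flagged_missing(self, even_grid):
        Y = np.full((4,) + even_grid.dims, 3.0)  # identical everywhere
        sm = lc.group_mean_laterality(lmaps_from_array(even_grid, Y))
        assert np.all(np.isnan(sm.t))
        assert sm.n_zero_variance == np.prod(even_grid.dims)

    def test_null_t_moments_match_t_distribution(self, even_grid, rng):
        # white-noise maps: voxel t values should follow Student t(df)
        n = 10
        Y = rng.standard_normal((n,) + even_grid.dims)
        sm = lc.group_mean_laterality(lmaps_from_array(even_grid, Y))
        t = sm.t[np.isfinite(sm.t)]
        df = n - 1
        assert abs(t.mean()) < 0.15
        assert t.var() == pytest.approx(df / (df - 2), rel=0.25)


class TestCovaryWithSeed:
    def test_exact_linear_relation(self, even_grid):
        Y = np.zeros((4,) + even_grid.dims)
        Y[:, 1, 1, 1] = [2.0, 4.0, 6.0, 8.0]
        Y[:, 2, 2, 2] = [1.0, 1.0, 1.0, 1.0]
        sm = lc.covary_with_seed(lmaps_from_array(even_grid, Y), np.array([1.0, 2, 3, 4]))
        assert sm.effect[1, 1, 1] == pytest.approx(2.0)
        assert np.isposinf(sm.t[1, 1, 1])  # zero residual, perfect fit
        assert sm.effect[2, 2, 2] == pytest.approx(0.0)
        assert sm.t[2, 2, 2] == 0.0
        assert sm.df == 2

    def test_matches_statsmodels_ols(self, even_grid, rng):
        import statsmodels.api as sma

        n = 25
        Y = rng.standard_normal((n,) + even_grid.dims)
        g = rng.standard_normal(n)
        cov = rng.standard_normal((n, 2))
        sm_map = lc.covary_with_seed(lmaps_from_array(even_grid, Y), g, covariates=cov)
        X = sma.add_constant(np.column_stack([g, cov]))
        for voxel in [(0, 0, 0), (3, 2, 1), (7, 5, 5)]:
            fit = sma.OLS(Y[(slice(None), *voxel)], X).fit()
            assert sm_map.effect[voxel] == pytest.approx(fit.params[1], rel=1e-10)
            assert sm_map.t[voxel] == pytest.approx(fit.tvalues[1], rel=1e-10)
        assert sm_map.df == n - 4

    def test_collinear_covariate_named(self, even_grid, rng):
        Y = rng.standard_normal((10,) + even_grid.dims)
        g = rng.standard_normal(10)
        with pytest.raises(ValueError, match="covariate 0"):
            lc.covary_with_seed(lmaps_from_array(even_grid, Y), g, covariates=2.0 * g)

    def test_zero_variance_seed_rejected(self, even_grid, rng):
        Y = rng.standard_normal((5,) + even_grid.dims)
        with pytest.raises(ValueError, match="zero variance"):
            lc.covary_with_seed(lmaps_from_array(even_grid, Y), np.ones(5))

    def test_laterality_slope_equals_hemisphere_difference(self, even_grid, rng):
        # linearity of OLS in the response: slope on the difference map
        # equals left-hemisphere slope minus the homologue's slope
        n = 15
        imgs = [
            lc.ContrastImage(grid=even_grid, values=rng.standard_normal(even_grid.dims))
            for _ in range(n)
        ]
        g = rng.standard_normal(n)
        lmaps = [lc.compute_laterality(i) for i in imgs]
        slope_lat = lc.covary_with_seed(lmaps, g).effect
        slope_img = lc.covary_with_seed(imgs, g).effect
        expected = slope_img - lc.flip_values(even_grid, slope_img)
        assert np.allclose(slope_lat, expected, atol=1e-10)


class TestTtoZ:
    def test_tail_probabilities_match(self):
        df = 80
        for t in [0.5, 1.0, 2.0, 4.0, 6.0, -3.0]:
            z = float(lc.t_to_z(np.array(t), df))
            assert abs(stats.norm.sf(abs(z)) - stats.t.sf(abs(t), df)) < 1e-10
            assert np.sign(z) == np.sign(t)

    def test_monotone(self):
        t = np.linspace(-5, 5, 101)
        z = lc.t_to_z(t, 40)
        assert np.all(np.diff(z) > 0)


class TestFweThreshold:
    def null_maps(self, grid, n, rng):
        return lmaps_from_array(grid, rng.standard_normal((n,) + grid.dims))

    def test_alpha_one_makes_everything_suprathreshold(self, even_grid, rng):
        maps = self.null_maps(even_grid, 12, rng)
        rep = lc.fwe_threshold(
            maps, rng.standard_normal(12), n_permutations=100, alpha=1.0,
            random_state=1,
        )
        assert rep.threshold_t == 0.0
        assert rep.significant.all()

    def test_too_few_permutations_for_alpha(self, even_grid, rng):
        maps = self.null_maps(even_grid, 12, rng)
        with pytest.raises(ValueError, match="permutations"):
            lc.fwe_threshold(maps, rng.standard_normal(12),
                             n_permutations=500, alpha=0.001)

    def test_reproducible_given_seed(self, even_grid, rng):
        maps = self.null_maps(even_grid, 14, rng)
        g = rng.standard_normal(14)
        r1 = lc.fwe_threshold(maps, g, n_permutations=150, random_state=42)
        r2 = lc.fwe_threshold(maps, g, n_permutations=150, random_state=42)
        assert r1.threshold_t == r2.threshold_t
        assert np.array_equal(r1.max_stat_null, r2.max_stat_null)

    def test_planted_effect_detected_null_not(self, even_grid, rng):
        n = 40
        Y = rng.standard_normal((n,) + even_grid.dims)
        g = rng.standard_normal(n)
        Y[:, 1, 2, 3] += 3.0 * g  # strong planted association
        rep = lc.fwe_threshold(lmaps_from_array(even_grid, Y), g,
                               n_permutations=500, random_state=7)
        assert rep.significant[1, 2, 3]
        assert rep.clusters.shape[0] >= 1
        top = rep.clusters.iloc[0]
        assert tuple(even_grid.mm_to_voxel((top.x, top.y, top.z))) == (1, 2, 3)

    def test_freedman_lane_with_covariates_runs(self, even_grid, rng):
        n = 20
        maps = self.null_maps(even_grid, n, rng)
        g = rng.standard_normal(n)
        cov = rng.standard_normal(n)
        rep = lc.fwe_threshold(maps, g, covariates=cov,
                               n_permutations=120, random_state=3)
        assert rep.df == n - 3

    def test_cluster_extent_variant(self, even_grid, rng):
        n = 30
        Y = rng.standard_normal((n,) + even_grid.dims)
        g = rng.standard_normal(n)
        Y[:, 1:4, 1:4, 1:4] += 2.5 * g[:, None, None, None]  # planted cluster
        rep = lc.fwe_threshold(lmaps_from_array(even_grid, Y), g,
                               n_permutations=300, random_state=5,
                               method="cluster")
        assert rep.method == "cluster"
        assert rep.significant[2, 2, 2]


class TestDependentCorrelations:
    @staticmethod
    def oracle_z(r_av, r_bv, r_ab, n):
        """Separately coded Meng-Rosenthal-Rubin formula."""
        import math

        z1 = 0.5 * math.log((1 + r_av) / (1 - r_av))
        z2 = 0.5 * math.log((1 + r_bv) / (1 - r_bv))
        rbar2 = (r_av**2 + r_bv**2) / 2
        f = (1 - r_ab) / (2 * (1 - rbar2))
        f = 1.0 if f > 1 else f
        h = (1 - f * rbar2) / (1 - rbar2)
        return (z1 - z2) * math.sqrt((n - 3) / (2 * (1 - r_ab) * h))

    @pytest.mark.parametrize(
        "r1,r2,r12,n",
        [(0.6, 0.3, 0.4, 82), (0.2, -0.5, 0.1, 82), (0.9, 0.85, 0.7, 40)],
    )
    def test_matches_formula_oracle(self, r1, r2, r12, n):
        assert lc.dependent_corr_z(r1, r2, r12, n) == pytest.approx(
            self.oracle_z(r1, r2, r12, n), abs=1e-6
        )

    def test_antisymmetric_in_seed_order(self, even_grid, rng):
        n = 30
        maps = lmaps_from_array(even_grid, rng.standard_normal((n,) + even_grid.dims))
        a, b = rng.standard_normal(n), rng.standard_normal(n)
        z_ab = lc.compare_seed_correlations(maps, a, b, voxel=(1, 1, 1))
        z_ba = lc.compare_seed_correlations(maps, b, a, voxel=(1, 1, 1))
        assert z_ab == pytest.approx(-z_ba, abs=1e-12)

    def test_identical_seeds_give_zero(self, even_grid, rng):
        n = 20
        maps = lmaps_from_array(even_grid, rng.standard_normal((n,) + even_grid.dims))
        a = rng.standard_normal(n)
        assert lc.compare_seed_correlations(maps, a, a.copy(), voxel=(2, 2, 2)) == 0.0

    def test_degenerate_correlation_rejected(self):
        with pytest.raises(ValueError, match="Fisher"):
            lc.dependent_corr_z(1.0, 0.3, 0.2, 50)
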