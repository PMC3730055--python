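"""Sphere VOI geometry and principal eigenvariate extraction."""

import numpy as np
import pytest

import latcov as lc
from latcov.seeds import EmptySphereError


def brute_force_sphere(grid, center_mm, diameter_mm):
    """Independent oracle: full-grid distance scan."""
    hits = []
    for i in range(grid.dims[0]):
        for j in range(grid.dims[1]):
            for k in range(grid.dims[2]):
                mm = grid.voxel_to_mm((i, j, k))
                if np.sum((mm - np.asarray(center_mm)) ** 2) <= (diameter_mm / 2) ** 2 + 1e-9:
                    hits.append((i, j, k))
    return sorted(hits)


class TestVoxelsInSphere:
    @pytest.mark.parametrize(
        "center,diameter",
        [
            ((-4.0, 0.0, 0.0), 4.0),   # centered on a voxel: center + 6 faces
            ((-3.0, 1.0, -1.0), 4.0),  # off-lattice center
            ((-4.0, 0.0, 0.0), 7.5),
            ((-5.0, 2.0, 2.0), 2.0),
            ((0.0, 0.0, 0.0), 5.0),    # midline sphere
        ],
    )
    def test_matches_brute_force_scan(self, midline_grid, center, diameter):
        seed = lc.SeedSpec("s", center, diameter)
        got = [tuple(v) for v in lc.voxels_in_sphere(midline_grid, seed)]
        assert got == brute_force_sphere(midline_grid, center, diameter)

    def test_voxel_centered_4mm_sphere_on_2mm_grid(self, midline_grid):
        # 2 mm radius around a voxel center: that voxel plus its 6 face
        # neighbours (at exactly 2 mm, inclusive boundary)
        seed = lc.SeedSpec("s", (-4.0, 0.0, 0.0), 4.0)
        voxels = lc.voxels_in_sphere(midline_grid, seed)
        assert voxels.shape[0] == 7

    def test_tiny_sphere_with_no_center_errors(self, midline_grid):
        seed = lc.SeedSpec("s", (-3.0, 1.0, 1.0), 0.1)  # 1 mm from any center
        with pytest.raises(EmptySphereError, match="diameter"):
            lc.voxels_in_sphere(midline_grid, seed)

    def test_inclusion_monotone_in_diameter(self, midline_grid):
        center = (-3.5, 0.5, 1.0)
        previous = set()
        for d in (2.5, 5.0, 10.0, 20.0):
            got = {tuple(v) for v in lc.voxels_in_sphere(midline_grid, lc.SeedSpec("s", center, d))}
            assert previous <= got
            previous = got


def eigh_oracle(data):
    """Independent full-decomposition oracle: first PC score via the
    eigen-decomposition of the voxel covariance matrix."""
    centered = data - data.mean(axis=0)
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    scores = centered @ v[:, -1]
    return scores * np.sqrt(w[-1]) / (np.linalg.norm(scores) * np.sqrt(data.shape[1]))


class TestPrincipalEigenvariate:
    def test_single_voxel_reduces_to_that_series(self):
        e = lc.principal_eigenvariate(np.array([[1.0], [2.0], [3.0]]))
        assert np.corrcoef(e, [1.0, 2.0, 3.0])[0, 1] == pytest.approx(1.0)

    def test_duplicated_column_correlates_perfectly(self, rng):
        col = rng.standard_normal(30)
        e = lc.principal_eigenvariate(np.column_stack([col, col]))
        assert abs(np.corrcoef(e, col)[0, 1]) == pytest.approx(1.0)

    def test_matches_full_decomposition_oracle(self, rng):
        data = rng.standard_normal((82, 7))
        e = lc.principal_eigenvariate(data)
        oracle = eigh_oracle(data)
        sign = np.sign(np.dot(e, oracle))
        assert np.allclose(e, sign * oracle, atol=1e-8)

    def test_scaling_matches_explained_variance_per_voxel(self, rng):
        data = rng.standard_normal((40, 5))
        e = lc.principal_eigenvariate(data)
        s1 = np.linalg.svd(data - data.mean(axis=0), compute_uv=False)[0]
        assert np.sum(e**2) == pytest.approx(s1**2 / 5, rel=1e-10)

    def test_constant_data_rejected(self):
        with pytest.raises(ValueError, match="no variance"):
            lc.principal_eigenvariate(np.full((10, 4), 3.25))

    def test_invariant_under_voxel_reordering(self, rng):
        data = rng.standard_normal((25, 6))
        e1 = lc.principal_eigenvariate(data)
        e2 = lc.principal_eigenvariate(data[:, ::-1])
        assert np.allclose(e1, e2, atol=1e-10)

    def test_uncentered_sign_follows_subject_dominance(self, rng):
        # uniformly positive VOI values: every score oriented positive
        data = 2.0 + 0.1 * rng.standard_normal((30, 5))
        e = lc.principal_eigenvariate(data, center=False)
        assert np.all(e > 0)


class TestExtractSeedSeries:
    def test_laterality_series_tracks_planted_values(self, rng):
        grid = lc.build_grid((17, 13, 13))
        cfg = lc.CohortConfig(
            regions=[lc.RegionSpec("r", (-8.0, 0.0, 0.0), sigma_mm=4.0)],
            n_subjects=20, noise_sd=0.05, smooth_fwhm_mm=0.0,
            atypical_fraction=0.0, rng_seed=3,
        )
        images, truth = lc.render_cohort(cfg, grid)
        lmaps = [lc.compute_laterality(i) for i in images]
        series = lc.extract_seed_series(lmaps, lc.SeedSpec("r", (-8.0, 0.0, 0.0)))
        r = np.corrcoef(series.values, truth.li[:, 0])[0, 1]
        assert r > 0.99
        assert series.n_voxels_used == 7

    def test_activation_right_mirrors_the_center(self, even_grid):
        values = np.zeros(even_grid.dims)
        grid = even_grid
        left = tuple(grid.mm_to_voxel((-3.0, -1.0, -1.0)))
        right = lc.homologue(grid, left)
        images = []
        for s in range(6):
            v = values.copy()
            v[left] = s  # left series 0..5
            v[right] = 5 - s  # right series 5..0
            images.append(lc.ContrastImage(grid=grid, values=v, subject_id=f"s{s}"))
        seed = lc.SeedSpec("s", (-3.0, -1.0, -1.0), diameter_mm=1.0)
        left_series = lc.extract_seed_series(images, seed, source="activation_left")
        right_series = lc.extract_seed_series(images, seed, source="activation_right")
        subjects = np.arange(6)
        assert np.corrcoef(left_series.values, subjects)[0, 1] == pytest.approx(1.0)
        assert np.corrcoef(right_series.values, subjects)[0, 1] == pytest.approx(-1.0)
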