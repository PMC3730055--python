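"""Synthetic cohort generator: planted truth, rendering, determinism."""

import numpy as np
import pytest

import latcov as lc


def two_region_config(**overrides):
    defaults = dict(
        regions=[
            lc.RegionSpec("seed", (-8.0, 0.0, 0.0), sigma_mm=3.0),
            lc.RegionSpec("target", (-6.0, 6.0, 4.0), sigma_mm=3.0),
        ],
        n_subjects=12,
        rng_seed=7,
    )
    defaults.update(overrides)
    return lc.CohortConfig(**defaults)


class TestSampleLaterality:
    def test_identity_corr_yields_uncorrelated_samples(self):
        cfg = two_region_config(n_subjects=10000, atypical_fraction=0.0)
        truth = lc.sample_laterality(cfg)
        # Monte-Carlo: sampling sd of r at n=1e4 is ~0.01, tolerance 0.03
        assert abs(truth.realized_corr[0, 1]) < 0.03

    def test_perfect_correlation_is_degenerate(self):
        cfg = two_region_config(
            laterality_corr=np.array([[1.0, 1.0], [1.0, 1.0]]), n_subjects=50
        )
        truth = lc.sample_laterality(cfg)
        assert truth.realized_corr[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_deterministic_given_seed(self):
        t1 = lc.sample_laterality(two_region_config())
        t2 = lc.sample_laterality(two_region_config())
        assert np.array_equal(t1.li, t2.li)
        assert np.array_equal(t1.handedness, t2.handedness)

    def test_atypical_fraction_flips_and_attenuates_means(self):
        cfg = two_region_config(
            n_subjects=4000, atypical_fraction=0.5, laterality_sd=0.0
        )
        truth = lc.sample_laterality(cfg)
        atypical = truth.handedness == "atypical"
        assert atypical.sum() == 2000
        assert np.allclose(truth.li[~atypical, 0], 1.0)
        assert np.allclose(truth.li[atypical, 0], -0.5)  # negated, attenuated

    def test_non_psd_correlation_rejected_before_sampling(self):
        bad = np.array([[1.0, 0.9, 0.0], [0.9, 1.0, 0.9], [0.0, 0.9, 1.0]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            lc.CohortConfig(
                regions=[
                    lc.RegionSpec("a", (-8.0, 0.0, 0.0)),
                    lc.RegionSpec("b", (-6.0, 6.0, 0.0)),
                    lc.RegionSpec("c", (-6.0, -6.0, 0.0)),
                ],
                laterality_corr=bad,
            )


class TestRenderCohort:
    def grid(self):
        return lc.build_grid((17, 13, 13))

    def test_zero_li_zero_noise_is_mirror_symmetric(self):
        cfg = two_region_config(
            n_subjects=1, laterality_mean=0.0, laterality_sd=0.0,
            noise_sd=0.0, atypical_fraction=0.0,
        )
        grid = self.grid()
        images, _ = lc.render_cohort(cfg, grid)
        vol = images[0].values
        assert np.allclose(vol, lc.flip_values(grid, vol), atol=1e-12)
        assert np.allclose(lc.compute_laterality(images[0]).values, 0.0, atol=1e-12)

    def test_left_increase_split_puts_difference_on_the_left(self):
        # tight blob: the mirrored tail at 16 mm is ~1e-14 of the amplitude
        cfg = two_region_config(
            regions=[lc.RegionSpec("r", (-8.0, 0.0, 0.0), sigma_mm=2.0)],
            n_subjects=1, laterality_mean=1.5, laterality_sd=0.0,
            left_increase_fraction=1.0, atypical_fraction=0.0,
            noise_sd=0.0, smooth_fwhm_mm=0.0,
        )
        grid = self.grid()
        images, _ = lc.render_cohort(cfg, grid)
        v = tuple(grid.mm_to_voxel((-8.0, 0.0, 0.0)))
        h = lc.homologue(grid, v)
        base = cfg.regions[0].base_amplitude
        assert images[0].values[v] == pytest.approx(base + 1.5, abs=1e-9)
        assert images[0].values[h] == pytest.approx(base, abs=1e-9)

    def test_right_decrease_split_reduces_the_right_peak(self):
        cfg = two_region_config(
            regions=[lc.RegionSpec("r", (-8.0, 0.0, 0.0), sigma_mm=2.0)],
            n_subjects=1, laterality_mean=1.5, laterality_sd=0.0,
            left_increase_fraction=0.0, atypical_fraction=0.0,
            noise_sd=0.0, smooth_fwhm_mm=0.0,
        )
        grid = self.grid()
        images, _ = lc.render_cohort(cfg, grid)
        v = tuple(grid.mm_to_voxel((-8.0, 0.0, 0.0)))
        h = lc.homologue(grid, v)
        base = cfg.regions[0].base_amplitude
        assert images[0].values[v] == pytest.approx(base, abs=1e-9)
        assert images[0].values[h] == pytest.approx(base - 1.5, abs=1e-9)

    def test_smoothing_preserves_mirror_symmetry(self):
        cfg = two_region_config(
            n_subjects=1, laterality_mean=0.0, laterality_sd=0.0,
            noise_sd=0.0, smooth_fwhm_mm=6.0, atypical_fraction=0.0,
        )
        grid = self.grid()
        images, _ = lc.render_cohort(cfg, grid)
        vol = images[0].values
        assert np.allclose(vol, lc.flip_values(grid, vol), atol=1e-12)

    def test_rendering_deterministic_given_seed(self):
        grid = self.grid()
        a, _ = lc.render_cohort(two_region_config(n_subjects=3), grid)
        b, _ = lc.render_cohort(two_region_config(n_subjects=3), grid)
        for ia, ib in zip(a, b):
            assert np.array_equal(ia.values, ib.values)

    def test_truncated_blob_warns(self):
        grid = lc.build_grid((8, 6, 6))  # spans only +/-7 mm
        cfg = two_region_config(
            regions=[lc.RegionSpec("big", (-4.0, 0.0, 0.0), sigma_mm=6.0)],
            n_subjects=1,
        )
        with pytest.warns(UserWarning, match="truncated"):
            lc.render_cohort(cfg, grid)


class TestCohortIO:
    def test_write_read_round_trip(self, tmp_path):
        grid = lc.build_grid((17, 13, 13))
        cfg = two_region_config(n_subjects=3)
        images, truth = lc.render_cohort(cfg, grid)
        lc.write_cohort(images, truth, tmp_path / "cohort")
        back, truth_df = lc.read_cohort(tmp_path / "cohort")
        assert len(back) == 3
        assert np.array_equal(back[1].values, images[1].values)
        assert list(truth_df["handedness"]) == list(truth.handedness)
        assert np.allclose(truth_df[["li_seed", "li_target"]].to_numpy(), truth.li)
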