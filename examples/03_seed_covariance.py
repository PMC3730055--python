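"""Seed-based laterality covariance with permutation FWE correction.

An 82-subject cohort is rendered with a seed region and a target region
whose laterality indices correlate at 0.6 across subjects (plus an
uncorrelated control region).  The seed eigenvariate is extracted from a
4 mm sphere on the laterality maps and regressed against every
left-hemisphere voxel; family-wise error is controlled by max-|t|
permutation (1000 permutations, alpha 0.05).  Expect the seed's own region
and the correlated target among the peaks, and the control region absent.
"""

import numpy as np

import latcov as lc

grid = lc.build_grid((36, 36, 36))
centers = {
    "seed": (-11.0, -11.0, -11.0),
    "target": (-11.0, 11.0, 11.0),
    "control": (-11.0, 11.0, -11.0),
}
corr = np.array([[1.0, 0.6, 0.0], [0.6, 1.0, 0.0], [0.0, 0.0, 1.0]])
config = lc.CohortConfig(
    regions=[lc.RegionSpec(n, c, sigma_mm=8.0) for n, c in centers.items()],
    n_subjects=82, laterality_corr=corr, atypical_fraction=0.0, rng_seed=2024,
)
images, truth = lc.render_cohort(config, grid)
lmaps = [lc.compute_laterality(img) for img in images]

series = lc.extract_seed_series(lmaps, lc.SeedSpec("seed", centers["seed"]))
print(f"seed eigenvariate from {series.n_voxels_used} voxels; "
      f"corr with planted seed LI = "
      f"{np.corrcoef(series.values, truth.li[:, 0])[0, 1]:.3f}")

report = lc.fwe_threshold(lmaps, series, n_permutations=1000,
                          alpha=0.05, random_state=7, mask="left",
                          min_peak_distance_mm=20.0)
print(f"\nFWE |t| threshold: {report.threshold_t:.2f} "
      f"({report.n_voxels_tested} voxels, {report.n_permutations} permutations)")
print("\ntop peaks (MNI mm, peaks separated by >= 20 mm):")
print(report.clusters.head(5).round(3).to_string(index=False))

tv = tuple(grid.mm_to_voxel(centers["target"]))
cv = tuple(grid.mm_to_voxel(centers["control"]))
print(f"\nr at target center : {report.statmap.partial_r()[tv]:.3f} "
      f"(planted latent correlation 0.6, attenuated by voxel noise)")
print(f"r at control center: {report.statmap.partial_r()[cv]:.3f} (planted 0)")
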