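"""Simulate a small lateralized cohort and inspect the planted ground truth.

Renders 12 subjects with two left-hemisphere activation blobs whose
per-subject laterality indices are correlated at 0.7 across subjects, and
prints the planted values.  The printed correlation is the sample
correlation of the planted laterality columns — it fluctuates around 0.7
with n = 12.
"""

import numpy as np

import latcov as lc

grid = lc.build_grid((32, 32, 32))  # 2 mm voxels, +/-31 mm, no midline column
config = lc.CohortConfig(
    regions=[
        lc.RegionSpec("seed", (-11.0, -11.0, 0.0), sigma_mm=6.0),
        lc.RegionSpec("target", (-11.0, 11.0, 4.0), sigma_mm=6.0),
    ],
    n_subjects=12,
    laterality_corr=np.array([[1.0, 0.7], [0.7, 1.0]]),
    rng_seed=42,
)
images, truth = lc.render_cohort(config, grid)

print(truth.to_dataframe().round(3).to_string(index=False))
print(f"\nrealized seed-target LI correlation: {truth.realized_corr[0, 1]:.3f}")
print(f"atypically lateralized subjects: {(truth.handedness == 'atypical').sum()}")
print("Each row is one subject's true laterality (left-minus-right blob")
print("amplitude, arbitrary units) at the two planted regions.")
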