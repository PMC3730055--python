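# Methods

This note documents the models, conventions and numerical choices behind
`latcov`, and what the simulation-based tests do and do not establish.

## Input contract: symmetric space

All volumes live on a `SymmetricGrid`: a voxel lattice whose x sampling is
mirror-symmetric about the MNI mid-sagittal plane, so every voxel has an
exact homologue at (−x, y, z) (grids with an x = 0 column have a
self-homologous midline).  Spatial normalization to such a space — with a
symmetric template, so that left and right activation are directly
comparable — is upstream of this package; inputs that violate the
symmetry contract are rejected rather than resampled.  The homologue map
is computed through the affine, not by blind array flipping, so any
axis-aligned x orientation works; affines that mix x with y/z are rejected
(the mirror of a voxel center would fall between voxels).  Voxel indexing
is 0-based internally; every user-facing coordinate is MNI mm.

Missing data is NaN in files and in memory.  Any derived pairwise quantity
(laterality, signs, CL) is missing whenever either member of a homologue
pair is missing, which keeps antisymmetry exact under one-sided masks.

## Laterality maps

The default laterality map is the plain difference
LI(v) = β(v) − β(h(v)): the voxel-wise task-by-hemisphere interaction,
linear in the inputs, in the same units as the contrast estimates.  A
normalized variant (β(v) − β(h(v))) / (|β(v)| + |β(h(v))| + ε), ε = 1e-6,
bounds values like classical (L−R)/(L+R) indices; it is provided for
comparison but is nonlinear, noisier where activation is weak, and not
used by downstream defaults.  Laterality maps are not re-smoothed; input
smoothing is treated as an upstream preprocessing property.

Signed maps threshold LI at zero: +1 left-dominant, −1 right-dominant.
Exact zeros get a tie code 0 — on real continuous estimates ties have
measure zero, but constructed and perfectly symmetric data must behave
deterministically.  Ties are counted, reported, and excluded from CL
numerator and denominator.

## Seed eigenvariates

A seed is a sphere (default diameter 4 mm, i.e. radius 2 mm, inclusive
boundary — 1 to 8 voxels on a 2 mm grid depending on center alignment;
`n_voxels_used` is always reported).  The per-subject summary is the
principal eigenvariate of the subject × voxel matrix, pinned exactly:

* first left singular vector of the (column-centered) matrix;
* scaled so its sum of squares equals s₁²/p (variance explained by the
  first component per voxel) — with one voxel it reduces, up to centering,
  to that voxel's series;
* sign-aligned to correlate non-negatively with the across-voxel mean
  series (falling back to making the largest-magnitude entry positive), so
  results are deterministic across runs and platforms.

Centering is used for regression covariates, where the intercept absorbs
it anyway.  For co-lateralization the *uncentered* eigenvariate is signed
instead: the sign of a centered score flips every subject below the cohort
mean and does not represent that subject's own dominance direction,
whereas the uncentered first component retains the cohort mean mode and
its per-subject sign is interpretable.  A sphere-mean alternative
(`method="mean"`) is available for both uses.

## Across-subject inference

`group_mean_laterality` is the voxel-wise one-sample t against zero.
`covary_with_seed` is voxel-wise OLS on [intercept, seed series, optional
covariates], returning the seed-slope t-map; run on contrast images it
gives the hemisphere-specific decomposition (does a laterality
correlation reflect left increase, right decrease, or both).  t-maps are
converted to signed standard-normal z by matching two-sided tail
probabilities.  Degenerate voxels are handled explicitly: zero-variance
voxels in the group mean are flagged missing and counted; numerically
perfect fits give t = ±inf (or 0 when the slope is itself zero); collinear
designs are rejected naming the offending column.

Family-wise error is controlled by permutation of the seed covariate with
the max-|t| statistic (the paper-conventional parametric random-field
correction is deliberately replaced: permutation is exactly specifiable,
distribution-free, and makes no smoothness assumptions — thresholds are
not expected to match random-field numbers).  Implementation notes:

* With nuisance covariates, Freedman–Lane residualization: both response
  and covariate are residualized against the nuisance design before
  permuting, df = n − 2 − q.
* Internally everything runs on the correlation scale — |t| is strictly
  increasing in |r| at fixed df — so each permutation is one matrix
  product; permutations are processed in chunks to bound memory.
* p_FWE(v) = (1 + #{max|t|ᵦ ≥ |t(v)|}) / (B + 1); a voxel is significant
  when p_FWE ≤ α.  With B = 1000 and α = 0.05 the procedure's exact
  rejection probability under exchangeability is 50/1001 ≈ 0.05.
  At α = 1 the reported threshold is 0 and everything is suprathreshold.
* `method="cluster"` uses max suprathreshold-cluster size at a two-sided
  forming threshold (default p < 0.001) instead of peak height.
* Peak tables use greedy descending-|t| selection with a minimum
  inter-peak distance (default 8 mm, configurable).

Seed-versus-seed comparisons at a voxel use the Meng–Rosenthal–Rubin z for
overlapping dependent correlations (the two correlations share the voxel
series), the standard test for exactly this configuration; identical seed
series return z = 0, |r| = 1 degeneracies raise.

## Co-lateralization

CL(v) = (# subjects with voxel sign = own seed sign, both non-tied) /
(# subjects with both non-tied).  Per-voxel effective counts are reported;
voxels with no informative subject are missing.  Because a subject who
agrees with the seed at v must disagree at h(v), CL(v) + CL(h(v)) = 1
wherever all subjects are informative; the right hemisphere is redundant
but emitted for map completeness.  No inferential test is attached — CL is
a descriptive concordance proportion.

## Synthetic cohorts

The generator emulates subject-level contrast images: Gaussian blobs of
spatial scale σ (default 6 mm, a ~14 mm FWHM cluster) and bilateral base
amplitude 2.0, one per region, per-subject laterality indices drawn from a
multivariate normal across regions (defaults: mean 1.0, SD 0.5, in blob
amplitude units — package conventions), white voxel noise (SD 1.0) and
isotropic Gaussian smoothing (6 mm FWHM, as in conventional single-subject
preprocessing), applied by default after the noise.  Laterality of
magnitude LI at a region is split λ : (1 − λ) between adding to the left
blob and subtracting from the mirrored right blob (default λ = 0.5, both
physiological mechanisms equally), so the left-minus-right difference at
the blob center is LI regardless of the split.  One root seed drives
everything; per-subject noise streams are spawned from it.

Handedness is a mixture: a fraction of subjects (default 0.15, a plausible
rate of atypical language dominance in a cohort with many left-handers) is
"atypical", with the mean LI vector negated and attenuated (default
factor 0.5 — weakly right-dominant, toward bilateral).  The attenuation is
load-bearing: sign concordance between two jointly Gaussian laterality
values is invariant under negating the subject's whole mean vector, so a
pure mirror flip cannot change co-lateralization at all; it is the weaker,
noisier dominance of atypical readers that lowers CL, and the generator
models exactly that.

A second consequence of the mixture, documented because it matters for
experiment design: mixing subjects whose mean vectors differ adds
between-group covariance p(1−p)·Δm² to every region pair, i.e. the
handedness mixture itself correlates all regions across subjects.  The
calibration, recovery and dissociation experiments therefore run with
`atypical_fraction = 0` so that the planted multivariate-normal
correlation is the only across-subject structure; the mixture is varied
only in the handedness experiment.

What the generator does *not* emulate: anatomy (no gray/white contrast, no
folding), physiological and motion noise structure, inter-subject
anatomical variability after normalization, non-Gaussian activation
shapes, and any hemodynamic time-series level.  Passing tests show the
*statistics* behave as specified on data satisfying the model's
assumptions; they do not validate preprocessing or registration on real
cohorts.

## Measurement attenuation

The voxel-wise sample correlation estimates the correlation between
*measured* quantities — the noisy seed eigenvariate and the noisy,
smoothed voxel value — which is systematically below the planted latent
correlation between the regions' true laterality values.  Under the
default conditions (laterality SD 0.5, noise SD 1.0, 6 mm smoothing), the
smoothed laterality-map noise has SD ≈ 0.15 while the blob signal at the
center is ≈ 0.85–0.87 of the latent LI, giving an attenuation factor of
roughly 0.95 per measured variable: a planted ρ = 0.6 yields observed
voxel-level r ≈ 0.53–0.55 at n = 82.  The recovery experiment reports this
measured r and its Fisher-interval coverage of the latent value honestly;
users comparing recovered correlations against planted ones should expect
exactly this disattenuation gap, as they would with real data.

## Problem sizes

The test suite and `scripts/acceptance.py` run the experiments at sizes
chosen to complete comfortably on a single CPU: null calibration on a
24³-voxel grid with 82 subjects, 1000 permutations and 500 (tests) or 250
(script) cohort replicates; correlation recovery on a 36³ grid with 200 /
100 replicates; the three-seed dissociation on a 40³ grid with 12 / 8
replicates; mechanism and handedness experiments with a handful of
replicates each.  All region layouts keep blob tails (3σ) inside the grid,
inter-region leakage below ~1% of amplitude, and centers far enough from
the midline that a blob barely overlaps its own mirror.

## Known limitations

* Oblique affines (x mixed with y/z) are out of scope by design.
* The eigenvariate is pinned as defined above; toolboxes that whiten or
  filter before the SVD will produce (slightly) different seed series.
* Permutation thresholds are not comparable to parametric random-field
  thresholds and depend on the analysis mask.
* CL carries no uncertainty quantification; treat it descriptively.
* The pipeline driver always simulates its cohort; analysis of external
  cohorts uses the library functions or the stage-level CLI directly.
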