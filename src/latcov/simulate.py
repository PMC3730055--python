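"""Synthetic lateralized fMRI cohorts with planted ground truth.

The generator emulates the kind of data the analysis consumes: one contrast
image per subject in a left-right symmetric 2 mm standard space, containing
Gaussian activation blobs at named regions, each blob lateralized by a
per-subject laterality index (LI) drawn from a multivariate normal whose
across-subject correlation structure is specified region-by-region.

Left dominance of magnitude LI at a region is realized as a mixture of the
two physiological mechanisms: a fraction ``lambda`` of the LI is added to
the left blob's amplitude (left increase) and the remaining ``1 - lambda``
is subtracted from the mirrored right blob (right decrease), so the
left-minus-right difference at the blob center is exactly LI regardless of
the split.  White voxel noise and isotropic Gaussian smoothing (default
6 mm FWHM, matching conventional single-subject preprocessing) complete the
forward model.

Handedness enters as a mixture: a fraction of subjects is "atypical", with
every region's mean LI negated and attenuated (weakly right-dominant,
tending toward bilateral).  The attenuation matters: a pure sign flip of
the whole mean vector leaves seed-target sign concordance unchanged (the
agreement probability of a multivariate normal is invariant under jointly
negating its mean), so it cannot lower co-lateralization scores the way
atypically lateralized readers do; weaker, noisier dominance can and does.

Everything is deterministic given ``rng_seed``; per-subject noise streams
are spawned from it so cohorts are reproducible subject-by-subject.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .volume import ContrastImage, SymmetricGrid, write_volume, read_volume

__all__ = [
    "RegionSpec",
    "CohortConfig",
    "GroundTruth",
    "sample_laterality",
    "render_cohort",
    "write_cohort",
    "read_cohort",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class RegionSpec:
    """A lateralized activation site, specified on the left (x < 0).

    ``sigma_mm`` is the spatial scale of the Gaussian blob (6 mm, i.e. a
    ~14 mm FWHM activation cluster, by default); ``base_amplitude`` is the
    bilateral mean activation in the same arbitrary units as the images.
    """

    name: str
    center_mm: tuple[float, float, float]
    sigma_mm: float = 6.0
    base_amplitude: float = 2.0

    def __post_init__(self) -> None:
        if self.center_mm[0] >= 0:
            raise ValueError(
                f"region {self.name!r}: center_mm has x = {self.center_mm[0]} "
                ">= 0; regions are specified in the left hemisphere"
            )
        if self.sigma_mm <= 0:
            raise ValueError(f"region {self.name!r}: sigma_mm must be positive")


@dataclass
class CohortConfig:
    """Full generative description of one synthetic cohort.

    Defaults describe a cohort of 82 subjects with mean LI 1.0, SD 0.5
    (package conventions, in blob amplitude units), voxel noise SD 1.0,
    6 mm FWHM smoothing, the left-increase/right-decrease split at 0.5
    (both mechanisms contribute equally) and 15% atypically lateralized
    subjects.
    """

    regions: list[RegionSpec]
    n_subjects: int = 82
    laterality_mean: float | list[float] = 1.0
    laterality_sd: float | list[float] = 0.5
    laterality_corr: np.ndarray | None = None
    left_increase_fraction: float | list[float] = 0.5
    atypical_fraction: float = 0.15
    atypical_attenuation: float = 0.5
    noise_sd: float = 1.0
    smooth_fwhm_mm: float = 6.0
    smooth_order: str = "after_noise"  # or "before_noise"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        for frac_name in ("atypical_fraction", "atypical_attenuation"):
            v = getattr(self, frac_name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{frac_name} must lie in [0, 1], got {v}")
        for lam in np.atleast_1d(self.left_increase_fraction):
            if not 0.0 <= lam <= 1.0:
                raise ValueError("left_increase_fraction must lie in [0, 1]")
        if self.smooth_order not in ("after_noise", "before_noise"):
            raise ValueError("smooth_order must be 'after_noise' or 'before_noise'")
        if self.laterality_corr is not None:
            C = np.asarray(self.laterality_corr, dtype=float)
            r = len(self.regions)
            if C.shape != (r, r):
                raise ValueError(f"laterality_corr must be {r}x{r}")
            if not np.allclose(C, C.T, atol=1e-10):
                raise ValueError("laterality_corr must be symmetric")
            if not np.allclose(np.diag(C), 1.0, atol=1e-10):
                raise ValueError("laterality_corr must have unit diagonal")
            if np.linalg.eigvalsh(C).min() < -1e-8:
                raise ValueError("laterality_corr is not positive semi-definite")
            self.laterality_corr = C

    def _per_region(self, value) -> np.ndarray:
        out = np.broadcast_to(np.asarray(value, dtype=float), (len(self.regions),))
        return np.array(out)

    @property
    def region_names(self) -> list[str]:
        return [r.name for r in self.regions]


@dataclass
class GroundTruth:
    """Planted per-subject truth returned alongside every rendered cohort."""

    region_names: list[str]
    li: np.ndarray  # (n_subjects, n_regions) true laterality values
    handedness: np.ndarray  # 'typical' / 'atypical' per subject
    realized_corr: np.ndarray  # sample correlation of the planted LI columns
    subject_ids: list[str] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.li, columns=[f"li_{n}" for n in self.region_names])
        df.insert(0, "handedness", self.handedness)
        ids = self.subject_ids or [f"sub-{i:03d}" for i in range(len(df))]
        df.insert(0, "subject_id", ids)
        return df


def _streams(config: CohortConfig):
    """Root-seeded streams: one for LI sampling, one per subject for noise."""
    root = np.random.SeedSequence(config.rng_seed)
    children = root.spawn(config.n_subjects + 1)
    return children[0], children[1:]


def sample_laterality(config: CohortConfig) -> GroundTruth:
    """Draw per-subject, per-region true laterality values.

    Subjects are i.i.d. multivariate normal across regions with the
    configured means, SDs and correlation; atypical subjects (a fixed
    rounded fraction, assigned at random positions) have their mean vector
    negated and scaled by ``atypical_attenuation``.
    """
    n, r = config.n_subjects, len(config.regions)
    mean = config._per_region(config.laterality_mean)
    sd = config._per_region(config.laterality_sd)
    C = config.laterality_corr if config.laterality_corr is not None else np.eye(r)
    cov = C * np.outer(sd, sd)
    rng = np.random.default_rng(_streams(config)[0])

    n_atypical = int(round(config.atypical_fraction * n))
    handed = np.array(["typical"] * n, dtype=object)
    atypical_idx = rng.choice(n, size=n_atypical, replace=False)
    handed[atypical_idx] = "atypical"

    # sample via eigen-decomposition so degenerate (corr = 1) cases work
    w, V = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    A = V * np.sqrt(w)
    dev = rng.standard_normal((n, r)) @ A.T
    means = np.tile(mean, (n, 1))
    means[handed == "atypical"] *= -config.atypical_attenuation
    li = means + dev

    if n >= 2 and r >= 1:
        with np.errstate(invalid="ignore", divide="ignore"):
            realized = np.corrcoef(li, rowvar=False).reshape(r, r)
    else:
        realized = np.full((r, r), np.nan)
    return GroundTruth(
        region_names=config.region_names,
        li=li,
        handedness=handed,
        realized_corr=realized,
        subject_ids=[f"sub-{i:03d}" for i in range(n)],
    )


def _region_kernels(config: CohortConfig, grid: SymmetricGrid):
    """Unit-amplitude Gaussian kernels for each region and its mirror."""
    x, y, z = grid.coordinate_arrays()
    kernels = []
    lo = grid.voxel_to_mm((0, 0, 0))
    hi = grid.voxel_to_mm(tuple(d - 1 for d in grid.dims))
    lo, hi = np.minimum(lo, hi), np.maximum(lo, hi)
    for region in config.regions:
        c = np.asarray(region.center_mm, dtype=float)
        for side, center in (("left", c), ("right", c * (-1, 1, 1))):
            if np.any(center - 3 * region.sigma_mm < lo) or np.any(
                center + 3 * region.sigma_mm > hi
            ):
                warnings.warn(
                    f"region {region.name!r} ({side}) extends beyond the grid; "
                    "the blob is truncated",
                    stacklevel=3,
                )
        d2l = (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2
        d2r = (x + c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2
        s2 = 2.0 * region.sigma_mm**2
        kernels.append((np.exp(-d2l / s2), np.exp(-d2r / s2)))
    return kernels


def render_cohort(
    config: CohortConfig, grid: SymmetricGrid
) -> tuple[list[ContrastImage], GroundTruth]:
    """Render the cohort's contrast images and return the planted truth.

    For subject s and region r with true laterality ``LI``, the left blob
    has amplitude ``base + lambda*LI`` and the mirrored right blob
    ``base - (1-lambda)*LI``; white noise of SD ``noise_sd`` is added and
    the volume smoothed with a ``smooth_fwhm_mm`` isotropic Gaussian
    (by default after the noise, as when estimated contrast images are
    smoothed in preprocessing).
    """
    truth = sample_laterality(config)
    kernels = _region_kernels(config, grid)
    lam = config._per_region(config.left_increase_fraction)
    sigmas = tuple(
        config.smooth_fwhm_mm * FWHM_TO_SIGMA / v for v in grid.voxel_size_mm
    )
    _, subject_streams = _streams(config)

    images = []
    for s in range(config.n_subjects):
        vol = np.zeros(grid.dims)
        for r, region in enumerate(config.regions):
            li = truth.li[s, r]
            kl, kr = kernels[r]
            vol += (region.base_amplitude + lam[r] * li) * kl
            vol += (region.base_amplitude - (1.0 - lam[r]) * li) * kr
        if config.smooth_fwhm_mm > 0 and config.smooth_order == "before_noise":
            vol = gaussian_filter(vol, sigmas, mode="nearest")
        if config.noise_sd > 0:
            rng = np.random.default_rng(subject_streams[s])
            vol = vol + rng.normal(0.0, config.noise_sd, size=grid.dims)
        if config.smooth_fwhm_mm > 0 and config.smooth_order == "after_noise":
            vol = gaussian_filter(vol, sigmas, mode="nearest")
        images.append(
            ContrastImage(grid=grid, values=vol, subject_id=truth.subject_ids[s])
        )
    return images, truth


# -- cohort I/O ------------------------------------------------------------


def write_cohort(images, truth: GroundTruth, out_dir) -> Path:
    """Write one NIfTI per subject plus ground-truth TSV and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for img in images:
        p = out / f"{img.subject_id}_contrast.nii"
        write_volume(img, p)
        paths.append(p.name)
    truth.to_dataframe().to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    manifest = {
        "n_subjects": len(images),
        "regions": truth.region_names,
        "volumes": paths,
        "ground_truth": "ground_truth.tsv",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def read_cohort(cohort_dir):
    """Read back a written cohort: (images, ground-truth DataFrame)."""
    cohort_dir = Path(cohort_dir)
    manifest = json.loads((cohort_dir / "manifest.json").read_text())
    images = []
    grid = None
    for name in manifest["volumes"]:
        img = read_volume(cohort_dir / name, grid=grid,
                          subject_id=name.replace("_contrast.nii", ""))
        grid = img.grid
        images.append(img)
    truth = pd.read_csv(cohort_dir / "ground_truth.tsv", sep="\t")
    return images, truth
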