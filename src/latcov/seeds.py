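"""Seed VOI definition and per-subject eigenvariate extraction.

A seed is a small sphere (4 mm diameter by default) around an MNI
coordinate.  For a cohort, the subject-by-voxel matrix of values inside the
sphere is summarized into one number per subject — the principal
eigenvariate — which then serves as the covariate of interest in the
across-subject covariance analysis, or (signed) as the subject's
lateralization direction at the seed.

The eigenvariate is pinned down exactly: the first left singular vector of
the (optionally column-centered) subject-by-voxel matrix, scaled so that
its sum of squares equals the explained variance per voxel
(``s1^2 / n_voxels``), and sign-aligned so that it correlates non-negatively
with the across-voxel mean series.  With a single voxel it reduces (up to
centering) to that voxel's series.  Centering is the default and is the
natural choice for regression covariates (the intercept absorbs it); the
uncentered variant keeps the cohort mean mode, so the sign of each
subject's score is interpretable as that subject's lateralization
direction — which is what co-lateralization needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import SymmetricGrid

__all__ = [
    "SeedSpec",
    "SeedSeries",
    "DEFAULT_SEEDS",
    "voxels_in_sphere",
    "principal_eigenvariate",
    "extract_seed_series",
]


class EmptySphereError(ValueError):
    """No voxel center falls inside the requested sphere."""


@dataclass(frozen=True)
class SeedSpec:
    """A spherical volume of interest: MNI center and sphere diameter (mm)."""

    name: str
    center_mm: tuple[float, float, float]
    diameter_mm: float = 4.0

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError(f"seed {self.name!r}: diameter_mm must be positive")


#: the three ventral occipito-temporal sub-region seeds used throughout:
#: posterior (pvOT), middle (mvOT) and anterior (avOT) vOT.
DEFAULT_SEEDS = (
    SeedSpec("pvOT", (-42.0, -70.0, -10.0)),
    SeedSpec("mvOT", (-44.0, -54.0, -16.0)),
    SeedSpec("avOT", (-44.0, -44.0, -16.0)),
)


@dataclass
class SeedSeries:
    """One scalar per subject extracted from a seed VOI."""

    seed: SeedSpec
    values: np.ndarray
    n_voxels_used: int
    source: str = "laterality"  # laterality | activation_left | activation_right
    method: str = "eigenvariate"
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()


def voxels_in_sphere(grid: SymmetricGrid, seed: SeedSpec) -> np.ndarray:
    """Indices (K, 3), lexicographically ordered, of voxel centers within
    ``diameter_mm / 2`` (inclusive) of the seed center."""
    center = np.asarray(seed.center_mm, dtype=float)
    radius = seed.diameter_mm / 2.0
    # search only the bounding box around the sphere
    inv = np.linalg.inv(grid.affine)
    corners = center + radius * np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
    )
    idx = corners @ inv[:3, :3].T + inv[:3, 3]
    lo = np.maximum(np.floor(idx.min(axis=0)).astype(int) - 1, 0)
    hi = np.minimum(np.ceil(idx.max(axis=0)).astype(int) + 1, np.asarray(grid.dims) - 1)
    if np.any(lo > hi):
        raise EmptySphereError(
            f"seed {seed.name!r}: sphere of diameter {seed.diameter_mm} mm at "
            f"{seed.center_mm} contains no voxel center; increase the diameter"
        )
    ii, jj, kk = np.meshgrid(
        np.arange(lo[0], hi[0] + 1),
        np.arange(lo[1], hi[1] + 1),
        np.arange(lo[2], hi[2] + 1),
        indexing="ij",
    )
    box = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    mm = grid.voxel_to_mm(box)
    inside = ((mm - center) ** 2).sum(axis=1) <= radius**2 + 1e-9
    voxels = box[inside]
    if voxels.shape[0] == 0:
        raise EmptySphereError(
            f"seed {seed.name!r}: sphere of diameter {seed.diameter_mm} mm at "
            f"{seed.center_mm} contains no voxel center; increase the diameter"
        )
    order = np.lexsort((voxels[:, 2], voxels[:, 1], voxels[:, 0]))
    return voxels[order]


def principal_eigenvariate(data: np.ndarray, center: bool = True) -> np.ndarray:
    """First-singular-vector summary of a subject-by-voxel matrix.

    Returns one value per subject (row).  Scale: the sum of squares of the
    output equals ``s1^2 / n_voxels`` (the variance explained by the first
    component, averaged over voxels).  Sign: non-negative correlation with
    the across-voxel mean series; if that alignment is degenerate, the
    largest-magnitude entry is made positive.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be a 2D subject-by-voxel matrix")
    n, p = data.shape
    if n < 2:
        raise ValueError("eigenvariate extraction needs at least 2 subjects")
    if p < 1:
        raise ValueError("eigenvariate extraction needs at least 1 voxel")
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite values inside the VOI")
    work = data - data.mean(axis=0) if center else data
    u, s, _ = np.linalg.svd(work, full_matrices=False)
    scale = np.abs(data).max()
    if s[0] <= max(1.0, scale) * n * p * np.finfo(float).eps:
        raise ValueError("no variance in VOI (constant data)")
    e = u[:, 0] * (s[0] / np.sqrt(p))
    mean_series = data.mean(axis=1)
    align = np.dot(e - e.mean(), mean_series - mean_series.mean())
    if align < 0:
        e = -e
    elif align == 0 and e[np.argmax(np.abs(e))] < 0:
        e = -e
    return e


def _voi_matrix(maps, seed: SeedSpec, source: str) -> tuple[np.ndarray, int]:
    grid = maps[0].grid
    center = np.asarray(seed.center_mm, dtype=float)
    if source == "activation_right":
        center = center * (-1, 1, 1)
    elif source not in ("laterality", "activation_left"):
        raise ValueError(f"unknown source {source!r}")
    voi_seed = SeedSpec(seed.name, tuple(center), seed.diameter_mm)
    voxels = voxels_in_sphere(grid, voi_seed)
    idx = tuple(voxels.T)
    rows = []
    for m in maps:
        if not m.grid.same_grid(grid):
            raise ValueError("maps are not on a common grid")
        rows.append(m.values[idx])
    return np.asarray(rows), voxels.shape[0]


def extract_seed_series(
    maps,
    seed: SeedSpec,
    source: str = "laterality",
    method: str = "eigenvariate",
    center: bool = True,
) -> SeedSeries:
    """Extract one value per subject from a seed VOI across a cohort.

    ``maps`` are laterality maps (``source='laterality'``) or contrast
    images; for ``source='activation_right'`` the seed center is mirrored
    to MNI (-x, y, z) so the same left-hemisphere seed list drives both
    hemisphere-specific analyses.  ``method='mean'`` replaces the
    eigenvariate with the plain mean over sphere voxels.
    """
    matrix, n_voxels = _voi_matrix(maps, seed, source)
    if method == "eigenvariate":
        values = principal_eigenvariate(matrix, center=center)
    elif method == "mean":
        values = matrix.mean(axis=1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return SeedSeries(
        seed=seed,
        values=values,
        n_voxels_used=n_voxels,
        source=source,
        method=method,
        subject_ids=[getattr(m, "subject_id", "") for m in maps],
    )
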