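"""Per-subject voxel-wise laterality maps and signed lateralization maps.

A laterality map codes, at every voxel, the difference between a subject's
task effect at that voxel and at its left-right homologue.  It is therefore
the voxel-wise task-by-hemisphere interaction: positive on the left wherever
the left hemisphere responds more than the right, and antisymmetric by
construction — ``li(v) = -li(h(v))``, zero on the midline.

Two variants are provided.  The default ``difference`` is the plain
difference of contrast estimates, ``li(v) = beta(v) - beta(h(v))``, which is
the interaction reading and keeps the map linear in the input.  The
``normalized`` variant divides by ``|beta(v)| + |beta(h(v))| + eps`` to give
a bounded index akin to classical (L-R)/(L+R) laterality indices; it is
offered for comparison and is not used by downstream defaults.

Thresholding a laterality map at zero gives the per-subject signed
lateralization map (+1 left-dominant, -1 right-dominant at that voxel),
the ingredient of co-lateralization mapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import ContrastImage, HemisphereMask, SymmetricGrid, flip_values

__all__ = ["LateralityMap", "SignedMap", "compute_laterality", "sign_map", "flip_image"]

#: guard against zero denominators in the normalized variant
DEFAULT_EPS = 1e-6

VARIANTS = ("difference", "normalized")


@dataclass
class LateralityMap:
    """Voxel-wise left-minus-homologous-right map for one subject."""

    grid: SymmetricGrid
    values: np.ndarray
    subject_id: str = ""
    variant: str = "difference"


@dataclass
class SignedMap:
    """Per-voxel lateralization sign: +1, -1, 0 (exact tie) or NaN (missing)."""

    grid: SymmetricGrid
    signs: np.ndarray
    subject_id: str = ""
    n_ties: int = 0


def compute_laterality(
    img: ContrastImage,
    mask: HemisphereMask | None = None,
    variant: str = "difference",
    eps: float = DEFAULT_EPS,
) -> LateralityMap:
    """Compute a subject's voxel-based laterality map.

    Missing data propagates pairwise: if either member of a homologue pair
    is NaN (or outside ``mask``), both voxels are NaN in the output, so the
    map stays antisymmetric even with one-sided masks.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
    values = img.values
    if mask is not None:
        if not mask.grid.same_grid(img.grid):
            raise ValueError("mask grid does not match image grid")
        values = np.where(mask.labels > 0, values, np.nan)
    flipped = flip_values(img.grid, values)
    if variant == "difference":
        li = values - flipped
    else:
        with np.errstate(invalid="ignore"):
            li = (values - flipped) / (np.abs(values) + np.abs(flipped) + eps)
    mid = img.grid.midline_index
    if mid is not None:
        # exact zero on the midline even when eps arithmetic leaves -0.0
        li[mid, :, :] = np.where(np.isfinite(li[mid, :, :]), 0.0, np.nan)
    return LateralityMap(grid=img.grid, values=li, subject_id=img.subject_id, variant=variant)


def sign_map(lmap: LateralityMap) -> SignedMap:
    """Threshold a laterality map at zero into a signed +/-1 map.

    Exact zeros (possible on constructed or perfectly symmetric data;
    measure-zero on real estimates) get the tie code 0 and are counted in
    ``n_ties`` over off-midline voxels; downstream co-lateralization
    excludes them from both numerator and denominator.
    """
    signs = np.sign(lmap.values)  # NaN stays NaN
    finite = np.isfinite(lmap.values)
    offmid = np.ones(lmap.grid.dims, dtype=bool)
    mid = lmap.grid.midline_index
    if mid is not None:
        offmid[mid, :, :] = False
    n_ties = int(np.sum((signs == 0) & finite & offmid))
    return SignedMap(grid=lmap.grid, signs=signs, subject_id=lmap.subject_id, n_ties=n_ties)


def flip_image(img: ContrastImage) -> ContrastImage:
    """Transport an image's values to homologous voxels (an involution)."""
    return ContrastImage(
        grid=img.grid,
        values=flip_values(img.grid, img.values),
        subject_id=img.subject_id,
    )
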