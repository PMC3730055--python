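"""Symmetric voxel grids, left-right homologue geometry, and NIfTI volume I/O.

Laterality analysis compares each voxel with its mirror-image (homologue)
voxel at MNI (-x, y, z).  That comparison is only meaningful on a grid whose
x-axis sampling is mirror-symmetric about the mid-sagittal plane x = 0 mm,
i.e. voxel-center x-coordinates come in +/- pairs, optionally with a single
x = 0 (midline) column.  :class:`SymmetricGrid` enforces that contract once,
and every downstream module inherits it.

Voxel indices are 0-based; all user-facing coordinates are MNI millimetres.
The homologue mapping is computed through the affine (coordinate matching),
not by blind array flipping, so any axis-aligned x orientation is handled;
oblique affines (x mixed with y/z) are rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "GridSymmetryError",
    "GridMismatchError",
    "SymmetricGrid",
    "ContrastImage",
    "HemisphereMask",
    "build_grid",
    "homologue",
    "flip_values",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
]

#: integer label convention for hemisphere masks stored as NIfTI
OUTSIDE, LEFT, RIGHT, MIDLINE = 0, 1, 2, 3

_COORD_TOL = 1e-6  # mm; tolerance for matching mirror voxel centers


class GridSymmetryError(ValueError):
    """The voxel lattice is not mirror-symmetric about x = 0 mm."""


class GridMismatchError(ValueError):
    """Volumes in a cohort do not share one grid (dims and affine)."""


@dataclass(frozen=True)
class SymmetricGrid:
    """A voxel lattice mirror-symmetric about the MNI mid-sagittal plane.

    Parameters
    ----------
    dims
        Grid shape ``(nx, ny, nz)``.
    affine
        4x4 voxel-index -> MNI-mm transform.  The x axis must be axis
        aligned (no x/y or x/z mixing) so that mirroring about x = 0 maps
        voxel centers onto voxel centers.
    """

    dims: tuple[int, int, int]
    affine: np.ndarray
    # index along axis 0 of the mirror partner of each x-column
    x_partner: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        if len(dims) != 3 or any(d <= 0 for d in dims):
            raise ValueError(f"dims must be three positive integers, got {self.dims}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if np.any(np.abs(affine[0, 1:3]) > _COORD_TOL) or np.any(
            np.abs(affine[1:3, 0]) > _COORD_TOL
        ):
            raise GridSymmetryError(
                "affine mixes the x axis with y/z (oblique in x); homologue "
                "mapping through the mid-sagittal plane is not defined"
            )
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "x_partner", self._solve_partners())
        self.affine.setflags(write=False)
        self.x_partner.setflags(write=False)

    def _solve_partners(self) -> np.ndarray:
        xs = self.x_coords_mm
        order = {round(float(x) / _COORD_TOL): i for i, x in enumerate(xs)}
        partner = np.empty(self.dims[0], dtype=np.intp)
        for i, x in enumerate(xs):
            key = round(float(-x) / _COORD_TOL)
            if key not in order:
                raise GridSymmetryError(
                    f"grid not mirror-symmetric along x: voxel column at "
                    f"x = {x:+.3f} mm has no partner at {-x:+.3f} mm"
                )
            partner[i] = order[key]
        return partner

    # -- geometry ----------------------------------------------------------

    @property
    def voxel_size_mm(self) -> tuple[float, float, float]:
        return tuple(np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0)))

    @property
    def x_coords_mm(self) -> np.ndarray:
        """MNI x-coordinate of each voxel column along array axis 0."""
        return self.affine[0, 0] * np.arange(self.dims[0]) + self.affine[0, 3]

    @property
    def midline_index(self) -> int | None:
        """Array index of the x = 0 mm column, or None if no voxel sits on it."""
        hits = np.flatnonzero(np.abs(self.x_coords_mm) <= _COORD_TOL)
        return int(hits[0]) if hits.size else None

    def voxel_to_mm(self, voxel) -> np.ndarray:
        """MNI mm coordinate(s) of voxel index triple(s)."""
        v = np.atleast_2d(np.asarray(voxel, dtype=float))
        mm = v @ self.affine[:3, :3].T + self.affine[:3, 3]
        return mm[0] if np.asarray(voxel).ndim == 1 else mm

    def mm_to_voxel(self, mm) -> np.ndarray:
        """Nearest voxel index triple(s) for MNI mm coordinate(s)."""
        m = np.atleast_2d(np.asarray(mm, dtype=float))
        inv = np.linalg.inv(self.affine)
        v = np.rint(m @ inv[:3, :3].T + inv[:3, 3]).astype(np.intp)
        return v[0] if np.asarray(mm).ndim == 1 else v

    def contains_mm(self, mm) -> bool:
        v = self.mm_to_voxel(mm)
        return bool(np.all(v >= 0) and np.all(v < np.asarray(self.dims)))

    def coordinate_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable arrays of the MNI x, y, z coordinate of every voxel."""
        ii = np.arange(self.dims[0]).reshape(-1, 1, 1)
        jj = np.arange(self.dims[1]).reshape(1, -1, 1)
        kk = np.arange(self.dims[2]).reshape(1, 1, -1)
        a = self.affine
        x = a[0, 0] * ii + a[0, 3] + 0.0 * (jj + kk)
        y = a[1, 1] * jj + a[1, 2] * kk + a[1, 3] + 0.0 * (ii + kk)
        z = a[2, 1] * jj + a[2, 2] * kk + a[2, 3] + 0.0 * (ii + jj)
        return x, y, z

    def same_grid(self, other: "SymmetricGrid", tol: float = 1e-4) -> bool:
        return self.dims == other.dims and bool(
            np.allclose(self.affine, other.affine, atol=tol)
        )

    def __eq__(self, other) -> bool:  # dataclass eq on arrays is ambiguous
        return isinstance(other, SymmetricGrid) and self.same_grid(other)

    def __hash__(self) -> int:
        return hash((self.dims, self.affine.tobytes()))


def build_grid(
    dims: tuple[int, int, int],
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0),
    origin_mm: tuple[float, float, float] | None = None,
) -> SymmetricGrid:
    """Construct a :class:`SymmetricGrid` from shape, voxel size and origin.

    ``origin_mm`` is the MNI coordinate of voxel (0, 0, 0).  When omitted the
    grid is centered on (0, 0, 0): with an even number of x columns the
    centers straddle the midline in +/- pairs; with an odd number one column
    sits exactly on x = 0 and is self-homologous.

    Raises
    ------
    GridSymmetryError
        If ``origin_mm`` places the x sampling asymmetrically about 0.
    """
    dims = tuple(int(d) for d in dims)
    vs = tuple(float(s) for s in voxel_size_mm)
    if any(s <= 0 for s in vs):
        raise ValueError(f"voxel_size_mm must be positive, got {voxel_size_mm}")
    if origin_mm is None:
        origin_mm = tuple(-(d - 1) / 2.0 * s for d, s in zip(dims, vs))
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = vs
    affine[:3, 3] = origin_mm
    return SymmetricGrid(dims=dims, affine=affine)


def mni_grid() -> SymmetricGrid:
    """The conventional 2 mm MNI bounding box [-78..78, -112..76, -70..84]."""
    return build_grid((79, 95, 78), (2.0, 2.0, 2.0), (-78.0, -112.0, -70.0))


def homologue(grid: SymmetricGrid, voxel) -> tuple[int, int, int]:
    """Mirror-image voxel: same (y, z), MNI x negated.  An involution."""
    i, j, k = (int(v) for v in voxel)
    if not (0 <= i < grid.dims[0] and 0 <= j < grid.dims[1] and 0 <= k < grid.dims[2]):
        raise IndexError(f"voxel {voxel!r} out of bounds for grid {grid.dims}")
    return (int(grid.x_partner[i]), j, k)


def flip_values(grid: SymmetricGrid, values: np.ndarray) -> np.ndarray:
    """Transport a per-voxel array to homologous voxels (left-right flip)."""
    return np.asarray(values)[grid.x_partner, :, :]


@dataclass
class ContrastImage:
    """One subject's task-vs-baseline effect-size map on a symmetric grid.

    Values are in arbitrary BOLD effect units; voxels outside the analysis
    mask are NaN (explicit missing), never silently zero.
    """

    grid: SymmetricGrid
    values: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.dims:
            raise GridMismatchError(
                f"values shape {self.values.shape} does not match grid {self.grid.dims}"
            )

    @property
    def mask(self) -> np.ndarray:
        """Boolean array of voxels carrying data."""
        return np.isfinite(self.values)


@dataclass
class HemisphereMask:
    """Per-voxel hemisphere labels: 0 outside, 1 left, 2 right, 3 midline."""

    grid: SymmetricGrid
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.shape != self.grid.dims:
            raise GridMismatchError("mask shape does not match grid")
        flipped = flip_values(self.grid, self.labels)
        swapped = self.labels.copy()
        swapped[self.labels == LEFT] = RIGHT
        swapped[self.labels == RIGHT] = LEFT
        if not np.array_equal(flipped, swapped):
            raise ValueError(
                "hemisphere labels are not mirror-consistent: left voxels "
                "must map to right homologues and midline to itself"
            )

    @classmethod
    def from_grid(
        cls, grid: SymmetricGrid, brain: np.ndarray | None = None
    ) -> "HemisphereMask":
        """Label every (in-brain) voxel by the sign of its MNI x coordinate."""
        x = grid.coordinate_arrays()[0] + np.zeros(grid.dims)
        labels = np.where(x < -_COORD_TOL, LEFT, np.where(x > _COORD_TOL, RIGHT, MIDLINE))
        if brain is not None:
            labels = np.where(np.asarray(brain, bool), labels, OUTSIDE)
        return cls(grid=grid, labels=labels.astype(np.uint8))

    def hemisphere(self, side: str) -> np.ndarray:
        code = {"left": LEFT, "right": RIGHT, "midline": MIDLINE, "outside": OUTSIDE}[side]
        return self.labels == code


# -- NIfTI I/O -------------------------------------------------------------


def _grid_from_nifti(img: nib.Nifti1Image, path) -> SymmetricGrid:
    if img.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3D scalar volume, got shape {img.shape} "
            "(4D time series are not valid inputs here)"
        )
    try:
        return SymmetricGrid(dims=tuple(img.shape), affine=img.affine)
    except GridSymmetryError as err:
        raise GridSymmetryError(f"{path}: {err}") from err


def read_volume(
    path, grid: SymmetricGrid | None = None, subject_id: str | None = None
) -> ContrastImage:
    """Read a 3D NIfTI volume as a :class:`ContrastImage`.

    If ``grid`` is given, the file must match it (cohort consistency check);
    otherwise the grid is derived from the file's shape and affine.  NaN
    voxels are preserved as missing.
    """
    img = nib.load(str(path))
    file_grid = _grid_from_nifti(img, path)
    if grid is not None and not grid.same_grid(file_grid):
        raise GridMismatchError(
            f"{path}: grid mismatch with cohort grid "
            f"(file {file_grid.dims} vs expected {grid.dims}, or affines differ)"
        )
    values = np.asarray(img.dataobj, dtype=float)
    sid = subject_id if subject_id is not None else ""
    return ContrastImage(grid=grid or file_grid, values=values, subject_id=sid)


def write_volume(image: ContrastImage, path) -> None:
    """Write a volume as NIfTI-1, float64 so values round-trip bit-exactly."""
    nifti = nib.Nifti1Image(image.values.astype(np.float64), image.grid.affine)
    nib.save(nifti, str(path))


def write_mask(mask: HemisphereMask, path) -> None:
    nifti = nib.Nifti1Image(mask.labels.astype(np.uint8), mask.grid.affine)
    nib.save(nifti, str(path))


def read_mask(path, grid: SymmetricGrid | None = None) -> HemisphereMask:
    img = nib.load(str(path))
    file_grid = _grid_from_nifti(img, path)
    if grid is not None and not grid.same_grid(file_grid):
        raise GridMismatchError(f"{path}: mask grid does not match cohort grid")
    labels = np.asarray(img.dataobj).astype(np.uint8)
    return HemisphereMask(grid=grid or file_grid, labels=labels)
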