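"""Voxel-wise co-lateralization proportion maps.

A significant across-subject correlation in laterality does not by itself
mean two regions lateralize to the same hemisphere.  The co-lateralization
(CL) map answers that directly: at each voxel it is the proportion of
subjects whose lateralization sign at the voxel matches their own
lateralization sign at a seed region — a one-voxel-VOI concordance
statistic.

Ties (exact zero laterality, possible only on constructed or perfectly
symmetric data) are excluded from both numerator and denominator, and the
per-voxel effective count is reported, so CL stays a proportion of
informative subjects.  Because a subject agreeing with the seed at a voxel
necessarily disagrees at its homologue, ``cl(v) + cl(h(v)) = 1`` wherever
subjects are non-tied; right-hemisphere values are redundant but emitted
for map completeness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .laterality import LateralityMap, SignedMap
from .seeds import SeedSpec, extract_seed_series
from .volume import SymmetricGrid

__all__ = ["CoLatMap", "seed_signs", "colat_map", "colat_summary"]


@dataclass
class CoLatMap:
    """Per-voxel proportion of subjects co-lateralizing with a seed."""

    grid: SymmetricGrid
    cl: np.ndarray  # proportion in [0, 1], NaN where no informative subject
    n_effective: np.ndarray  # per-voxel count of non-tied subjects
    seed_name: str = ""


def seed_signs(
    lmaps: list[LateralityMap], seed: SeedSpec, method: str = "eigenvariate"
) -> np.ndarray:
    """Per-subject lateralization direction (+1/-1/0) at a seed VOI.

    The default signs the uncentered principal eigenvariate of the seed
    sphere (cohort-mean mode retained, so the sign is each subject's own
    direction); ``method='mean'`` signs the plain sphere mean instead.
    """
    series = extract_seed_series(
        lmaps, seed, source="laterality", method=method, center=False
    )
    return np.sign(series.values)


def colat_map(
    signed_maps: list[SignedMap], seed_sign_per_subject, seed_name: str = ""
) -> CoLatMap:
    """Proportion of subjects whose voxel sign matches their seed sign.

    A subject contributes to a voxel only when both the voxel sign and the
    seed sign are non-tied and non-missing; voxels with no contributing
    subject are missing (NaN) with ``n_effective = 0``.
    """
    seed_sign = np.asarray(seed_sign_per_subject, dtype=float).ravel()
    if seed_sign.size != len(signed_maps):
        raise ValueError(
            f"seed sign vector has {seed_sign.size} entries for "
            f"{len(signed_maps)} signed maps"
        )
    grid = signed_maps[0].grid
    match = np.zeros(grid.dims)
    n_eff = np.zeros(grid.dims, dtype=np.intp)
    for s, smap in enumerate(signed_maps):
        if not smap.grid.same_grid(grid):
            raise ValueError("signed maps are not on a common grid")
        if seed_sign[s] == 0 or not np.isfinite(seed_sign[s]):
            continue
        v = smap.signs
        usable = np.isfinite(v) & (v != 0)
        n_eff += usable
        match += usable & (v == seed_sign[s])
    with np.errstate(invalid="ignore"):
        cl = np.where(n_eff > 0, match / np.maximum(n_eff, 1), np.nan)
    return CoLatMap(grid=grid, cl=cl, n_effective=n_eff, seed_name=seed_name)


def colat_summary(
    clmap: CoLatMap, peaks_mm, labels: list[str] | None = None
) -> pd.DataFrame:
    """CL at each requested peak plus the whole-map maximum location.

    ``peaks_mm`` is a list of MNI coordinates; out-of-grid peaks raise with
    the offending coordinates listed.
    """
    peaks_mm = [tuple(float(c) for c in p) for p in peaks_mm]
    bad = [p for p in peaks_mm if not clmap.grid.contains_mm(p)]
    if bad:
        raise ValueError(f"peaks outside the grid: {bad}")
    labels = labels if labels is not None else ["" for _ in peaks_mm]
    rows = []
    for label, p in zip(labels, peaks_mm):
        i, j, k = clmap.grid.mm_to_voxel(p)
        rows.append(
            {
                "region": label, "x": p[0], "y": p[1], "z": p[2],
                "cl": float(clmap.cl[i, j, k]),
                "n_effective": int(clmap.n_effective[i, j, k]),
            }
        )
    if np.any(np.isfinite(clmap.cl)):
        flat = np.where(np.isfinite(clmap.cl), clmap.cl, -np.inf)
        imax = np.unravel_index(int(np.argmax(flat)), clmap.grid.dims)
        mm = clmap.grid.voxel_to_mm(imax)
        rows.append(
            {
                "region": "max CL", "x": mm[0], "y": mm[1], "z": mm[2],
                "cl": float(clmap.cl[imax]),
                "n_effective": int(clmap.n_effective[imax]),
            }
        )
    return pd.DataFrame(rows, columns=["region", "x", "y", "z", "cl", "n_effective"])
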