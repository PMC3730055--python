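"""Across-subject voxel-wise inference on laterality (or activation) maps.

Three second-level analyses:

* ``group_mean_laterality`` — one-sample t per voxel against zero, the group
  main effect over voxel-based laterality maps.
* ``covary_with_seed`` — per voxel, ordinary least squares of the map value
  on [intercept, seed covariate, optional nuisance covariates], returning
  the seed-slope t-map (and its signed z equivalent).  Run on laterality
  maps this is the seed-based laterality covariance analysis; run on
  contrast images restricted to one hemisphere it decomposes a laterality
  correlation into its left-increase and right-decrease components.
* ``fwe_threshold`` — family-wise error control by sign/label permutation of
  the seed covariate with the max-|t| statistic (Freedman-Lane residual
  permutation when nuisance covariates are present).  Permutation maxT is
  exactly specifiable and distribution-free; it replaces parametric
  random-field corrections and is not expected to reproduce their numbers.

``compare_seed_correlations`` tests whether a voxel's correlation with one
seed exceeds its correlation with another, using the Meng-Rosenthal-Rubin
z for overlapping dependent correlations (the two correlations share the
voxel variable).

t statistics are converted to standard-normal z deviates by matching
two-sided tail probabilities; reported z values carry the sign of the
slope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .volume import HemisphereMask, SymmetricGrid

logger = logging.getLogger(__name__)

__all__ = [
    "StatMap",
    "ThresholdReport",
    "t_to_z",
    "group_mean_laterality",
    "covary_with_seed",
    "fwe_threshold",
    "compare_seed_correlations",
    "dependent_corr_z",
]


def t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    """Signed standard-normal deviate with the same two-sided tail area."""
    t = np.asarray(t, dtype=float)
    with np.errstate(invalid="ignore"):
        z = np.sign(t) * stats.norm.isf(stats.t.sf(np.abs(t), df))
    # survival function underflow (|t| astronomically large) -> +/- inf
    return z


@dataclass
class StatMap:
    """Per-voxel slope, t and z for one second-level contrast."""

    grid: SymmetricGrid
    t: np.ndarray
    effect: np.ndarray
    df: int
    contrast_label: str = ""
    n_subjects: int = 0
    n_zero_variance: int = 0
    _z: np.ndarray | None = field(default=None, repr=False)

    @property
    def z(self) -> np.ndarray:
        if self._z is None:
            self._z = t_to_z(self.t, self.df)
        return self._z

    def partial_r(self) -> np.ndarray:
        """Correlation equivalent of the t-map: r = t / sqrt(t^2 + df)."""
        with np.errstate(invalid="ignore"):
            return self.t / np.sqrt(self.t**2 + self.df)


def _stack(maps) -> tuple[SymmetricGrid, np.ndarray]:
    grid = maps[0].grid
    for m in maps:
        if not m.grid.same_grid(grid):
            raise ValueError("maps are not on a common grid")
    return grid, np.stack([np.asarray(m.values, dtype=float) for m in maps])


def group_mean_laterality(maps) -> StatMap:
    """One-sample t-map of the group mean against zero.

    Voxels where every subject has the identical value (zero variance) get
    a missing statistic; their count is recorded and logged.
    """
    if len(maps) < 3:
        raise ValueError("group mean needs at least 3 subjects")
    grid, Y = _stack(maps)
    n = Y.shape[0]
    finite = np.all(np.isfinite(Y), axis=0)
    mean = Y.mean(axis=0)
    sd = Y.std(axis=0, ddof=1)
    zero_var = finite & (sd == 0)
    n_zero = int(zero_var.sum())
    if n_zero:
        logger.info("group_mean_laterality: %d zero-variance voxels flagged missing", n_zero)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(finite & ~zero_var, mean / (sd / np.sqrt(n)), np.nan)
    return StatMap(
        grid=grid, t=t, effect=np.where(finite, mean, np.nan), df=n - 1,
        contrast_label="group mean", n_subjects=n, n_zero_variance=n_zero,
    )


def _design(seed_values: np.ndarray, covariates: np.ndarray | None, n: int) -> np.ndarray:
    g = np.asarray(seed_values, dtype=float).ravel()
    if g.size != n:
        raise ValueError(f"seed series length {g.size} != number of maps {n}")
    if g.std() == 0:
        raise ValueError("seed series has zero variance")
    cols = [np.ones(n), g]
    if covariates is not None:
        Z = np.atleast_2d(np.asarray(covariates, dtype=float))
        if Z.shape[0] != n:
            Z = Z.T
        if Z.shape[0] != n:
            raise ValueError("covariates do not match number of subjects")
        cols.extend(Z.T)
    X = np.column_stack(cols)
    # reject rank-deficient designs, naming the first offending column
    for j in range(1, X.shape[1]):
        resid = X[:, j] - X[:, :j] @ np.linalg.lstsq(X[:, :j], X[:, j], rcond=None)[0]
        if np.linalg.norm(resid) <= 1e-10 * max(1.0, np.linalg.norm(X[:, j])):
            name = "seed series" if j == 1 else f"covariate {j - 2}"
            raise ValueError(f"design is collinear: {name} lies in the span of earlier columns")
    return X


def covary_with_seed(
    maps, seed_series, covariates: np.ndarray | None = None, contrast_label: str = ""
) -> StatMap:
    """OLS of each voxel's value on the seed covariate (plus nuisance).

    Returns the t-map for the seed regressor.  Voxels with a perfect fit
    get t = +/-inf (or t = 0 when the slope itself is zero); voxels with
    any missing subject are missing.
    """
    grid, Y = _stack(maps)
    n = Y.shape[0]
    seed_values = getattr(seed_series, "values", seed_series)
    X = _design(seed_values, covariates, n)
    k = X.shape[1]
    if n <= k:
        raise ValueError(f"need more than {k} subjects for {k} regressors")
    df = n - k

    shape = Y.shape[1:]
    Yf = Y.reshape(n, -1)
    finite = np.all(np.isfinite(Yf), axis=0)
    XtXinv = np.linalg.inv(X.T @ X)
    B = XtXinv @ (X.T @ np.where(finite, Yf, 0.0))
    Yz = np.where(finite, Yf, 0.0)
    resid = Yz - X @ B
    rss = (resid**2).sum(axis=0)
    # numerically perfect fits: zero residual up to round-off in |Y|
    yscale2 = np.maximum((Yz**2).sum(axis=0), np.finfo(float).tiny)
    perfect = rss <= 1e-24 * yscale2 * n
    sigma2 = rss / df
    se = np.sqrt(np.maximum(sigma2 * XtXinv[1, 1], 0.0))
    slope = B[1]
    gsd = X[:, 1].std()
    slope_is_zero = np.abs(slope) * gsd <= 1e-10 * np.sqrt(yscale2 / n)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = slope / se
        t = np.where(
            perfect, np.where(slope_is_zero, 0.0, np.sign(slope) * np.inf), t
        )
        slope = np.where(perfect & slope_is_zero, 0.0, slope)
    t[~finite] = np.nan
    slope = np.where(finite, slope, np.nan)
    return StatMap(
        grid=grid, t=t.reshape(shape), effect=slope.reshape(shape), df=df,
        contrast_label=contrast_label or "seed covariance", n_subjects=n,
    )


# -- permutation FWE -------------------------------------------------------


@dataclass
class ThresholdReport:
    """Result of permutation family-wise-error thresholding."""

    method: str
    alpha: float
    voxelwise_p_uncorrected: float
    n_permutations: int
    df: int
    threshold_t: float
    statmap: StatMap
    significant: np.ndarray  # boolean per voxel
    clusters: pd.DataFrame  # peak table: x, y, z, t, z, p_fwe, n_voxels
    max_stat_null: np.ndarray = field(repr=False, default=None)
    n_voxels_tested: int = 0

    @property
    def any_significant(self) -> bool:
        return bool(self.significant.any())

    @property
    def threshold_z(self) -> float:
        return float(t_to_z(np.array(self.threshold_t), self.df))


def _resolve_mask(maps, mask) -> np.ndarray:
    grid = maps[0].grid
    if mask is None:
        return np.ones(grid.dims, dtype=bool)
    if isinstance(mask, HemisphereMask):
        return mask.labels > 0
    if isinstance(mask, str):
        return HemisphereMask.from_grid(grid).hemisphere(mask)
    return np.asarray(mask, dtype=bool)


def _peaks(t_abs_flat, coords_flat_mm, min_distance_mm):
    """Greedy descending-|t| peak selection with a minimum separation."""
    order = np.argsort(t_abs_flat)[::-1]
    kept = []
    for i in order:
        p = coords_flat_mm[i]
        if all(np.sum((p - coords_flat_mm[j]) ** 2) >= min_distance_mm**2 for j in kept):
            kept.append(i)
    return kept


def fwe_threshold(
    maps,
    seed_series,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    covariates: np.ndarray | None = None,
    random_state=None,
    forming_p: float = 0.001,
    method: str = "maxT",
    mask=None,
    min_peak_distance_mm: float = 8.0,
    chunk: int = 250,
) -> ThresholdReport:
    """Permutation family-wise-error control for the seed-slope t-map.

    The seed covariate is permuted across subjects (``n_permutations``
    times; Freedman-Lane residualization against nuisance covariates when
    present) and the maximum |t| over the mask recorded per permutation.
    A voxel is FWE-significant when its permutation p-value
    ``(1 + #{max|t|_perm >= |t|}) / (B + 1)`` is at most ``alpha``.  With
    ``method='cluster'`` the max suprathreshold-cluster size (forming
    threshold ``forming_p``, two-sided) replaces max |t| and whole clusters
    are declared significant.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be at least 100")
    min_b = int(np.ceil(1.0 / alpha)) - 1
    if alpha < 1.0 and n_permutations < min_b:
        raise ValueError(
            f"alpha = {alpha} needs at least {min_b} permutations for a "
            "resolvable p-value"
        )
    if method not in ("maxT", "cluster"):
        raise ValueError("method must be 'maxT' or 'cluster'")

    grid, Y = _stack(maps)
    n = Y.shape[0]
    seed_values = np.asarray(getattr(seed_series, "values", seed_series), dtype=float).ravel()
    X = _design(seed_values, covariates, n)  # validates
    q = X.shape[1] - 2  # number of nuisance covariates
    df = n - 2 - q

    sel = _resolve_mask(maps, mask)
    Yf = Y.reshape(n, -1)
    valid = sel.ravel() & np.all(np.isfinite(Yf), axis=0)

    # Freedman-Lane: residualize response and covariate against nuisance
    if q > 0:
        Z = X[:, [0] + list(range(2, X.shape[1]))]
        H = Z @ np.linalg.inv(Z.T @ Z) @ Z.T
        R = np.eye(n) - H
        g = R @ X[:, 1]
        Yv = R @ Yf[:, valid]
    else:
        g = seed_values - seed_values.mean()
        Yv = Yf[:, valid] - Yf[:, valid].mean(axis=0)
    gnorm = np.linalg.norm(g)
    ynorm = np.linalg.norm(Yv, axis=0)
    nzv = ynorm > 0
    V = int(nzv.sum())
    if V == 0:
        raise ValueError("no valid voxels in mask")
    Yv = Yv[:, nzv] / ynorm[nzv]

    def corr_to_t(r):
        r = np.clip(r, -1.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt(df / np.maximum(1.0 - r**2, 0.0))
        return np.where(np.abs(r) >= 1.0, np.sign(r) * np.inf, t)

    # everything below works on the correlation scale: |t| is a strictly
    # increasing function of |r| at fixed df, so max-|t| ranks = max-|r| ranks
    r_obs = (g @ Yv) / gnorm
    t_obs = corr_to_t(r_obs)
    valid_idx = np.flatnonzero(valid)[nzv]

    if method == "cluster":
        t_form = stats.t.isf(forming_p / 2.0, df)
        r_form = t_form / np.sqrt(t_form**2 + df)

        def max_cluster(r_abs):
            sup = np.zeros(grid.dims, dtype=bool)
            sup.ravel()[valid_idx] = r_abs >= r_form
            lab, nlab = ndimage.label(sup)
            if nlab == 0:
                return 0
            return int(np.max(ndimage.sum_labels(sup, lab, np.arange(1, nlab + 1))))

    rng = np.random.default_rng(random_state)
    B = int(n_permutations)
    max_null = np.empty(B)  # max |r| per permutation
    cluster_null = np.empty(B) if method == "cluster" else None
    done = 0
    while done < B:
        m = min(chunk, B - done)
        G = rng.permuted(np.tile(g, (m, 1)), axis=1)
        Rperm = G @ Yv
        np.abs(Rperm, out=Rperm)
        max_null[done : done + m] = Rperm.max(axis=1) / gnorm
        if method == "cluster":
            for b in range(m):
                cluster_null[done + b] = max_cluster(Rperm[b] / gnorm)
        done += m

    # voxel-wise FWE p-values against the max-|r| null
    sorted_null = np.sort(max_null)
    exceed = B - np.searchsorted(sorted_null, np.abs(r_obs), side="left")
    p_fwe = (1.0 + exceed) / (B + 1.0)

    if method == "maxT":
        sig_v = p_fwe <= alpha
        # smallest statistic that would be declared significant
        c = int(np.floor(alpha * (B + 1))) - 1
        threshold_t = 0.0 if c >= B else float(corr_to_t(sorted_null[B - 1 - c]))
    else:
        t_form = stats.t.isf(forming_p / 2.0, df)
        r_form = t_form / np.sqrt(t_form**2 + df)
        sorted_cnull = np.sort(cluster_null)
        obs_sup = np.abs(r_obs) >= r_form
        sup = np.zeros(grid.dims, dtype=bool)
        sup.ravel()[valid_idx] = obs_sup
        lab, nlab = ndimage.label(sup)
        sig_v = np.zeros_like(r_obs, dtype=bool)
        lab_v = lab.ravel()[valid_idx]
        for li in range(1, nlab + 1):
            size = int((lab_v == li).sum())
            exceed_c = B - np.searchsorted(sorted_cnull, size, side="left")
            if (1.0 + exceed_c) / (B + 1.0) <= alpha:
                sig_v |= lab_v == li
        threshold_t = float(t_form)

    # assemble full-volume outputs
    t_full = np.full(int(np.prod(grid.dims)), np.nan)
    slope_full = np.full_like(t_full, np.nan)
    t_full[valid_idx] = t_obs
    slope_full[valid_idx] = r_obs * ynorm[nzv] / gnorm  # OLS slope on residualized data
    significant = np.zeros(int(np.prod(grid.dims)), dtype=bool)
    significant[valid_idx] = sig_v
    statmap = StatMap(
        grid=grid, t=t_full.reshape(grid.dims), effect=slope_full.reshape(grid.dims),
        df=df, contrast_label="seed covariance (permutation)", n_subjects=n,
    )

    # peak table over significant voxels
    rows = []
    if sig_v.any():
        sig_idx = valid_idx[sig_v]
        coords = np.array(np.unravel_index(sig_idx, grid.dims)).T
        mm = grid.voxel_to_mm(coords)
        t_sig = t_full[sig_idx]
        keep = _peaks(np.abs(t_sig), mm, min_peak_distance_mm)
        for i in keep:
            rows.append(
                {
                    "x": mm[i][0], "y": mm[i][1], "z": mm[i][2],
                    "t": t_sig[i], "z_score": float(t_to_z(np.array(t_sig[i]), df)),
                    "p_fwe": p_fwe[sig_v][i] if method == "maxT" else np.nan,
                    "n_voxels": int(sig_v.sum()),
                }
            )
    clusters = pd.DataFrame(rows, columns=["x", "y", "z", "t", "z_score", "p_fwe", "n_voxels"])
    logger.info(
        "fwe_threshold: %d voxels tested, %d permutations, threshold |t| = %.3f, "
        "%d significant voxels, %d peaks",
        V, B, threshold_t, int(sig_v.sum()), len(clusters),
    )
    return ThresholdReport(
        method=method, alpha=alpha, voxelwise_p_uncorrected=forming_p,
        n_permutations=B, df=df, threshold_t=threshold_t, statmap=statmap,
        significant=significant.reshape(grid.dims), clusters=clusters,
        max_stat_null=corr_to_t(max_null), n_voxels_tested=V,
    )


# -- dependent overlapping correlations ------------------------------------


def dependent_corr_z(r1: float, r2: float, r12: float, n: int) -> float:
    """Meng-Rosenthal-Rubin z for H0: rho(y, a) = rho(y, b).

    ``r1`` and ``r2`` are the two correlations sharing variable y, ``r12``
    the correlation between the two predictors, ``n`` the sample size.
    Positive when ``r1`` is the larger correlation.
    """
    for name, r in (("r1", r1), ("r2", r2), ("r12", r12)):
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"{name} = {r} is not a correlation")
        if name != "r12" and abs(r) >= 1.0:
            raise ValueError(f"{name} = {r}: Fisher transform undefined at |r| = 1")
    if r12 >= 1.0:
        if abs(r1 - r2) <= 1e-12:  # identical predictors: no difference to test
            return 0.0
        raise ValueError("r12 = 1: the two seed series are degenerate")
    if n < 4:
        raise ValueError("need at least 4 subjects")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    rbar2 = (r1**2 + r2**2) / 2.0
    f = min(1.0, (1.0 - r12) / (2.0 * (1.0 - rbar2)))
    h = (1.0 - f * rbar2) / (1.0 - rbar2)
    return float((z1 - z2) * np.sqrt((n - 3.0) / (2.0 * (1.0 - r12) * h)))


def compare_seed_correlations(maps, seed_a, seed_b, voxel=None, mm=None) -> float:
    """Signed z for whether a voxel correlates more with seed A than seed B.

    The voxel's across-subject series is correlated with both seed series
    (which share the same subjects) and the difference tested with the
    Meng-Rosenthal-Rubin statistic for overlapping dependent correlations.
    """
    grid, Y = _stack(maps)
    if (voxel is None) == (mm is None):
        raise ValueError("give exactly one of voxel= or mm=")
    if voxel is None:
        voxel = grid.mm_to_voxel(mm)
    y = Y[:, int(voxel[0]), int(voxel[1]), int(voxel[2])]
    if not np.all(np.isfinite(y)):
        raise ValueError("voxel series has missing values")
    a = np.asarray(getattr(seed_a, "values", seed_a), dtype=float).ravel()
    b = np.asarray(getattr(seed_b, "values", seed_b), dtype=float).ravel()
    if a.size != y.size or b.size != y.size:
        raise ValueError("seed series and maps must cover the same subjects")
    r1 = float(np.corrcoef(y, a)[0, 1])
    r2 = float(np.corrcoef(y, b)[0, 1])
    r12 = float(np.corrcoef(a, b)[0, 1])
    return dependent_corr_z(r1, r2, r12, y.size)
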