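"""End-to-end pipeline driver: simulate -> laterality -> seeds -> covariance
-> co-lateralization, with peak/CL tables and a reproducibility manifest.

The pipeline is deterministic: one root seed in the config drives cohort
generation and the permutation streams, and the manifest records the seeds,
SHA-256 hashes and per-stage outputs so a rerun with the same config
reproduces every file bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .colat import colat_map, colat_summary, seed_signs
from .covariance import StatMap, ThresholdReport, covary_with_seed, fwe_threshold, t_to_z
from .laterality import compute_laterality, sign_map
from .seeds import DEFAULT_SEEDS, SeedSpec, extract_seed_series
from .simulate import CohortConfig, RegionSpec, render_cohort, write_cohort
from .volume import HemisphereMask, build_grid, write_volume
from .volume import ContrastImage  # noqa: F401  (re-export convenience)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "make_peak_table"]


@dataclass
class PipelineConfig:
    """Everything needed to rerun one full analysis."""

    out_dir: str
    cohort: CohortConfig
    grid_dims: tuple[int, int, int] = (48, 56, 24)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    grid_origin_mm: tuple[float, float, float] | None = None
    seeds: list[SeedSpec] = field(default_factory=lambda: list(DEFAULT_SEEDS))
    variant: str = "difference"
    n_permutations: int = 1000
    alpha: float = 0.05
    forming_p: float = 0.001
    fwe_method: str = "maxT"
    min_peak_distance_mm: float = 8.0
    rng_seed: int = 0

    def build_grid(self):
        return build_grid(self.grid_dims, self.voxel_size_mm, self.grid_origin_mm)

    # -- lossless YAML round-trip -----------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["cohort"]["laterality_corr"] is not None:
            d["cohort"]["laterality_corr"] = np.asarray(
                d["cohort"]["laterality_corr"]
            ).tolist()
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        cd = dict(d.pop("cohort"))
        cd["regions"] = [
            RegionSpec(
                name=r["name"], center_mm=tuple(r["center_mm"]),
                sigma_mm=r.get("sigma_mm", 6.0),
                base_amplitude=r.get("base_amplitude", 2.0),
            )
            for r in cd["regions"]
        ]
        if cd.get("laterality_corr") is not None:
            cd["laterality_corr"] = np.asarray(cd["laterality_corr"], dtype=float)
        d["cohort"] = CohortConfig(**cd)
        d["seeds"] = [
            SeedSpec(s["name"], tuple(s["center_mm"]), s.get("diameter_mm", 4.0))
            for s in d.get("seeds", [])
        ] or list(DEFAULT_SEEDS)
        for key in ("grid_dims", "voxel_size_mm"):
            if key in d:
                d[key] = tuple(d[key])
        if d.get("grid_origin_mm") is not None:
            d["grid_origin_mm"] = tuple(d["grid_origin_mm"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_peak_table(
    statmaps: dict[str, StatMap],
    reports: dict[str, "ThresholdReport"],
    min_distance_mm: float = 8.0,
) -> pd.DataFrame:
    """Cross-seed peak table: one row per location, one z column per seed.

    Peaks are the FWE-significant local maxima of each seed's map, merged
    across seeds within ``min_distance_mm``; per seed each row carries the
    z-score there and a significance flag (``fwe`` when FWE-significant at
    that location, ``unc`` when below the uncorrected forming threshold
    only, ``n.s.`` otherwise).
    """
    locations: list[np.ndarray] = []
    for name, rep in reports.items():
        for _, row in rep.clusters.iterrows():
            p = np.array([row["x"], row["y"], row["z"]])
            if all(np.sum((p - q) ** 2) >= min_distance_mm**2 for q in locations):
                locations.append(p)
    rows = []
    for p in locations:
        entry = {"x": p[0], "y": p[1], "z": p[2]}
        for name, sm in statmaps.items():
            i, j, k = sm.grid.mm_to_voxel(p)
            tval = float(sm.t[i, j, k])
            zval = float(t_to_z(np.array(tval), sm.df))
            rep = reports[name]
            if bool(rep.significant[i, j, k]):
                flag = "fwe"
            elif np.isfinite(tval) and 2.0 * float(
                stats.t.sf(abs(tval), sm.df)
            ) < rep.voxelwise_p_uncorrected:
                flag = "unc"
            else:
                flag = "n.s."
            entry[f"z_{name}"] = zval
            entry[f"sig_{name}"] = flag
        rows.append(entry)
    cols = ["x", "y", "z"]
    for name in statmaps:
        cols += [f"z_{name}", f"sig_{name}"]
    return pd.DataFrame(rows, columns=cols)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and return (and write) the run manifest.

    Stage order: simulate the cohort, compute laterality and signed maps,
    extract seed eigenvariates, run the seed covariance analysis with
    permutation FWE per seed, build co-lateralization maps per seed, then
    render the combined peak table.  Any stage failure aborts with the
    stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = config.build_grid()

    # pre-flight: every seed and region center must be on the grid
    missing = [s.name for s in config.seeds if not grid.contains_mm(s.center_mm)]
    missing += [
        r.name for r in config.cohort.regions if not grid.contains_mm(r.center_mm)
    ]
    if missing:
        raise ValueError(f"pre-flight failed: centers outside the grid: {missing}")

    manifest: dict = {
        "latcov_version": __version__,
        "rng_seed": config.rng_seed,
        "config": config.to_dict(),
        "stages": {},
    }

    def record(stage: str, paths: list[Path]) -> None:
        manifest["stages"][stage] = {
            p.name: _sha256(p) for p in paths if p.is_file()
        }
        logger.info("stage %s: wrote %d files", stage, len(paths))

    stage = "simulate"
    try:
        cohort_cfg = dataclasses.replace(config.cohort, rng_seed=config.rng_seed)
        images, truth = render_cohort(cohort_cfg, grid)
        cohort_dir = write_cohort(images, truth, out / "cohort")
        record(stage, sorted(cohort_dir.iterdir()))

        stage = "latmap"
        mask = HemisphereMask.from_grid(grid)
        lmaps = [compute_laterality(img, mask, config.variant) for img in images]
        smaps = [sign_map(lm) for lm in lmaps]
        lat_dir = out / "laterality"
        lat_dir.mkdir(exist_ok=True)
        for lm, sm in zip(lmaps, smaps):
            write_volume(ContrastImage(grid, lm.values, lm.subject_id),
                         lat_dir / f"{lm.subject_id}_laterality.nii")
            write_volume(ContrastImage(grid, sm.signs, sm.subject_id),
                         lat_dir / f"{sm.subject_id}_signed.nii")
        record(stage, sorted(lat_dir.iterdir()))

        stage = "seed-extract"
        seed_dir = out / "seeds"
        seed_dir.mkdir(exist_ok=True)
        series = {}
        for seed in config.seeds:
            ss = extract_seed_series(lmaps, seed)
            series[seed.name] = ss
            pd.DataFrame(
                {"subject_id": ss.subject_ids, "value": ss.values}
            ).to_csv(seed_dir / f"{seed.name}.tsv", sep="\t", index=False)
        record(stage, sorted(seed_dir.iterdir()))

        stage = "covary"
        cov_dir = out / "covariance"
        cov_dir.mkdir(exist_ok=True)
        statmaps, reports = {}, {}
        perm_root = np.random.SeedSequence(config.rng_seed).spawn(len(config.seeds))
        for pss, seed in zip(perm_root, config.seeds):
            rep = fwe_threshold(
                lmaps, series[seed.name],
                n_permutations=config.n_permutations, alpha=config.alpha,
                random_state=np.random.default_rng(pss),
                forming_p=config.forming_p, method=config.fwe_method,
                mask="left", min_peak_distance_mm=config.min_peak_distance_mm,
            )
            statmaps[seed.name] = rep.statmap
            reports[seed.name] = rep
            write_volume(ContrastImage(grid, rep.statmap.t), cov_dir / f"{seed.name}_t.nii")
            write_volume(ContrastImage(grid, rep.statmap.z), cov_dir / f"{seed.name}_z.nii")
            write_volume(ContrastImage(grid, rep.statmap.effect),
                         cov_dir / f"{seed.name}_slope.nii")
            rep.clusters.to_csv(cov_dir / f"{seed.name}_peaks.tsv", sep="\t", index=False)
            (cov_dir / f"{seed.name}_threshold.json").write_text(
                json.dumps(
                    {
                        "method": rep.method, "alpha": rep.alpha,
                        "voxelwise_p_uncorrected": rep.voxelwise_p_uncorrected,
                        "n_permutations": rep.n_permutations,
                        "threshold_t": rep.threshold_t, "df": rep.df,
                        "n_voxels_tested": rep.n_voxels_tested,
                        "n_significant": int(rep.significant.sum()),
                    },
                    indent=2,
                )
            )
        peak_table = make_peak_table(statmaps, reports, config.min_peak_distance_mm)
        peak_table.to_csv(out / "peak_table.tsv", sep="\t", index=False)
        record(stage, sorted(cov_dir.iterdir()) + [out / "peak_table.tsv"])

        stage = "colat"
        cl_dir = out / "colateralization"
        cl_dir.mkdir(exist_ok=True)
        for seed in config.seeds:
            signs = seed_signs(lmaps, seed)
            clm = colat_map(smaps, signs, seed_name=seed.name)
            write_volume(ContrastImage(grid, clm.cl), cl_dir / f"{seed.name}_cl.nii")
            write_volume(ContrastImage(grid, clm.n_effective.astype(float)),
                         cl_dir / f"{seed.name}_n_effective.nii")
            peaks = [tuple(r.center_mm) for r in config.cohort.regions]
            labels = [r.name for r in config.cohort.regions]
            colat_summary(clm, peaks, labels).to_csv(
                cl_dir / f"{seed.name}_summary.tsv", sep="\t", index=False
            )
        record(stage, sorted(cl_dir.iterdir()))
    except Exception as err:
        logger.error("pipeline stage %r failed: %s", stage, err)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    config.to_yaml(out / "config.yaml")
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
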