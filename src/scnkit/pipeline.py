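"""End-to-end analysis orchestration and the run manifest.

`run_analysis` executes the full working scheme on one cohort: voxel-wise
group difference (VBM), per-group per-seed SCN maps, per-seed Met > Val
slope-interaction maps, peak-sphere volume extraction, seed- and
peak-volume behavior correlation tables, demographics and the
Hardy-Weinberg check.  Stat maps are written as NIfTI, tables as TSV, and
a JSON manifest records the config snapshot, input checksums, stage
timings and software version so a run can be audited and reproduced.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clinical import correlate_volumes_scores, demographics_report, hwe_test
from .cohort import Cohort
from .config import AnalysisConfig
from .glm import GroupDifference, SeedCovarianceNetwork
from .images import smooth_array, write_stat_volume
from .interaction import SlopeInteraction, peak_sphere_volumes
from .roi import DEFAULT_SEEDS, SeedSpec, extract_volumes
from .clinical import compare_groups_scalar


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def clusters_to_frame(clusters) -> pd.DataFrame:
    """Cluster table with the conventional columns: id, extent, MNI peak, peak T."""
    return pd.DataFrame(
        [
            {
                "cluster_id": c.cluster_id,
                "size_voxels": c.size_voxels,
                "peak_x": c.peak_mni_xyz[0],
                "peak_y": c.peak_mni_xyz[1],
                "peak_z": c.peak_mni_xyz[2],
                "peak_t": c.peak_t,
            }
            for c in clusters
        ],
        columns=["cluster_id", "size_voxels", "peak_x", "peak_y", "peak_z", "peak_t"],
    )


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format="%.6g")


def _active_seeds(config: AnalysisConfig) -> list[SeedSpec]:
    seeds = DEFAULT_SEEDS
    if config.seeds is not None:
        wanted = set(config.seeds)
        unknown = wanted - {s.name for s in DEFAULT_SEEDS}
        if unknown:
            raise ValueError(f"unknown seed names in config: {sorted(unknown)}")
        seeds = tuple(s for s in DEFAULT_SEEDS if s.name in wanted)
    return [SeedSpec(s.name, s.model, s.mni_xyz, config.sphere_radius_mm) for s in seeds]


def run_analysis(cohort: Cohort, config: AnalysisConfig, out_dir,
                 input_files: dict[str, str] | None = None) -> dict:
    """Run the full pipeline; returns the manifest dict (also written as JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    notes: list[str] = []

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return _T()

    if config.apply_smoothing and config.smoothing_fwhm_mm > 0:
        with stage("smoothing"):
            for i in range(cohort.n_subjects):
                cohort.data[i] = np.clip(
                    smooth_array(cohort.data[i], cohort.voxel_size, config.smoothing_fwhm_mm),
                    0.0, None,
                )
            notes.append(f"re-smoothed inputs at {config.smoothing_fwhm_mm} mm FWHM")
    if config.proportional_scaling:
        with stage("proportional_scaling"):
            totals = cohort.data.reshape(cohort.n_subjects, -1).sum(axis=1)
            cohort.data /= (totals / totals.mean())[:, None, None, None]
            notes.append("proportional scaling by total GM applied")

    seeds = _active_seeds(config)

    with stage("demographics"):
        demo = demographics_report(cohort.phenotypes, welch=config.welch,
                                   chi2_correction=config.chi2_correction)
        _write_tsv(demo, out / "demographics.tsv")
        counts = cohort.phenotypes["genotype"].value_counts()
        chi2, p = hwe_test(int(counts.get("MM", 0)), int(counts.get("MV", 0)),
                           int(counts.get("VV", 0)))
        with open(out / "hwe.json", "w") as fh:
            json.dump({"n_MM": int(counts.get("MM", 0)), "n_MV": int(counts.get("MV", 0)),
                       "n_VV": int(counts.get("VV", 0)), "chi2": chi2, "p": p,
                       "in_equilibrium": bool(p > config.alpha)}, fh, indent=2)

    with stage("seed_volumes"):
        seed_vols = extract_volumes(cohort, seeds)
        _write_tsv(seed_vols.reset_index(), out / "seed_volumes.tsv")
        rows = []
        groups = cohort.phenotypes["group"].to_numpy()
        for name in seed_vols.columns:
            res = compare_groups_scalar(seed_vols[name].to_numpy(), groups,
                                        "continuous", welch=config.welch)
            rows.append({"seed": name, "t": res.statistic, "df": res.df, "p": res.p,
                         **{f"mean_{g}": res.summary[g]["mean"] for g in res.summary}})
        _write_tsv(pd.DataFrame(rows), out / "seed_volume_comparison.tsv")

    with stage("group_difference"):
        vbm = GroupDifference(
            q=config.group_q, min_cluster_voxels=config.min_cluster_voxels,
            connectivity=config.connectivity, mask_threshold=config.mask_threshold,
            nuisance=config.nuisance,
        ).fit(cohort)
        write_stat_volume(vbm.stat_map_.tstat, cohort.affine,
                          out / "group_difference_t.nii.gz")
        _write_tsv(clusters_to_frame(vbm.clusters_), out / "group_difference_clusters.tsv")

    with stage("scn_and_interaction"):
        correlations_by_seed = {}
        for spec in seeds:
            seed_dir = out / "seeds" / spec.name
            seed_dir.mkdir(parents=True, exist_ok=True)
            for group in ("Met", "Val"):
                scn = SeedCovarianceNetwork(
                    seed_name=spec.name, q=config.scn_q,
                    min_cluster_voxels=config.min_cluster_voxels,
                    connectivity=config.connectivity,
                    sphere_radius_mm=config.sphere_radius_mm,
                    mask_threshold=config.mask_threshold, nuisance=config.nuisance,
                ).fit(cohort.select_group(group))
                write_stat_volume(scn.stat_map_.tstat, cohort.affine,
                                  seed_dir / f"scn_{group}_t.nii.gz")
                _write_tsv(clusters_to_frame(scn.clusters_),
                           seed_dir / f"scn_{group}_clusters.tsv")
            inter = SlopeInteraction(
                seed_name=spec.name, q=config.scn_q,
                min_cluster_voxels=config.min_cluster_voxels,
                connectivity=config.connectivity,
                sphere_radius_mm=config.sphere_radius_mm,
                mask_threshold=config.mask_threshold, nuisance=config.nuisance,
                direction="met_gt_val",
            ).fit(cohort)
            write_stat_volume(inter.stat_map_.tstat, cohort.affine,
                              seed_dir / "interaction_met_gt_val_t.nii.gz")
            _write_tsv(clusters_to_frame(inter.clusters_),
                       seed_dir / "interaction_met_gt_val_clusters.tsv")
            peak_vols = peak_sphere_volumes(cohort, inter.clusters_,
                                            radius_mm=config.sphere_radius_mm)
            _write_tsv(peak_vols.reset_index(), seed_dir / "peak_volumes.tsv")
            if len(peak_vols.columns):
                corr = correlate_volumes_scores(peak_vols, cohort.phenotypes)
                corr.columns = ["|".join(map(str, c)) for c in corr.columns]
                _write_tsv(corr.reset_index(), seed_dir / "peak_correlations.tsv")
                correlations_by_seed[spec.name] = corr

    with stage("seed_correlations"):
        corr = correlate_volumes_scores(seed_vols, cohort.phenotypes)
        corr.columns = ["|".join(map(str, c)) for c in corr.columns]
        _write_tsv(corr.reset_index(), out / "seed_correlations.tsv")

    manifest = {
        "software": {"name": "scnkit", "version": __version__},
        "config": config.to_dict(),
        "n_subjects": int(cohort.n_subjects),
        "n_met": int((cohort.phenotypes["group"] == "Met").sum()),
        "n_val": int((cohort.phenotypes["group"] == "Val").sum()),
        "seeds": [s.name for s in seeds],
        "input_files": input_files or {},
        "stage_timings_s": timings,
        "notes": notes + [
            f"analysis mask: mean GM >= {config.mask_threshold}",
            f"FDR: voxel-level Benjamini-Hochberg within mask, then extent >= "
            f"{config.min_cluster_voxels} voxels",
            f"cluster connectivity: {config.connectivity}-neighbourhood",
            "SCN contrast one-sided positive; group VBM two-sided; "
            "interaction reported Met > Val",
            "t tests Welch" if config.welch else "t tests pooled-variance",
            "chi-square " + ("with" if config.chi2_correction else "without") +
            " continuity correction",
        ],
        "rng_seed": int(config.rng_seed),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def checksum_outputs(out_dir) -> dict[str, str]:
    """SHA-256 of every file in a run directory except the manifest
    (whose stage timings legitimately vary between runs)."""
    out = Path(out_dir)
    sums = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            sums[str(path.relative_to(out))] = _sha256(path)
    return sums
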