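"""Genotype x seed slope-interaction mapping and peak-sphere extraction.

Voxels where the seed-to-voxel covariance slope differs between genotype
groups are found with a pooled model

    GM(v) = b0 + b1*seed + b2*group + b3*(seed x group) + nuisance

with group coded Val = 0, Met = 1, so b3 > 0 exactly when the Met-carrier
slope exceeds the Val-homozygote slope.  A one-sided T on b3 with BH-FDR
and cluster-extent thresholding yields the Met > Val interaction clusters;
a sphere on each cluster's peak voxel then gives per-subject peak volumes
for the behavioral correlation stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .glm import StatMap, _VoxelwiseMapper, _build_design, extract_clusters, fdr_select, fit_voxelwise
from .images import analysis_mask
from .roi import SeedSpec, SphereROI, extract_volumes, seed_by_name


class SlopeInteraction(_VoxelwiseMapper):
    """Voxel-wise seed-slope difference between two groups (default Met > Val).

    Parameters mirror :class:`scnkit.glm.SeedCovarianceNetwork`;
    ``direction`` selects the one-sided contrast: ``"met_gt_val"`` (the
    default reporting convention) or ``"val_gt_met"``.

    Attributes
    ----------
    stat_map_ : StatMap
        3D maps for the interaction coefficient b3 (slope difference in GM
        units per mL of seed volume), its T and p, and the FDR mask.
    clusters_ : list of ClusterRecord
    seed_volumes_ : ndarray
        Pooled-cohort seed sphere volumes (mL).
    """

    def __init__(self, seed_name: str = "dorsal_caudal_putamen", q: float = 0.01,
                 min_cluster_voxels: int = 100, connectivity: int = 18,
                 sphere_radius_mm: float = 4.0, mask_threshold: float = 0.1,
                 nuisance: tuple = (), direction: str = "met_gt_val"):
        self.seed_name = seed_name
        self.q = q
        self.min_cluster_voxels = min_cluster_voxels
        self.connectivity = connectivity
        self.sphere_radius_mm = sphere_radius_mm
        self.mask_threshold = mask_threshold
        self.nuisance = nuisance
        self.direction = direction

    def fit(self, cohort, y=None):
        if self.direction not in ("met_gt_val", "val_gt_met"):
            raise ValueError("direction must be 'met_gt_val' or 'val_gt_met'")
        groups = cohort.phenotypes["group"].to_numpy()
        n_met = int((groups == "Met").sum())
        n_val = int((groups == "Val").sum())
        if min(n_met, n_val) < 3:
            raise ValueError(
                f"each group needs >= 3 subjects for the interaction model "
                f"(got Met={n_met}, Val={n_val})"
            )
        seed = seed_by_name(self.seed_name)
        spec = SeedSpec(seed.name, seed.model, seed.mni_xyz, self.sphere_radius_mm)
        seed_vol = extract_volumes(cohort, [spec])[spec.name].to_numpy()
        coded = (groups == "Met").astype(np.float64)

        mask = analysis_mask(cohort, self.mask_threshold)
        if not mask.any():
            raise ValueError("analysis mask is empty; lower mask_threshold")
        Y = cohort.data.reshape(cohort.n_subjects, -1)[:, mask.ravel()]
        base = _build_design(cohort, seed_vol, tuple(self.nuisance))
        # columns: [1, seed, nuisance..., group, seed*group]; contrast on last
        X = np.column_stack([base, coded, seed_vol * coded])
        sided = "pos" if self.direction == "met_gt_val" else "neg"
        label = f"interaction[{self.seed_name}] " + (
            "Met>Val" if sided == "pos" else "Val>Met"
        )
        flat = fit_voxelwise(Y, X, contrast_index=X.shape[1] - 1, sided=sided,
                             contrast_label=label)
        if sided == "neg":  # report the magnitude direction actually tested
            flat.tstat = -flat.tstat
            flat.beta = -flat.beta
        selected = fdr_select(flat.p, self.q)
        sel3d = np.zeros(mask.shape, dtype=bool)
        sel3d[mask] = selected

        def expand(v, fill):
            out = np.full(mask.shape, fill, dtype=np.float64)
            out[mask] = v
            return out

        t3d = expand(flat.tstat, 0.0)
        self.stat_map_ = StatMap(
            beta=expand(flat.beta, 0.0),
            tstat=t3d,
            p=expand(flat.p, 1.0),
            df=flat.df,
            contrast_label=label,
            sided=sided,
            q_mask=sel3d,
            mask=mask,
            affine=cohort.affine,
            n_zero_variance=flat.n_zero_variance,
        )
        self.clusters_ = extract_clusters(
            sel3d, t3d, self.min_cluster_voxels, self.connectivity, cohort.affine
        )
        self.seed_volumes_ = seed_vol
        return self


def fit_interaction(cohort, seed_name: str, config: AnalysisConfig | None = None,
                    direction: str = "met_gt_val"):
    """Map Met/Val slope differences for one seed; returns (StatMap, clusters)."""
    config = config or AnalysisConfig()
    model = SlopeInteraction(
        seed_name=seed_name,
        q=config.scn_q,
        min_cluster_voxels=config.min_cluster_voxels,
        connectivity=config.connectivity,
        sphere_radius_mm=config.sphere_radius_mm,
        mask_threshold=config.mask_threshold,
        nuisance=config.nuisance,
        direction=direction,
    ).fit(cohort)
    return model.stat_map_, model.clusters_


def peak_sphere_volumes(cohort, clusters, radius_mm: float = 4.0,
                        prefix: str = "peak") -> pd.DataFrame:
    """GM volume (mL) of a sphere on each cluster's peak voxel, per subject.

    One column per cluster, named ``{prefix}{cluster_id}_x_y_z``; zero
    clusters yield an empty table with zero columns.
    """
    rois = [
        SphereROI(
            name="%s%d_%d_%d_%d"
            % (prefix, c.cluster_id, round(c.peak_mni_xyz[0]),
               round(c.peak_mni_xyz[1]), round(c.peak_mni_xyz[2])),
            mni_xyz=c.peak_mni_xyz,
            radius_mm=radius_mm,
        )
        for c in clusters
    ]
    return extract_volumes(cohort, rois)
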