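"""Sphere ROIs at MNI coordinates and per-subject GM volume extraction.

A seed is a small sphere (default 4-mm radius) around a literature MNI
coordinate; its extracted GM volume — the sum of modulated density over the
sphere's voxels times the voxel volume, in millilitres — is the covariate
of interest for the covariance-network regressions.

Ten default seeds are provided: six striatal subdivisions (ventral and
dorsal striatum/putamen parcellation) and four nodes of the triple-network
model (default-mode, salience and executive-control networks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SeedSpec:
    """A named MNI coordinate with a sphere radius.

    ``model`` tags the seed's parent network model: ``"striatal"`` or
    ``"triple"`` (triple-network: DMN / salience / executive control).
    """

    name: str
    model: str
    mni_xyz: tuple[float, float, float]
    radius_mm: float = 4.0

    def __post_init__(self) -> None:
        if self.radius_mm < 0:
            raise ValueError("radius_mm must be >= 0")
        if self.model not in ("striatal", "triple"):
            raise ValueError("model must be 'striatal' or 'triple'")
        object.__setattr__(self, "mni_xyz", tuple(float(c) for c in self.mni_xyz))


@dataclass(frozen=True)
class SphereROI:
    """A bare sphere ROI (e.g. on an interaction-cluster peak voxel)."""

    name: str
    mni_xyz: tuple[float, float, float]
    radius_mm: float = 4.0

    def __post_init__(self) -> None:
        if self.radius_mm < 0:
            raise ValueError("radius_mm must be >= 0")
        object.__setattr__(self, "mni_xyz", tuple(float(c) for c in self.mni_xyz))


STRIATAL_SEEDS: tuple[SeedSpec, ...] = (
    SeedSpec("inferior_ventral_striatum", "striatal", (9, 9, -8)),
    SeedSpec("superior_ventral_striatum", "striatal", (10, 15, 0)),
    SeedSpec("dorsal_caudate", "striatal", (13, 15, 9)),
    SeedSpec("ventral_rostral_putamen", "striatal", (20, 12, -3)),
    SeedSpec("dorsal_caudal_putamen", "striatal", (28, 1, 3)),
    SeedSpec("dorsal_rostral_putamen", "striatal", (25, 8, 6)),
)

TRIPLE_NETWORK_SEEDS: tuple[SeedSpec, ...] = (
    SeedSpec("right_entorhinal", "triple", (25, -9, -28)),
    SeedSpec("left_pcc", "triple", (-2, -36, 35)),
    SeedSpec("right_frontoinsular", "triple", (38, 26, -10)),
    SeedSpec("right_dlpfc", "triple", (44, 36, 20)),
)

DEFAULT_SEEDS: tuple[SeedSpec, ...] = STRIATAL_SEEDS + TRIPLE_NETWORK_SEEDS


def seed_by_name(name: str) -> SeedSpec:
    for seed in DEFAULT_SEEDS:
        if seed.name == name:
            return seed
    raise KeyError(f"unknown seed {name!r}; known: {[s.name for s in DEFAULT_SEEDS]}")


def voxel_centers_mni(shape, affine) -> np.ndarray:
    """MNI-mm coordinates of every voxel center, shape (*shape, 3)."""
    ii, jj, kk = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )
    vox = np.stack([ii, jj, kk], axis=-1).astype(np.float64)
    return vox @ affine[:3, :3].T + affine[:3, 3]


def sphere_mask(shape, affine, center_mni, radius_mm: float) -> np.ndarray:
    """Boolean mask of voxels whose center lies within ``radius_mm`` of
    ``center_mni`` (boundary-closed: distance == radius is included).

    Raises if the center falls outside the field of view — silently
    truncated spheres would bias extracted volumes.
    """
    affine = np.asarray(affine, dtype=np.float64)
    center = np.asarray(center_mni, dtype=np.float64)
    if radius_mm < 0:
        raise ValueError("radius_mm must be >= 0")
    inv = np.linalg.inv(affine)
    vox_center = inv[:3, :3] @ center + inv[:3, 3]
    if np.any(vox_center < -0.5) or np.any(vox_center > np.asarray(shape) - 0.5):
        raise ValueError(
            f"ROI center {tuple(center)} maps to voxel index {tuple(vox_center)} "
            f"outside the field of view {tuple(shape)}"
        )
    coords = voxel_centers_mni(shape, affine)
    dist2 = ((coords - center) ** 2).sum(axis=-1)
    return dist2 <= radius_mm**2 + 1e-9


def extract_volumes(cohort, roi_specs) -> pd.DataFrame:
    """Per-subject GM volume of each ROI sphere, in millilitres.

    Entry (i, r) = sum of subject i's GM density over ROI r's voxels,
    times the voxel volume in mL.  Columns are ROI names; the row order is
    the cohort's subject order.
    """
    roi_specs = list(roi_specs)
    vox_ml = cohort.voxel_volume_ml
    flat = cohort.data.reshape(cohort.n_subjects, -1)
    out = {}
    for spec in roi_specs:
        mask = sphere_mask(cohort.image_shape, cohort.affine, spec.mni_xyz, spec.radius_mm)
        out[spec.name] = flat[:, mask.ravel()].sum(axis=1) * vox_ml
    table = pd.DataFrame(out, index=cohort.phenotypes.get("subject_id"))
    table.index.name = "subject_id"
    return table
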