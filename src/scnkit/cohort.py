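"""Cohort container: stacked subject volumes plus the phenotype table.

The phenotype table follows a fixed schema (tab-separated, one header row):
``subject_id, genotype, group, age, education, sex, apoe4`` followed by any
number of score columns (MMSE, CASI total and subdomains, NPI total and
subdomains, ...).  ``genotype`` is one of MM, MV, VV and ``group`` pools
MM+MV into ``Met`` (Met-carriers) versus ``Val`` (Val-homozygotes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .images import GMVolume, read_volume

GENOTYPES = ("MM", "MV", "VV")
GROUPS = ("Met", "Val")

#: leading non-score columns of the phenotype schema
PHENOTYPE_ID_COLUMNS = ("subject_id", "genotype", "group", "age", "education", "sex", "apoe4")


def genotype_to_group(genotype: str) -> str:
    """Pool genotypes into analysis groups: MM and MV are Met-carriers."""
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}; expected one of {GENOTYPES}")
    return "Met" if genotype in ("MM", "MV") else "Val"


@dataclass
class Cohort:
    """Subjects' GM volumes in one common geometry plus their phenotypes.

    Attributes
    ----------
    data : ndarray, shape (n_subjects, nx, ny, nz)
        Stacked GM density maps, float64.
    affine : ndarray, shape (4, 4)
        Shared voxel->MNI transform.
    phenotypes : DataFrame
        One row per subject, aligned with ``data`` along axis 0.
    """

    data: np.ndarray
    affine: np.ndarray
    phenotypes: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError("cohort data must be (n_subjects, nx, ny, nz)")
        if len(self.phenotypes) != self.data.shape[0]:
            raise ValueError(
                f"phenotype rows ({len(self.phenotypes)}) do not match "
                f"volumes ({self.data.shape[0]})"
            )
        if "group" in self.phenotypes.columns:
            bad = set(self.phenotypes["group"]) - set(GROUPS)
            if bad:
                raise ValueError(f"unknown group labels: {sorted(bad)}")
        self.phenotypes = self.phenotypes.reset_index(drop=True)

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def image_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def voxel_size(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume_ml(self) -> float:
        return abs(np.linalg.det(self.affine[:3, :3])) / 1000.0

    def volume(self, i: int) -> GMVolume:
        return GMVolume(data=self.data[i], affine=self.affine)

    def group_indices(self, group: str) -> np.ndarray:
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
        return np.flatnonzero((self.phenotypes["group"] == group).to_numpy())

    def subset(self, indices) -> "Cohort":
        idx = np.asarray(indices)
        return Cohort(
            data=self.data[idx],
            affine=self.affine,
            phenotypes=self.phenotypes.iloc[idx].reset_index(drop=True),
        )

    def select_group(self, group: str) -> "Cohort":
        return self.subset(self.group_indices(group))

    @classmethod
    def from_volumes(cls, volumes: list[GMVolume], phenotypes: pd.DataFrame) -> "Cohort":
        if not volumes:
            raise ValueError("cohort requires at least one volume")
        ref = volumes[0]
        for v in volumes[1:]:
            if not ref.same_geometry(v):
                raise ValueError("all volumes in a cohort must share shape and affine")
        data = np.stack([v.data for v in volumes], axis=0)
        return cls(data=data, affine=ref.affine, phenotypes=phenotypes)


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PHENOTYPE_ID_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table missing required columns: {missing}")
    return df


def load_cohort(directory) -> Cohort:
    """Load a cohort written by :func:`scnkit.simulate.write_cohort`.

    Expects ``phenotypes.tsv`` plus one ``<subject_id>.nii.gz`` per row.
    """
    directory = Path(directory)
    pheno = read_phenotypes(directory / "phenotypes.tsv")
    volumes = [read_volume(directory / f"{sid}.nii.gz") for sid in pheno["subject_id"]]
    return Cohort.from_volumes(volumes, pheno)


def load_simulation_sidecar(directory) -> dict:
    """Read the ground-truth simulation sidecar, if the cohort is synthetic."""
    with open(Path(directory) / "simulation.json") as fh:
        return json.load(fh)
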