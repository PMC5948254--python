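"""Synthetic cohort generator with planted covariance-network structure.

The generator emulates what a seed-based SCN analysis assumes about its
input: a cohort of spatially-normalized, smoothed, modulated GM density
maps in one common space, split into Met-carrier and Val-homozygote
genotype groups, in which

* genotypes follow Hardy-Weinberg proportions (p^2, 2pq, q^2),
* each network template ties a latent per-subject score s_i ~ N(0,
  latent_sd) to the seed region (so the extracted 4-mm seed sphere volume
  is a noisy linear readout of s_i with unit gain, in mL) and to remote
  target blobs with a group-specific slope (slope_met vs slope_val, in GM
  density units per mL of seed volume) — a slope difference plants a
  Met > Val interaction,
* behavior scores are linear in the extracted seed volume plus noise.

Images are generated already smooth: target blobs carry a compact
raised-cosine profile (value 1 at the center, 1/2 at ``radius_mm``, 0
beyond twice the radius), standing in for 8-mm-FWHM smoothed data while
keeping the planted slopes exact.  White Gaussian voxel noise is added on
top and the result is clamped at zero, as GM density maps are
non-negative.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, genotype_to_group, write_phenotypes
from .images import GMVolume, smooth_array, write_volume
from .roi import SphereROI, extract_volumes, seed_by_name, sphere_mask, voxel_centers_mni

#: Met allele frequency implied by genotype counts 20 MM / 71 MV / 101 VV
DEFAULT_MET_ALLELE_FREQ = 111.0 / 384.0


def default_affine(shape=(40, 48, 40), voxel_mm: float = 4.0) -> np.ndarray:
    """Affine of a desk-scale MNI-like grid: isotropic voxels with the
    MNI origin at the grid center."""
    shape = np.asarray(shape)
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = -voxel_mm * (shape - 1) / 2.0
    return affine


@dataclass(frozen=True)
class NetworkTemplate:
    """A planted covariance network: one seed, remote targets, group slopes.

    ``target_blobs`` is a tuple of (MNI center, half-max radius in mm,
    amplitude); ``slope_met`` / ``slope_val`` are the covariance slopes
    (GM density per mL of seed volume) in each genotype group.
    """

    seed_name: str
    target_blobs: tuple = ()
    slope_met: float = 1.0
    slope_val: float = 1.0

    def __post_init__(self) -> None:
        blobs = []
        for center, radius, amplitude in self.target_blobs:
            if radius <= 0:
                raise ValueError("blob radius must be > 0")
            blobs.append((tuple(float(c) for c in center), float(radius), float(amplitude)))
        object.__setattr__(self, "target_blobs", tuple(blobs))


#: Default planted network: the dorsal caudal putamen seed drives two
#: posterior cortical blobs twice as strongly in Met-carriers as in
#: Val-homozygotes — the condition the interaction analysis is built to
#: detect.
DEFAULT_TEMPLATE = NetworkTemplate(
    seed_name="dorsal_caudal_putamen",
    target_blobs=(((-32, -48, 28), 14.0, 1.0), ((24, -52, 8), 14.0, 1.0)),
    slope_met=2.0,
    slope_val=1.0,
)

#: Behavior couplings (score, seed, intercept, slope per mL, noise SD),
#: scaled to yield MMSE/CASI-like score ranges with weak-to-moderate
#: volume-behavior correlations.
DEFAULT_BEHAVIOR_COUPLINGS = (
    ("MMSE", "dorsal_caudal_putamen", 10.5, 60.0, 6.0),
    ("CASI_total", "dorsal_caudal_putamen", 47.5, 120.0, 20.0),
)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults reproduce the reference study's design: 91 Met-carriers vs
    101 Val-homozygotes, Met allele frequency 111/384 (the value implied
    by genotype counts 20/71/101), one planted Met>Val network on the
    dorsal caudal putamen seed, and MMSE/CASI scores coupled to that
    seed's volume.
    """

    n_met: int = 91
    n_val: int = 101
    met_allele_freq: float = DEFAULT_MET_ALLELE_FREQ
    image_shape: tuple = (40, 48, 40)
    voxel_mm: float = 4.0
    baseline: dict = field(default_factory=lambda: {"kind": "brain", "density": 0.6})
    latent_sd: float = 0.02
    noise_sd: float = 0.015
    templates: tuple = (DEFAULT_TEMPLATE,)
    behavior_couplings: tuple = DEFAULT_BEHAVIOR_COUPLINGS
    sphere_radius_mm: float = 4.0
    smoothing_fwhm_mm: float = 0.0
    clip_negative: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_met < 0 or self.n_val < 0:
            raise ValueError("group sizes must be >= 0")
        if not 0.0 <= self.met_allele_freq <= 1.0:
            raise ValueError("met_allele_freq must lie in [0, 1]")
        if self.latent_sd < 0 or self.noise_sd < 0:
            raise ValueError("latent_sd and noise_sd must be >= 0")
        self.image_shape = tuple(int(s) for s in self.image_shape)
        self.templates = tuple(
            t if isinstance(t, NetworkTemplate) else NetworkTemplate(**t)
            for t in self.templates
        )
        self.behavior_couplings = tuple(tuple(c) for c in self.behavior_couplings)

    @property
    def affine(self) -> np.ndarray:
        return default_affine(self.image_shape, self.voxel_mm)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["templates"] = [
            {"seed_name": t.seed_name,
             "target_blobs": [[list(c), r, a] for (c, r, a) in t.target_blobs],
             "slope_met": t.slope_met, "slope_val": t.slope_val}
            for t in self.templates
        ]
        d["behavior_couplings"] = [list(c) for c in self.behavior_couplings]
        d["image_shape"] = list(self.image_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "templates" in d:
            d["templates"] = tuple(
                NetworkTemplate(
                    seed_name=t["seed_name"],
                    target_blobs=tuple((tuple(c), r, a) for c, r, a in t["target_blobs"]),
                    slope_met=t["slope_met"],
                    slope_val=t["slope_val"],
                )
                for t in d["templates"]
            )
        return cls(**d)


def sample_genotypes(n: int, met_allele_freq: float, rng: np.random.Generator) -> list[str]:
    """Draw n genotypes i.i.d. under Hardy-Weinberg proportions.

    With p the Met allele frequency, genotype probabilities are
    (p^2, 2pq, q^2) for (MM, MV, VV).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if not 0.0 <= met_allele_freq <= 1.0:
        raise ValueError("met_allele_freq must lie in [0, 1]")
    p = met_allele_freq
    q = 1.0 - p
    probs = np.array([p * p, 2 * p * q, q * q])
    return list(rng.choice(["MM", "MV", "VV"], size=n, p=probs))


def _sample_genotypes_by_group(n_met: int, n_val: int, freq: float,
                               rng: np.random.Generator) -> list[str]:
    """Genotypes for fixed group sizes: Val-homozygotes are VV; within
    Met-carriers, MM vs MV follow their HWE-conditional odds p : 2q."""
    p, q = freq, 1.0 - freq
    if n_met > 0:
        if p == 0.0:
            raise ValueError("cannot draw Met-carriers with met_allele_freq = 0")
        p_mm = p * p / (p * p + 2 * p * q)  # = p / (p + 2q)
        met = list(rng.choice(["MM", "MV"], size=n_met, p=[p_mm, 1 - p_mm]))
    else:
        met = []
    return met + ["VV"] * n_val


def baseline_map(config: SimulationConfig) -> np.ndarray:
    """The noise-free group-mean GM density map.

    ``kind="brain"``: an ellipsoid (semi-axes 70 x 88 x 66 mm around MNI
    (0, -18, 5)) at the given density with a soft taper over the outer
    15% — large enough that all ten default seeds fall in its interior.
    ``kind="box"``: uniform density over the whole grid (useful for
    calibration studies where the mask must be the full volume).
    """
    kind = config.baseline.get("kind", "brain")
    density = float(config.baseline.get("density", 0.6))
    shape = config.image_shape
    if kind == "box":
        return np.full(shape, density, dtype=np.float64)
    if kind != "brain":
        raise ValueError(f"unknown baseline kind {kind!r}")
    coords = voxel_centers_mni(shape, config.affine)
    center = np.array([0.0, -18.0, 5.0])
    semi = np.array([70.0, 88.0, 66.0])
    rho = np.sqrt((((coords - center) / semi) ** 2).sum(axis=-1))
    taper = np.clip((1.0 - rho) / 0.15, 0.0, 1.0)
    return density * taper


def blob_profile(shape, affine, center_mni, radius_mm: float) -> np.ndarray:
    """Compact raised-cosine blob: 1 at the center, 1/2 at ``radius_mm``,
    exactly 0 beyond ``2 * radius_mm``."""
    coords = voxel_centers_mni(shape, affine)
    d = np.sqrt(((coords - np.asarray(center_mni, dtype=np.float64)) ** 2).sum(axis=-1))
    full = 2.0 * radius_mm
    out = np.where(d < full, np.cos(np.pi * d / (2.0 * full)) ** 2, 0.0)
    return out


def template_fields(config: SimulationConfig, template: NetworkTemplate):
    """Ground-truth spatial fields for one template.

    Returns (seed_field, target_field, support_mask): the seed readout
    field is scaled so that summing it over the seed's sphere voxels
    times the voxel volume gives exactly 1 (unit mL gain per latent
    unit); the support mask marks voxels where the target profile is at
    least 5% of its peak.
    """
    shape, affine = config.image_shape, config.affine
    seed = seed_by_name(template.seed_name)
    fov = np.abs(default_affine(shape, config.voxel_mm)[:3, 3])
    for center, radius, _ in template.target_blobs:
        if np.any(np.abs(np.asarray(center)) > fov + config.voxel_mm / 2):
            raise ValueError(f"target blob at {center} lies outside the field of view")
    seed_profile = blob_profile(shape, affine, seed.mni_xyz, config.sphere_radius_mm)
    sphere = sphere_mask(shape, affine, seed.mni_xyz, config.sphere_radius_mm)
    vox_ml = abs(np.linalg.det(affine[:3, :3])) / 1000.0
    gain = seed_profile[sphere].sum() * vox_ml
    if gain <= 0:
        raise ValueError(f"seed sphere for {template.seed_name} captures no signal")
    seed_field = seed_profile / gain
    target_field = np.zeros(shape, dtype=np.float64)
    for center, radius, amplitude in template.target_blobs:
        target_field += amplitude * blob_profile(shape, affine, center, radius)
    support = target_field >= 0.05 * max(target_field.max(), 1e-300)
    return seed_field, target_field, support


def generate_cohort(config: SimulationConfig) -> tuple[Cohort, dict]:
    """Generate one cohort plus its ground truth.

    Subject i's image is ``baseline + sum_templates [ (s_i / gain) *
    seed_profile + slope_group(i) * s_i * target_profile ] + noise``,
    optionally smoothed, clamped at zero.  Behavior scores are
    ``intercept + slope * extracted_seed_volume + N(0, noise)``.

    Returns
    -------
    (cohort, ground_truth) : the ground-truth dict records the config,
    the per-template latent scores, and the realized group labels; it is
    what :func:`write_cohort` stores as the JSON sidecar.
    """
    n = config.n_met + config.n_val
    if n == 0:
        raise ValueError("cohort must contain at least one subject")
    rng = np.random.default_rng(config.rng_seed)
    shape, affine = config.image_shape, config.affine

    genotypes = _sample_genotypes_by_group(config.n_met, config.n_val,
                                           config.met_allele_freq, rng)
    groups = [genotype_to_group(g) for g in genotypes]
    is_met = np.array([g == "Met" for g in groups], dtype=np.float64)

    age = np.round(rng.normal(73.6, 7.9, size=n), 1)
    education = np.clip(np.round(rng.normal(7.4, 4.9, size=n), 1), 0.0, None)
    sex = np.where(rng.random(n) < 95.0 / 192.0, "M", "F")
    apoe4 = (rng.random(n) < 66.0 / 192.0).astype(int)

    signal = np.zeros((n,) + shape, dtype=np.float64)
    latents: dict[str, list[float]] = {}
    for template in config.templates:
        s = rng.normal(0.0, config.latent_sd, size=n)
        latents[template.seed_name] = s.tolist()
        seed_field, target_field, _ = template_fields(config, template)
        slope = np.where(is_met == 1.0, template.slope_met, template.slope_val)
        signal += s[:, None, None, None] * seed_field[None]
        signal += (slope * s)[:, None, None, None] * target_field[None]

    data = baseline_map(config)[None] + signal
    data += rng.normal(0.0, config.noise_sd, size=(n,) + shape)
    if config.smoothing_fwhm_mm > 0:
        voxel_size = np.full(3, config.voxel_mm)
        for i in range(n):
            data[i] = smooth_array(data[i], voxel_size, config.smoothing_fwhm_mm)
    if config.clip_negative:
        np.clip(data, 0.0, None, out=data)

    pheno = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:03d}" for i in range(n)],
            "genotype": genotypes,
            "group": groups,
            "age": age,
            "education": education,
            "sex": sex,
            "apoe4": apoe4,
        }
    )
    cohort = Cohort(data=data, affine=affine, phenotypes=pheno)

    for score, seed_name, intercept, slope, score_noise in config.behavior_couplings:
        seed = seed_by_name(seed_name)
        roi = SphereROI(seed_name, seed.mni_xyz, config.sphere_radius_mm)
        vol = extract_volumes(cohort, [roi])[seed_name].to_numpy()
        scores = intercept + slope * vol + rng.normal(0.0, score_noise, size=n)
        cohort.phenotypes[score] = np.round(scores, 2)

    ground_truth = {
        "config": config.to_dict(),
        "latents": latents,
        "groups": groups,
    }
    return cohort, ground_truth


def write_cohort(cohort: Cohort, ground_truth: dict | None, directory) -> list[str]:
    """Write a cohort: one float32 NIfTI per subject, ``phenotypes.tsv``,
    and (for synthetic cohorts) the ``simulation.json`` ground-truth
    sidecar.  Returns the written file names."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for i, sid in enumerate(cohort.phenotypes["subject_id"]):
        path = directory / f"{sid}.nii.gz"
        write_volume(GMVolume(data=cohort.data[i], affine=cohort.affine), path)
        written.append(path.name)
    write_phenotypes(cohort.phenotypes, directory / "phenotypes.tsv")
    written.append("phenotypes.tsv")
    if ground_truth is not None:
        with open(directory / "simulation.json", "w") as fh:
            json.dump(ground_truth, fh, indent=2, sort_keys=True)
        written.append("simulation.json")
    return written
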