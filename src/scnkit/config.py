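"""Analysis configuration: every threshold and ambiguous default in one place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml


@dataclass
class AnalysisConfig:
    """Thresholds and options for a full SCN analysis run.

    Parameters
    ----------
    scn_q : float
        Voxel-level Benjamini-Hochberg FDR level for the per-group SCN maps
        and the interaction maps (default 0.01).
    group_q : float
        FDR level for the voxel-wise group-difference (VBM) comparison
        (default 0.05).
    min_cluster_voxels : int
        Cluster-extent threshold: connected suprathreshold components
        smaller than this many voxels are discarded (default 100).
    sphere_radius_mm : float
        Radius of the seed and peak-voxel spheres in millimetres (default 4).
    smoothing_fwhm_mm : float
        Gaussian kernel FWHM applied when ``apply_smoothing`` is on
        (default 8 mm, the conventional VBM kernel).
    apply_smoothing : bool
        Re-smooth input volumes before analysis.  Off by default: the
        pipeline expects already-smoothed modulated GM maps.
    mask_threshold : float
        Mean-GM-density threshold defining the analysis mask (default 0.1).
    proportional_scaling : bool
        Divide each image by its total GM volume before regression.
        Off by default.
    nuisance : tuple of str
        Phenotype columns added as nuisance regressors to every voxel-wise
        model (e.g. ``("age", "sex")``).  Empty by default.
    connectivity : int
        Cluster neighbourhood rule: 6 (faces), 18 (faces+edges, default)
        or 26 (faces+edges+corners).
    alpha : float
        Significance level for scalar tests (default 0.05).
    fdr_adjust_correlations : bool
        Apply BH adjustment to the correlation tables instead of flagging
        raw p-values at 0.05/0.01.  Off by default.
    welch : bool
        Use Welch's t test instead of pooled-variance Student t.
    chi2_correction : bool
        Apply Yates continuity correction in 2x2 chi-square tests.
    seeds : tuple of str or None
        Restrict the analysis to these seed names; None means all ten.
    rng_seed : int
        Seed for any stochastic step.
    """

    scn_q: float = 0.01
    group_q: float = 0.05
    min_cluster_voxels: int = 100
    sphere_radius_mm: float = 4.0
    smoothing_fwhm_mm: float = 8.0
    apply_smoothing: bool = False
    mask_threshold: float = 0.1
    proportional_scaling: bool = False
    nuisance: tuple = field(default_factory=tuple)
    connectivity: int = 18
    alpha: float = 0.05
    fdr_adjust_correlations: bool = False
    welch: bool = False
    chi2_correction: bool = False
    seeds: tuple | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("scn_q", "group_q"):
            q = getattr(self, name)
            if not 0.0 < q < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {q}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.min_cluster_voxels < 1:
            raise ValueError("min_cluster_voxels must be >= 1")
        if self.sphere_radius_mm < 0:
            raise ValueError("sphere_radius_mm must be >= 0")
        if self.smoothing_fwhm_mm < 0:
            raise ValueError("smoothing_fwhm_mm must be >= 0")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be one of 6, 18, 26")
        self.nuisance = tuple(self.nuisance)
        if self.seeds is not None:
            self.seeds = tuple(self.seeds)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["nuisance"] = list(self.nuisance)
        d["seeds"] = None if self.seeds is None else list(self.seeds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)
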