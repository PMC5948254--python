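"""Mass-univariate GLM, FDR thresholding, cluster extraction, SCN construction.

The structural covariance network (SCN) for a seed is the map of voxels
whose GM density regresses positively on the seed's extracted sphere
volume across subjects.  Per voxel, ordinary least squares of intensity on
a shared design matrix gives a slope, a Student-t statistic and a p-value;
Benjamini-Hochberg FDR at level q selects voxels within the analysis mask,
and connected suprathreshold components larger than a minimum extent are
reported as clusters with their peak-T voxel in MNI coordinates.

The estimators (`SeedCovarianceNetwork`, `GroupDifference`) follow the
scikit-learn protocol: parameters at construction, ``fit(cohort)``, fitted
attributes with a trailing underscore.  The module-level functions are
thin wrappers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig
from .images import analysis_mask
from .roi import SeedSpec, extract_volumes, seed_by_name, sphere_mask

logger = logging.getLogger(__name__)

#: scipy.ndimage connectivity rank for the 6/18/26-neighbourhood rules
_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class StatMap:
    """Per-voxel statistics for one contrast in one fit.

    ``beta``, ``tstat`` and ``p`` share one shape: flat ``(m,)`` arrays for
    a bare matrix fit, or full 3D maps (with ``mask`` and ``affine`` set)
    for an image-space analysis.  ``q_mask`` marks FDR survivors.
    """

    beta: np.ndarray
    tstat: np.ndarray
    p: np.ndarray
    df: int
    contrast_label: str
    sided: str
    q_mask: np.ndarray | None = None
    mask: np.ndarray | None = None
    affine: np.ndarray | None = None
    n_zero_variance: int = 0


@dataclass
class ClusterRecord:
    """A connected suprathreshold component with its peak voxel."""

    cluster_id: int
    size_voxels: int
    peak_mni_xyz: tuple[float, float, float]
    peak_t: float
    peak_index: tuple[int, int, int]
    members: np.ndarray = field(repr=False)  # (size, 3) voxel indices


def fit_voxelwise(Y, X, contrast_index: int, sided: str = "two",
                  contrast_label: str = "") -> StatMap:
    """Vectorized per-voxel OLS of ``Y`` (n_subjects x m_voxels) on ``X``.

    T = beta / SE for the ``contrast_index`` column, p from Student-t with
    ``n - rank(X)`` degrees of freedom; ``sided`` is ``"two"``, ``"pos"``
    (upper tail) or ``"neg"``.  Numerically identical to fitting each voxel
    separately.  Voxels with zero residual variance get a ``+inf`` T
    sentinel with p = 0 and are counted in ``n_zero_variance``.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("design matrix must be 2D")
    n, k = X.shape
    if Y.shape[0] != n:
        raise ValueError(f"Y has {Y.shape[0]} rows but design has {n}")
    if sided not in ("two", "pos", "neg"):
        raise ValueError("sided must be 'two', 'pos' or 'neg'")
    if not 0 <= contrast_index < k:
        raise ValueError("contrast_index out of range")
    if np.linalg.matrix_rank(X) < k:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    if n <= k:
        raise ValueError(f"need more subjects ({n}) than design columns ({k})")

    df = n - k
    beta_all, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta_all
    rss = np.einsum("ij,ij->j", resid, resid)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = beta_all[contrast_index]

    # residual variance indistinguishable from zero relative to data scale
    yss = np.einsum("ij,ij->j", Y, Y)
    zero_var = rss <= 1e-24 + 1e-14 * yss
    if zero_var.any():
        logger.info("fit_voxelwise: %d voxel(s) with zero residual variance", int(zero_var.sum()))

    sigma2 = rss / df
    se = np.sqrt(sigma2 * xtx_inv[contrast_index, contrast_index])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    t[zero_var] = np.inf

    if sided == "two":
        p = 2.0 * stats.t.sf(np.abs(t), df)
    elif sided == "pos":
        p = stats.t.sf(t, df)
    else:
        p = stats.t.cdf(t, df)
    p[zero_var] = 0.0

    return StatMap(
        beta=beta,
        tstat=t,
        p=p,
        df=df,
        contrast_label=contrast_label,
        sided=sided,
        n_zero_variance=int(zero_var.sum()),
    )


def fdr_select(p_values, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up selection at FDR level ``q``.

    Sort the m p-values, find the largest k with p_(k) <= k*q/m, and
    select every p-value at or below p_(k); nothing is selected when no
    such k exists.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must lie in (0, 1), got {q}")
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return reject.reshape(p.shape)


def extract_clusters(selection_mask, tstat, min_size: int, connectivity: int = 18,
                     affine=None) -> list[ClusterRecord]:
    """Connected components of a suprathreshold mask, filtered by extent.

    Components under the given neighbourhood rule (6, 18 or 26) with fewer
    than ``min_size`` voxels are discarded.  Each record's peak is the
    member voxel with maximal T (ties broken by lexicographic voxel
    index); records are sorted by descending peak T.
    """
    mask = np.asarray(selection_mask, dtype=bool)
    t = np.asarray(tstat, dtype=np.float64)
    if mask.shape != t.shape:
        raise ValueError("selection mask and tstat must share geometry")
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError("connectivity must be one of 6, 18, 26")
    if affine is None:
        affine = np.eye(4)
    affine = np.asarray(affine, dtype=np.float64)

    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, n_labels = ndimage.label(mask, structure=structure)
    records = []
    for lab in range(1, n_labels + 1):
        members = np.argwhere(labels == lab)  # lexicographically sorted
        if len(members) < min_size:
            continue
        tvals = t[members[:, 0], members[:, 1], members[:, 2]]
        peak_pos = int(np.argmax(tvals))  # first max in lex order breaks ties
        peak_idx = tuple(int(c) for c in members[peak_pos])
        peak_mni = affine[:3, :3] @ np.asarray(peak_idx, dtype=np.float64) + affine[:3, 3]
        records.append(
            ClusterRecord(
                cluster_id=0,
                size_voxels=len(members),
                peak_mni_xyz=tuple(float(c) for c in peak_mni),
                peak_t=float(tvals[peak_pos]),
                peak_index=peak_idx,
                members=members,
            )
        )
    records.sort(key=lambda r: (-r.peak_t, r.peak_index))
    for i, rec in enumerate(records, start=1):
        rec.cluster_id = i
    return records


def _expand(flat: np.ndarray, mask: np.ndarray, fill: float) -> np.ndarray:
    out = np.full(mask.shape, fill, dtype=np.float64)
    out[mask] = flat
    return out


def _build_design(cohort, covariate: np.ndarray | None, nuisance: tuple) -> np.ndarray:
    cols = [np.ones(cohort.n_subjects)]
    if covariate is not None:
        cols.append(np.asarray(covariate, dtype=np.float64))
    for name in nuisance:
        col = cohort.phenotypes[name]
        if col.dtype == object:  # e.g. sex coded M/F
            col = col.astype("category").cat.codes
        cols.append(np.asarray(col, dtype=np.float64))
    return np.column_stack(cols)


class _VoxelwiseMapper(BaseEstimator):
    """Shared machinery: mask, design, masked fit, FDR, clusters."""

    def _fit_map(self, cohort, covariate, contrast_index, sided, q,
                 contrast_label, exclude_mask=None):
        mask = analysis_mask(cohort, self.mask_threshold)
        if not mask.any():
            raise ValueError("analysis mask is empty; lower mask_threshold")
        Y = cohort.data.reshape(cohort.n_subjects, -1)[:, mask.ravel()]
        X = _build_design(cohort, covariate, tuple(self.nuisance))
        flat = fit_voxelwise(Y, X, contrast_index, sided, contrast_label)
        selected = fdr_select(flat.p, q)
        sel3d = np.zeros(mask.shape, dtype=bool)
        sel3d[mask] = selected
        if exclude_mask is not None:
            sel3d &= ~exclude_mask
        t3d = _expand(flat.tstat, mask, 0.0)
        stat_map = StatMap(
            beta=_expand(flat.beta, mask, 0.0),
            tstat=t3d,
            p=_expand(flat.p, mask, 1.0),
            df=flat.df,
            contrast_label=contrast_label,
            sided=sided,
            q_mask=sel3d,
            mask=mask,
            affine=cohort.affine,
            n_zero_variance=flat.n_zero_variance,
        )
        clusters = extract_clusters(
            sel3d, t3d, self.min_cluster_voxels, self.connectivity, cohort.affine
        )
        return stat_map, clusters


class SeedCovarianceNetwork(_VoxelwiseMapper):
    """Seed-based structural covariance network for one subject group.

    Fits, per voxel, ``GM(v) ~ 1 + seed_volume (+ nuisance)`` by OLS and
    selects voxels with a significantly positive slope (one-sided T,
    BH-FDR at ``q`` within the analysis mask, cluster extent
    >= ``min_cluster_voxels``).  The seed's own sphere is excluded from
    cluster reporting, since self-covariance is trivial.

    Parameters
    ----------
    seed_name : str
        One of the ten default seeds, or any name resolvable by
        :func:`scnkit.roi.seed_by_name`.
    q : float
        Voxel-level FDR level (default 0.01).
    min_cluster_voxels, connectivity, sphere_radius_mm, mask_threshold,
    nuisance : see :class:`scnkit.config.AnalysisConfig`.

    Attributes
    ----------
    stat_map_ : StatMap
        3D slope/T/p maps with the FDR survival mask.
    clusters_ : list of ClusterRecord
        Extent-thresholded clusters, sorted by descending peak T.
    seed_volumes_ : ndarray
        Extracted seed sphere volume per subject (mL), the covariate.
    """

    def __init__(self, seed_name: str = "dorsal_caudal_putamen", q: float = 0.01,
                 min_cluster_voxels: int = 100, connectivity: int = 18,
                 sphere_radius_mm: float = 4.0, mask_threshold: float = 0.1,
                 nuisance: tuple = ()):
        self.seed_name = seed_name
        self.q = q
        self.min_cluster_voxels = min_cluster_voxels
        self.connectivity = connectivity
        self.sphere_radius_mm = sphere_radius_mm
        self.mask_threshold = mask_threshold
        self.nuisance = nuisance

    def fit(self, cohort, y=None):
        if cohort.n_subjects == 0:
            raise ValueError("cannot fit an SCN on an empty group")
        seed = seed_by_name(self.seed_name)
        spec = SeedSpec(seed.name, seed.model, seed.mni_xyz, self.sphere_radius_mm)
        self.seed_volumes_ = extract_volumes(cohort, [spec])[spec.name].to_numpy()
        seed_sphere = sphere_mask(
            cohort.image_shape, cohort.affine, spec.mni_xyz, self.sphere_radius_mm
        )
        self.stat_map_, self.clusters_ = self._fit_map(
            cohort,
            covariate=self.seed_volumes_,
            contrast_index=1,
            sided="pos",
            q=self.q,
            contrast_label=f"SCN[{self.seed_name}]+",
            exclude_mask=seed_sphere,
        )
        return self


class GroupDifference(_VoxelwiseMapper):
    """Voxel-wise two-sided group comparison (VBM-style) of GM density.

    Fits ``GM(v) ~ 1 + group (+ nuisance)`` with group coded Val = 0,
    Met = 1, two-sided T on the group column, BH-FDR at ``q`` (default
    0.05) and the same cluster-extent rule as the SCN maps.
    """

    def __init__(self, q: float = 0.05, min_cluster_voxels: int = 100,
                 connectivity: int = 18, mask_threshold: float = 0.1,
                 nuisance: tuple = ()):
        self.q = q
        self.min_cluster_voxels = min_cluster_voxels
        self.connectivity = connectivity
        self.mask_threshold = mask_threshold
        self.nuisance = nuisance

    def fit(self, cohort, y=None):
        groups = cohort.phenotypes["group"].to_numpy()
        coded = (groups == "Met").astype(np.float64)
        if len(np.unique(groups)) < 2:
            raise ValueError("group comparison needs both groups present")
        self.stat_map_, self.clusters_ = self._fit_map(
            cohort,
            covariate=coded,
            contrast_index=1,
            sided="two",
            q=self.q,
            contrast_label="Met-Val",
        )
        return self


def build_scn(cohort_group, seed_name: str, config: AnalysisConfig | None = None):
    """Construct one group's SCN for one seed; returns (StatMap, clusters)."""
    config = config or AnalysisConfig()
    model = SeedCovarianceNetwork(
        seed_name=seed_name,
        q=config.scn_q,
        min_cluster_voxels=config.min_cluster_voxels,
        connectivity=config.connectivity,
        sphere_radius_mm=config.sphere_radius_mm,
        mask_threshold=config.mask_threshold,
        nuisance=config.nuisance,
    ).fit(cohort_group)
    return model.stat_map_, model.clusters_
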