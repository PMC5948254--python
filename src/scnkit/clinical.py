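"""Scalar statistics: demographics, Hardy-Weinberg, ROI-behavior correlations.

This layer produces the tabular results of a genotype-stratified cohort
study: group comparisons of continuous variables (pooled-variance Student
t) and categorical variables (Pearson chi-square), a Hardy-Weinberg
equilibrium check on genotype counts, and tables of Pearson correlations
between ROI volumes (seed or peak-cluster spheres) and cognitive /
neuropsychiatric scores, per group, flagged at p < 0.05 (*) and
p < 0.01 (**).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import PHENOTYPE_ID_COLUMNS

logger = logging.getLogger(__name__)


def hwe_test(n_mm: int, n_mv: int, n_vv: int) -> tuple[float, float]:
    """Pearson chi-square test of Hardy-Weinberg equilibrium (1 df).

    The allele frequency estimate p_hat = (2*n_MM + n_MV) / (2n) implies
    expected genotype counts (n*p^2, 2n*p*q, n*q^2); the statistic is the
    usual sum of (observed - expected)^2 / expected.

    Returns
    -------
    (chi2, p) : tuple of float
    """
    counts = np.array([n_mm, n_mv, n_vv], dtype=np.float64)
    if np.any(counts < 0):
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise ValueError("total genotype count must be positive")
    p_hat = (2 * counts[0] + counts[1]) / (2 * n)
    q_hat = 1.0 - p_hat
    expected = n * np.array([p_hat**2, 2 * p_hat * q_hat, q_hat**2])
    if p_hat in (0.0, 1.0):  # monomorphic: trivially in equilibrium
        return 0.0, 1.0
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


@dataclass
class GroupComparison:
    """Result of a two-group scalar comparison."""

    kind: str
    statistic: float
    df: float
    p: float
    summary: dict


def compare_groups_scalar(values, groups, kind: str = "continuous",
                          welch: bool = False, correction: bool = False) -> GroupComparison:
    """Two-group comparison of one variable.

    ``kind="continuous"``: two-sided Student t test (pooled variance by
    default, Welch optional), reporting per-group mean and SD.
    ``kind="categorical"``: Pearson chi-square on the group x level
    contingency table (no continuity correction by default), reporting
    per-group counts.
    """
    values = np.asarray(values)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must align")
    labels = sorted(set(groups.tolist()))
    if len(labels) != 2:
        raise ValueError(f"expected exactly two groups, got {labels}")
    a = values[groups == labels[0]]
    b = values[groups == labels[1]]

    if kind == "continuous":
        if len(a) < 2 or len(b) < 2:
            raise ValueError("each group needs >= 2 observations for a t test")
        a = a.astype(np.float64)
        b = b.astype(np.float64)
        res = stats.ttest_ind(a, b, equal_var=not welch)
        df = res.df if hasattr(res, "df") else len(a) + len(b) - 2
        summary = {
            lab: {"n": int(len(x)), "mean": float(x.mean()), "sd": float(x.std(ddof=1))}
            for lab, x in zip(labels, (a, b))
        }
        return GroupComparison("t", float(res.statistic), float(df), float(res.pvalue), summary)

    if kind == "categorical":
        table = pd.crosstab(groups, values)
        if table.shape[1] < 2:  # variable constant in both groups
            chi2, p, df = 0.0, 1.0, 0
        else:
            chi2, p, df, _ = stats.chi2_contingency(table.to_numpy(), correction=correction)
        summary = {str(lab): {str(k): int(v) for k, v in row.items()}
                   for lab, row in table.iterrows()}
        return GroupComparison("chi2", float(chi2), float(df), float(p), summary)

    raise ValueError("kind must be 'continuous' or 'categorical'")


def _score_columns(phenotypes: pd.DataFrame) -> list[str]:
    return [c for c in phenotypes.columns if c not in PHENOTYPE_ID_COLUMNS]


def correlate_volumes_scores(volume_table: pd.DataFrame, phenotypes: pd.DataFrame,
                             by_group: bool = True, score_columns=None) -> pd.DataFrame:
    """Pearson correlations between ROI volumes and behavioral scores.

    Rows are score names; columns are a (ROI, group) MultiIndex (or just
    ROI when ``by_group`` is off).  Each cell carries r, the two-sided p,
    the pair count n, and significance flags at 0.05 / 0.01.  Rows with
    missing values are dropped pairwise with a logged count; a constant
    column leaves r undefined (NaN) with a log message.
    """
    if len(volume_table) != len(phenotypes):
        raise ValueError("volume table and phenotypes must have equal row counts")
    scores = score_columns if score_columns is not None else _score_columns(phenotypes)
    group_values = (
        sorted(phenotypes["group"].unique()) if by_group else ["all"]
    )
    records = []
    for roi in volume_table.columns:
        vols = volume_table[roi].to_numpy(dtype=np.float64)
        for grp in group_values:
            sel = np.ones(len(phenotypes), dtype=bool) if grp == "all" else (
                (phenotypes["group"] == grp).to_numpy()
            )
            for score in scores:
                sc = pd.to_numeric(phenotypes[score], errors="coerce").to_numpy()
                ok = sel & np.isfinite(sc) & np.isfinite(vols)
                n_dropped = int(sel.sum() - ok.sum())
                if n_dropped:
                    logger.info("correlate: dropped %d subject(s) with missing %s",
                                n_dropped, score)
                n = int(ok.sum())
                if n < 3:
                    raise ValueError(f"need >= 3 paired observations for {roi}/{score}")
                v, s = vols[ok], sc[ok]
                if np.std(v) == 0 or np.std(s) == 0:
                    logger.info("correlate: constant column for %s/%s; r undefined", roi, score)
                    r, p = np.nan, np.nan
                else:
                    r, p = stats.pearsonr(v, s)
                records.append(
                    {"score": score, "roi": roi, "group": grp, "r": float(r),
                     "p": float(p), "n": n,
                     "sig05": bool(np.isfinite(p) and p < 0.05),
                     "sig01": bool(np.isfinite(p) and p < 0.01)}
                )
    if not records:
        return pd.DataFrame()
    long = pd.DataFrame.from_records(records)
    table = long.pivot(index="score", columns=["roi", "group"],
                       values=["r", "p", "n", "sig05", "sig01"])
    table = table.reorder_levels([1, 2, 0], axis=1).sort_index(axis=1)
    # keep the caller's score ordering
    return table.loc[[s for s in scores if s in table.index]]


def format_percentage(count: int, total: int) -> str:
    """Count with percentage to two decimals, e.g. ``"32, 35.16%"``."""
    if total <= 0:
        raise ValueError("total must be positive")
    return f"{count}, {100.0 * count / total:.2f}%"


def demographics_report(phenotypes: pd.DataFrame, continuous=None, categorical=None,
                        welch: bool = False, chi2_correction: bool = False) -> pd.DataFrame:
    """Group-wise demographics table: mean +/- SD or count (percentage), with
    the between-group test p-value per variable.

    ``continuous`` / ``categorical`` name phenotype columns; by default all
    score columns plus age and education are treated as continuous and
    sex / apoe4 as categorical.
    """
    groups = phenotypes["group"].to_numpy()
    labels = sorted(set(groups.tolist()))
    if continuous is None:
        continuous = ["age", "education"] + _score_columns(phenotypes)
        continuous = [c for c in continuous if c in phenotypes.columns]
    if categorical is None:
        categorical = [c for c in ("sex", "apoe4") if c in phenotypes.columns]

    rows = []
    for var in continuous:
        vals = pd.to_numeric(phenotypes[var], errors="coerce").to_numpy()
        ok = np.isfinite(vals)
        res = compare_groups_scalar(vals[ok], groups[ok], "continuous", welch=welch)
        row = {"variable": var, "type": "continuous", "p": res.p}
        for lab in labels:
            cell = res.summary[lab]
            row[lab] = f"{cell['mean']:.2f} ± {cell['sd']:.2f}"
        rows.append(row)
    for var in categorical:
        vals = phenotypes[var].to_numpy()
        res = compare_groups_scalar(vals, groups, "categorical",
                                    correction=chi2_correction)
        row = {"variable": var, "type": "categorical", "p": res.p}
        for lab in labels:
            counts = res.summary[str(lab)]
            total = sum(counts.values())
            # report the "positive" level for binary 0/1 variables,
            # otherwise the full level breakdown
            keys = sorted(counts)
            if set(keys) <= {"0", "1"}:
                row[lab] = format_percentage(counts.get("1", 0), total)
            else:
                row[lab] = "/".join(f"{k}:{counts[k]}" for k in keys)
        rows.append(row)
    report = pd.DataFrame(rows, columns=["variable", "type", *labels, "p"])
    return report
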