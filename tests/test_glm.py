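"""Mass-univariate OLS, BH-FDR selection, cluster extraction, SCN recovery."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from scnkit.config import AnalysisConfig
from scnkit.glm import (
    build_scn,
    extract_clusters,
    fdr_select,
    fit_voxelwise,
)
from scnkit.simulate import template_fields


class TestFitVoxelwise:
    def test_exact_linear_voxel_hits_zero_variance_sentinel(self):
        seed = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        X = np.column_stack([np.ones(5), seed])
        y = (3.0 * seed + 5.0)[:, None]
        res = fit_voxelwise(y, X, contrast_index=1)
        assert res.beta[0] == pytest.approx(3.0, rel=1e-12)
        assert np.isinf(res.tstat[0]) and res.p[0] == 0.0
        assert res.n_zero_variance == 1

    def test_matches_closed_form_simple_regression(self):
        """Six-subject, one-voxel fixture against the textbook formulas."""
        x = np.array([0.11, 0.13, 0.09, 0.15, 0.12, 0.10])
        y = np.array([0.52, 0.61, 0.48, 0.67, 0.55, 0.50])
        n = 6
        sxx = ((x - x.mean()) ** 2).sum()
        slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        resid = y - (y.mean() + slope * (x - x.mean()))
        se = np.sqrt((resid**2).sum() / (n - 2) / sxx)
        t_expected = slope / se
        p_expected = 2 * stats.t.sf(abs(t_expected), n - 2)

        res = fit_voxelwise(y[:, None], np.column_stack([np.ones(n), x]), 1)
        assert res.beta[0] == pytest.approx(slope, rel=1e-10)
        assert res.tstat[0] == pytest.approx(t_expected, rel=1e-10)
        assert res.p[0] == pytest.approx(p_expected, rel=1e-10)
        assert res.df == 4

    def test_matches_statsmodels_per_voxel(self, rng):
        """Vectorized fit is numerically identical to independent OLS fits."""
        import statsmodels.api as sm

        n, m = 25, 40
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        Y = rng.normal(size=(n, m))
        res = fit_voxelwise(Y, X, contrast_index=1, sided="two")
        for j in range(m):
            fit = sm.OLS(Y[:, j], X).fit()
            assert res.beta[j] == pytest.approx(fit.params[1], rel=1e-8)
            assert res.tstat[j] == pytest.approx(fit.tvalues[1], rel=1e-8)
            assert res.p[j] == pytest.approx(fit.pvalues[1], rel=1e-8, abs=1e-12)

    def test_null_pvalues_uniform(self, rng):
        n, m = 60, 2000
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        Y = rng.normal(size=(n, m))
        res = fit_voxelwise(Y, X, 1, sided="pos")
        ks = stats.kstest(res.p, "uniform").statistic
        assert ks < 1.36 / np.sqrt(m)  # 5% critical value

    def test_rank_deficient_design_rejected(self, rng):
        x = rng.normal(size=10)
        X = np.column_stack([np.ones(10), x, x])
        with pytest.raises(np.linalg.LinAlgError):
            fit_voxelwise(rng.normal(size=(10, 3)), X, 1)

    def test_more_columns_than_subjects_rejected(self, rng):
        X = rng.normal(size=(3, 3))
        with pytest.raises(ValueError):
            fit_voxelwise(rng.normal(size=(3, 2)), X, 0)


def bh_oracle(p, q):
    """Textbook step-up rule, implemented independently."""
    p = np.asarray(p, float)
    m = len(p)
    ps = np.sort(p)
    k = 0
    for rank in range(1, m + 1):
        if ps[rank - 1] <= rank * q / m:
            k = rank
    if k == 0:
        return np.zeros(m, dtype=bool)
    return p <= ps[k - 1]


class TestFdrSelect:
    def test_worked_example(self):
        sel = fdr_select([0.001, 0.02, 0.03, 0.5], q=0.05)
        np.testing.assert_array_equal(sel, [True, True, True, False])

    def test_all_ones_select_nothing(self):
        assert not fdr_select(np.ones(7), q=0.05).any()

    def test_single_test_reduces_to_p_below_q(self):
        assert fdr_select([0.04], q=0.05)[0]
        assert not fdr_select([0.06], q=0.05)[0]

    def test_invalid_q_rejected(self):
        with pytest.raises(ValueError):
            fdr_select([0.5], q=1.5)

    def test_exhaustive_enumeration_matches_textbook_rule(self):
        """All 2^10 vectors from a two-level p-grid agree with the oracle."""
        lo = np.array([0.002, 0.004, 0.008, 0.011, 0.02, 0.03, 0.04, 0.06, 0.09, 0.2])
        hi = np.array([0.05, 0.1, 0.15, 0.3, 0.4, 0.5, 0.6, 0.7, 0.9, 1.0])
        for bits in range(1024):
            take = np.array([(bits >> i) & 1 for i in range(10)], dtype=bool)
            p = np.where(take, hi, lo)
            np.testing.assert_array_equal(fdr_select(p, 0.05), bh_oracle(p, 0.05),
                                          err_msg=f"bits={bits:010b}")

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    def test_raising_q_never_shrinks_selection(self, p):
        tight = fdr_select(p, 0.01)
        loose = fdr_select(p, 0.10)
        assert not (tight & ~loose).any()


def flood_fill_oracle(mask, connectivity):
    """Brute-force BFS connected components."""
    reach = {6: 1, 18: 2, 26: 3}[connectivity]
    offsets = [
        (di, dj, dk)
        for di in (-1, 0, 1) for dj in (-1, 0, 1) for dk in (-1, 0, 1)
        if (di, dj, dk) != (0, 0, 0) and abs(di) + abs(dj) + abs(dk) <= reach
    ]
    todo = {tuple(v) for v in np.argwhere(mask)}
    components = []
    while todo:
        frontier = [todo.pop()]
        comp = set(frontier)
        while frontier:
            i, j, k = frontier.pop()
            for di, dj, dk in offsets:
                nb = (i + di, j + dj, k + dk)
                if nb in todo:
                    todo.remove(nb)
                    comp.add(nb)
                    frontier.append(nb)
        components.append(frozenset(comp))
    return set(components)


class TestExtractClusters:
    def test_extent_threshold_semantics(self):
        mask = np.zeros((20, 20, 20), dtype=bool)
        mask[1:4, 1:11, 1:6] = True  # 150 voxels
        mask[10:12, 10:15, 10:15] = True  # 50 voxels
        t = np.random.default_rng(0).random((20, 20, 20))
        recs = extract_clusters(mask, t, min_size=100, connectivity=18)
        assert len(recs) == 1 and recs[0].size_voxels == 150

    def test_empty_mask(self):
        recs = extract_clusters(np.zeros((5, 5, 5), bool), np.zeros((5, 5, 5)), 1)
        assert recs == []

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, connectivity, rng):
        for _ in range(25):
            mask = rng.random((12, 12, 12)) < 0.25
            t = rng.normal(size=(12, 12, 12))
            recs = extract_clusters(mask, t, min_size=1, connectivity=connectivity)
            got = {frozenset(map(tuple, r.members)) for r in recs}
            assert got == flood_fill_oracle(mask, connectivity)
            # peak bookkeeping: member with max T, records sorted descending
            for r in recs:
                member_t = t[r.members[:, 0], r.members[:, 1], r.members[:, 2]]
                assert r.peak_t == member_t.max()
            peaks = [r.peak_t for r in recs]
            assert peaks == sorted(peaks, reverse=True)

    def test_raising_min_size_never_adds_clusters(self, rng):
        mask = rng.random((15, 15, 15)) < 0.3
        t = rng.normal(size=(15, 15, 15))
        n_small = len(extract_clusters(mask, t, min_size=2))
        n_large = len(extract_clusters(mask, t, min_size=10))
        assert n_large <= n_small

    def test_peak_tie_broken_lexicographically(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1, 1, 1] = mask[1, 1, 2] = True
        t = np.zeros((4, 4, 4))
        t[1, 1, 1] = t[1, 1, 2] = 3.0
        rec = extract_clusters(mask, t, min_size=1)[0]
        assert rec.peak_index == (1, 1, 1)


class TestBuildScn:
    def test_recovers_planted_network(self, fixture_cohort):
        """Met-group SCN clusters overlap the planted blobs (Dice >= 0.5)."""
        config, cohort, truth = fixture_cohort
        met = cohort.select_group("Met")
        stat_map, clusters = build_scn(met, "dorsal_caudal_putamen", AnalysisConfig())
        assert clusters, "no clusters recovered"
        _, _, support = template_fields(config, config.templates[0])
        found = np.zeros(support.shape, dtype=bool)
        for c in clusters:
            found[c.members[:, 0], c.members[:, 1], c.members[:, 2]] = True
        dice = 2 * (found & support).sum() / (found.sum() + support.sum())
        assert dice >= 0.5

    def test_permuting_subjects_leaves_map_unchanged(self, small_cohort):
        _, cohort, _ = small_cohort
        rng = np.random.default_rng(0)
        perm = rng.permutation(cohort.n_subjects)
        m1, _ = build_scn(cohort, "dorsal_caudal_putamen")
        m2, _ = build_scn(cohort.subset(perm), "dorsal_caudal_putamen")
        np.testing.assert_allclose(m1.tstat, m2.tstat, rtol=1e-8, atol=1e-10)

    def test_seed_sphere_excluded_from_clusters(self, fixture_cohort):
        from scnkit.roi import seed_by_name, sphere_mask

        config, cohort, _ = fixture_cohort
        met = cohort.select_group("Met")
        stat_map, clusters = build_scn(met, "dorsal_caudal_putamen")
        seed = seed_by_name("dorsal_caudal_putamen")
        sphere = sphere_mask(cohort.image_shape, cohort.affine, seed.mni_xyz, 4.0)
        for c in clusters:
            member_mask = np.zeros(sphere.shape, dtype=bool)
            member_mask[c.members[:, 0], c.members[:, 1], c.members[:, 2]] = True
            assert not (member_mask & sphere).any()
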