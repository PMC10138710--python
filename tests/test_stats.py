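"""Statistical battery: distances, PERMANOVA, PCoA, exact tests, FDR."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from guildnet.stats import (DistanceMatrix, bh_fdr, bray_curtis, fisher_exact,
                            jensen_shannon, kruskal_wallis, pcoa, permanova,
                            rank_tests, robust_linreg, spearman)


def frame(rows, index=None):
    rows = np.asarray(rows, dtype=float)
    idx = index or [f"S{i}" for i in range(rows.shape[0])]
    return pd.DataFrame(rows, index=idx)


class TestBrayCurtis:
    def test_identical_samples_distance_zero(self):
        d = bray_curtis(frame([[1, 2, 3], [1, 2, 3]]))
        assert d.values[0, 1] == pytest.approx(0.0)

    def test_disjoint_supports_distance_one(self):
        d = bray_curtis(frame([[1, 0], [0, 5]]))
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_hand_computed_pair(self):
        d = bray_curtis(frame([[0.2, 0.8], [0.4, 0.6]]))
        assert d.values[0, 1] == pytest.approx(0.2)

    def test_two_all_zero_samples_undefined(self):
        d = bray_curtis(frame([[0, 0], [0, 0], [1, 1]]))
        assert np.isnan(d.values[0, 1])
        assert not np.isnan(d.values[0, 2])

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis(frame([[1, -1], [0, 1]]))


class TestPermanova:
    def test_extreme_separation_reaches_minimal_p(self):
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal(0, 0.01, (6, 3)), rng.normal(100, 0.01, (6, 3))])
        d = bray_curtis(frame(np.abs(x)))
        res = permanova(d, ["a"] * 6 + ["b"] * 6, n_perm=199, seed=1)
        assert res.p == pytest.approx(1 / 200)
        assert 0 <= res.r2 <= 1

    def test_duplicating_samples_preserves_r2(self):
        rng = np.random.default_rng(1)
        x = np.abs(rng.normal(1, 0.3, (8, 5)))
        labels = ["a"] * 4 + ["b"] * 4
        r2_once = permanova(bray_curtis(frame(x)), labels, n_perm=99, seed=0).r2
        xx = np.vstack([x, x])
        r2_twice = permanova(bray_curtis(frame(xx)), labels * 2, n_perm=99, seed=0).r2
        assert r2_twice == pytest.approx(r2_once, abs=1e-9)

    def test_single_group_rejected(self):
        d = bray_curtis(frame([[1, 2], [2, 1], [1, 1]]))
        with pytest.raises(ValueError):
            permanova(d, ["a", "a", "a"])

    def test_matches_scikit_bio_on_small_example(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(5)
        x = np.abs(rng.normal(1, 0.5, (10, 6)))
        d = bray_curtis(frame(x))
        labels = ["a"] * 5 + ["b"] * 5
        mine = permanova(d, labels, n_perm=999, seed=0)
        dm = skbio_stats.DistanceMatrix(d.values, ids=list(d.ids))
        theirs = skbio_stats.permanova(dm, grouping=labels, permutations=999)
        assert mine.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-9)
        assert abs(mine.p - theirs["p-value"]) < 0.05  # both are MC estimates


class TestPcoa:
    def test_reconstructs_planar_configuration(self):
        pts = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 4.0]])
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        res = pcoa(DistanceMatrix(pd.Index(["a", "b", "c"]), d))
        coords = res.coordinates.to_numpy()
        rec = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        assert np.allclose(rec, d, atol=1e-8)

    def test_equilateral_three_points_equal_eigenvalues(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = pcoa(DistanceMatrix(pd.Index(list("abc")), d))
        pos = res.eigenvalues[res.eigenvalues > 1e-12]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1])

    def test_duplicate_points_coincide(self):
        pts = np.array([[0.0], [0.0], [5.0]])
        d = np.abs(pts - pts.T)
        res = pcoa(DistanceMatrix(pd.Index(list("abc")), d))
        assert np.allclose(res.coordinates.iloc[0], res.coordinates.iloc[1],
                           atol=1e-10)

    def test_axes_limit_enforced(self):
        d = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(ValueError):
            pcoa(DistanceMatrix(pd.Index(list("abc")), d), n_axes=3)


def _fisher_enumeration(table):
    """Independent oracle: exhaustive hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    p_obs = (math.comb(r1, a) * math.comb(r2, c)) / math.comb(n, c1)
    total = 0.0
    for aa in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = (math.comb(r1, aa) * math.comb(r2, c1 - aa)) / math.comb(n, c1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


class TestFisherExact:
    def test_study_table_two_decimals(self):
        # 4/13 vs 11/16 male participants across the two FCP arms
        assert fisher_exact([[4, 9], [11, 5]]) == pytest.approx(0.07, abs=5e-3)

    def test_balanced_table_p_one(self):
        assert fisher_exact([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_perfectly_separated_table(self):
        assert fisher_exact([[10, 0], [0, 10]]) == pytest.approx(2 / 184756, rel=1e-9)

    def test_matches_enumeration_for_all_small_tables(self):
        for n in range(2, 13):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        t = [[a, b], [c, d]]
                        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                            continue
                        assert fisher_exact(t) == pytest.approx(
                            _fisher_enumeration(t), rel=1e-9), t

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -2], [3, 4]])


class TestBhFdr:
    def test_single_p_passes_through(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_step_up(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_and_dominates_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        q = bh_fdr(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(1)
        p = rng.uniform(size=40)
        assert np.allclose(bh_fdr(p), multipletests(p, method="fdr_bh")[1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


def _mannwhitney_enumeration(x, y):
    """Exact two-sided Mann-Whitney p by enumerating group assignments."""
    pooled = np.concatenate([x, y])
    nx = len(x)
    idx = range(len(pooled))

    def u_stat(ix):
        xs = pooled[list(ix)]
        ys = np.delete(pooled, list(ix))
        u = sum((xs[:, None] > ys[None, :]).sum() +
                0.5 * (xs[:, None] == ys[None, :]).sum() for _ in [0])
        return u

    u_obs = u_stat(range(nx))
    n_tot = 0
    n_ext = 0
    mu = nx * len(y) / 2
    for comb in itertools.combinations(idx, nx):
        u = u_stat(comb)
        n_tot += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            n_ext += 1
    return n_ext / n_tot


class TestRankTests:
    def test_identical_groups_large_p(self):
        _, p = rank_tests([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert p > 0.9

    def test_complete_separation_minimal_u(self):
        u, p = rank_tests(list(range(10)), list(range(100, 110)))
        assert u == 0.0
        assert p < 1e-3

    def test_exact_mode_matches_enumeration(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 5)
        y = rng.normal(0.8, 1, 5)
        _, p = rank_tests(x, y)
        assert p == pytest.approx(_mannwhitney_enumeration(x, y), rel=1e-9)

    def test_paired_wilcoxon_runs_and_drops_zeros(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        y = x + np.array([0.0, 0.5, -0.2, 0.8, 0.3, 0.9, 0.1])
        stat, p = rank_tests(x, y, paired=True)
        assert 0 <= p <= 1

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            rank_tests([1.0, 2.0], [1.0, 2.0], paired=True)


class TestKruskalWallis:
    def test_constant_everything_p_one(self):
        h, p = kruskal_wallis([[1, 1], [1, 1], [1, 1]])
        assert p == 1.0

    def test_separated_groups_near_maximal_h(self):
        groups = [[1, 2, 3], [11, 12, 13], [21, 22, 23]]
        h, p = kruskal_wallis(groups)
        # maximal H for g fully separated equal groups: (n-1) - something small
        h_ref = sps.kruskal(*groups)[0]
        assert h == pytest.approx(h_ref)
        assert p < 0.05

    def test_monotone_in_separation(self):
        base = [[1, 2, 3, 4], [3, 4, 5, 6]]
        far = [[1, 2, 3, 4], [13, 14, 15, 16]]
        assert kruskal_wallis(far)[0] > kruskal_wallis(base)[0]

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])


class TestRobustRegression:
    def test_noiseless_line_exact(self):
        x = np.linspace(0, 1, 30)
        X = np.column_stack([np.ones_like(x), x])
        fit = robust_linreg(X, 2.0 + 3.0 * x)
        assert np.allclose(fit.params, [2.0, 3.0], atol=1e-8)

    def test_clean_gaussian_close_to_ols(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(500)
        X = np.column_stack([np.ones_like(x), x])
        y = 1.0 + 2.0 * x + rng.standard_normal(500)
        fit = robust_linreg(X, y)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(fit.params, ols, rtol=5e-3, atol=5e-3)

    def test_resists_gross_outlier(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(50)
        X = np.column_stack([np.ones_like(x), x])
        y = 1.0 + 2.0 * x + 0.2 * rng.standard_normal(50)
        y[0] += 200.0
        robust = robust_linreg(X, y).params[1]
        ols = np.linalg.lstsq(X, y, rcond=None)[0][1]
        assert abs(robust - 2.0) < abs(ols - 2.0)

    def test_rank_deficient_rejected(self):
        X = np.ones((10, 2))
        with pytest.raises(ValueError):
            robust_linreg(X, np.arange(10.0))


class TestSpearman:
    def test_hand_computed_rho(self):
        rho, _ = spearman([1, 2, 3, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(0.8)

    def test_rank_invariance_under_monotone_transform(self):
        x = np.array([0.3, 1.2, 2.5, 3.1, 7.9])
        rho, _ = spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)

    def test_exact_p_matches_definitional_enumeration(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(7)
        y = rng.standard_normal(7)
        rho_obs, p_exact = spearman(x, y)
        # oracle: enumerate every pairing of the rank vectors
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        rx = (rx - rx.mean()) / rx.std()
        ry = (ry - ry.mean()) / ry.std()
        rhos = np.array([np.mean(rx * ry[list(perm)])
                         for perm in itertools.permutations(range(7))])
        p_ref = np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12)
        assert p_exact == pytest.approx(p_ref, rel=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestJensenShannon:
    def test_identical_profiles_zero(self):
        d = jensen_shannon(frame([[0.5, 0.5], [0.5, 0.5]]))
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(0)
        x = rng.dirichlet(np.ones(5), 6)
        d = jensen_shannon(frame(x))
        assert np.allclose(d.values, d.values.T)
        assert (d.values <= np.sqrt(np.log(2)) + 1e-9).all()
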