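"""Co-abundance network: correlation, adjacency, modules, eigengenes, kME."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from guildnet.network import (NetworkConfig, CoAbundanceNetwork, adjacency,
                              complete_membership, correlation_matrix,
                              detect_modules, merge_modules, module_eigengene,
                              refine_membership, signed_kme,
                              soft_threshold_scan, _scale_free_r2)


def _factor_table(n=60, k=4, per=15, loading=0.9, noise=0.3, seed=0,
                  extra_noise_features=0):
    rng = np.random.default_rng(seed)
    f = rng.standard_normal((n, k))
    cols, data, truth = [], [], []
    for m in range(k):
        for j in range(per):
            data.append(loading * f[:, m] + noise * rng.standard_normal(n))
            cols.append(f"f{m}_{j}")
            truth.append(m)
    for j in range(extra_noise_features):
        data.append(rng.standard_normal(n))
        cols.append(f"noise_{j}")
        truth.append(-1)
    df = pd.DataFrame(np.column_stack(data), columns=cols)
    return df, np.array(truth), f


class TestCorrelationMatrix:
    def test_hand_computed_spearman(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4], "y": [1, 3, 2, 4]})
        rho = correlation_matrix(df)
        assert rho.loc["x", "y"] == pytest.approx(0.8)

    def test_rank_invariance(self):
        x = np.array([0.1, 0.9, 2.2, 3.5, 9.0])
        df = pd.DataFrame({"x": x, "y": np.exp(x)})
        assert correlation_matrix(df).loc["x", "y"] == pytest.approx(1.0)

    def test_unit_diagonal_and_symmetry(self):
        df, _, _ = _factor_table(n=20, k=2, per=5)
        rho = correlation_matrix(df)
        assert np.allclose(np.diag(rho), 1.0)
        assert np.allclose(rho, rho.T)

    def test_constant_feature_named_in_error(self):
        df = pd.DataFrame({"ok": [1, 2, 3], "flat": [5, 5, 5]})
        with pytest.raises(ValueError, match="flat"):
            correlation_matrix(df)


class TestAdjacency:
    def test_unsigned_power(self):
        rho = pd.DataFrame([[1.0, -0.5], [-0.5, 1.0]])
        assert adjacency(rho, 2).iloc[0, 1] == pytest.approx(0.25)

    def test_perfect_correlation_stays_one(self):
        rho = pd.DataFrame([[1.0, 1.0], [1.0, 1.0]])
        assert adjacency(rho, 13).iloc[0, 1] == pytest.approx(1.0)

    def test_high_power_shrinks_moderate_edges(self):
        rho = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]])
        assert adjacency(rho, 10).iloc[0, 1] == pytest.approx(0.5**10)

    def test_signed_transform(self):
        rho = pd.DataFrame([[1.0, -1.0], [-1.0, 1.0]])
        a = adjacency(rho, 3, network_sign="signed")
        assert a.iloc[0, 1] == pytest.approx(0.0)

    def test_strictly_decreasing_in_beta(self):
        rho = pd.DataFrame([[1.0, 0.7], [0.7, 1.0]])
        vals = [adjacency(rho, b).iloc[0, 1] for b in (1, 2, 5, 12)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_invalid_beta_rejected(self):
        with pytest.raises(ValueError):
            adjacency(pd.DataFrame([[1.0]]), 0)

    def test_feature_permutation_equivariance(self):
        df, _, _ = _factor_table(n=30, k=2, per=12)
        rho = correlation_matrix(df)
        a = adjacency(rho, 6)
        perm = list(df.columns[::-1])
        a_perm = adjacency(correlation_matrix(df[perm]), 6)
        assert np.allclose(a.loc[perm, perm], a_perm)


class TestSoftThresholdScan:
    def test_one_row_per_power(self):
        df, _, _ = _factor_table(n=30, k=2, per=15)
        rho = correlation_matrix(df)
        sft = soft_threshold_scan(rho, range(1, 21))
        assert len(sft) == 20
        assert list(sft["power"]) == list(range(1, 21))

    def test_constant_correlation_gives_undefined_marker(self):
        n = 30
        rho = pd.DataFrame(np.full((n, n), 0.5) + np.eye(n) * 0.5)
        sft = soft_threshold_scan(rho, [2, 4])
        assert sft["scale_free_r2"].isna().all()

    def test_exact_power_law_degrees_fit_perfectly(self):
        # connectivities concentrated at bin centers with counts k^-gamma:
        # the log-log regression of bin frequency on mean degree is exact
        # degree groups at the centers of the ten equal-width bins with
        # counts exactly proportional to k^-1 (2520 = lcm(1..10))
        centers = np.array([10.0 * (i + 1) for i in range(10)])
        counts = (2520 / (np.arange(10) + 1)).astype(int)
        k = np.repeat(centers, counts)
        assert _scale_free_r2(k) == pytest.approx(1.0, abs=1e-6)

    def test_mean_connectivity_decreases_with_power(self):
        df, _, _ = _factor_table(n=40, k=3, per=10)
        sft = soft_threshold_scan(correlation_matrix(df), [1, 4, 10])
        mk = sft["mean_connectivity"].to_numpy()
        assert mk[0] > mk[1] > mk[2]


class TestDetectModules:
    def test_recovers_planted_modules(self):
        df, truth, _ = _factor_table(n=60, k=4, per=15, loading=0.9, noise=0.3)
        rho = correlation_matrix(df)
        labels = detect_modules(df, rho, NetworkConfig(min_module_size=8))
        assert adjusted_rand_score(truth, labels) >= 0.8

    def test_pure_noise_mostly_unassigned(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.standard_normal((60, 100)),
                          columns=[f"n{j}" for j in range(100)])
        rho = correlation_matrix(df)
        labels = detect_modules(df, rho, NetworkConfig())
        assert (labels == 0).mean() >= 0.9

    def test_duplicated_module_features_form_one_module(self):
        df, _, _ = _factor_table(n=40, k=1, per=12, loading=0.95, noise=0.1)
        dup = df.copy()
        dup.columns = [f"{c}_copy" for c in df.columns]
        both = pd.concat([df, dup], axis=1)
        rho = correlation_matrix(both)
        labels = detect_modules(both, rho, NetworkConfig())
        assigned = labels[labels != 0]
        assert assigned.nunique() == 1
        assert len(assigned) == 24

    def test_fewer_features_than_min_size_all_unassigned(self):
        df, _, _ = _factor_table(n=30, k=1, per=5)
        rho = correlation_matrix(df)
        labels = detect_modules(df, rho, NetworkConfig(min_module_size=11))
        assert (labels == 0).all()


class TestModuleEigengene:
    def test_single_feature_module_is_zscore(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.standard_normal(25)})
        me = module_eigengene(df, ["x"])
        z = (df["x"] - df["x"].mean()) / df["x"].std(ddof=0)
        scale = z.std(ddof=1)
        assert np.allclose(np.abs(me), np.abs(z / scale), atol=1e-10)
        assert np.corrcoef(me, df["x"])[0, 1] > 0

    def test_tracks_latent_factor(self):
        rng = np.random.default_rng(1)
        f = rng.standard_normal(60)
        df = pd.DataFrame({f"x{j}": f + 0.1 * rng.standard_normal(60)
                           for j in range(30)})
        me = module_eigengene(df, list(df.columns))
        assert abs(np.corrcoef(me, f)[0, 1]) >= 0.99

    def test_invariant_to_feature_duplication(self):
        df, _, _ = _factor_table(n=30, k=1, per=10)
        me1 = module_eigengene(df, list(df.columns))
        dup = pd.concat([df, df.add_suffix("_d")], axis=1)
        me2 = module_eigengene(dup, list(dup.columns))
        assert np.allclose(me1, me2, atol=1e-10)

    def test_unit_variance(self):
        df, _, _ = _factor_table(n=45, k=1, per=8)
        me = module_eigengene(df, list(df.columns))
        assert me.std(ddof=1) == pytest.approx(1.0)

    def test_explains_at_least_any_single_member(self):
        # PC1 variance share dominates each member's squared correlation-based share
        df, _, _ = _factor_table(n=50, k=1, per=12, loading=0.7, noise=0.5)
        me = module_eigengene(df, list(df.columns))
        kme = signed_kme(df, me.to_frame("m"))
        z = (df - df.mean()) / df.std(ddof=0)
        pc1_share = np.square(z.to_numpy().T @ (me / np.linalg.norm(me))).sum() / \
            np.square(z.to_numpy()).sum()
        assert pc1_share >= float((kme["m"] ** 2).max()) / len(df.columns)

    def test_empty_module_rejected(self):
        with pytest.raises(ValueError):
            module_eigengene(pd.DataFrame({"x": [1.0, 2.0]}), [])


class TestSignedKme:
    def test_feature_equal_to_eigengene(self):
        rng = np.random.default_rng(2)
        e = rng.standard_normal(40)
        df = pd.DataFrame({"same": e, "anti": -e})
        kme = signed_kme(df, pd.DataFrame({"m": e}))
        assert kme.loc["same", "m"] == pytest.approx(1.0)
        assert kme.loc["anti", "m"] == pytest.approx(-1.0)

    def test_independent_noise_has_small_membership(self):
        rng = np.random.default_rng(3)
        e = rng.standard_normal(1000)
        df = pd.DataFrame({"noise": rng.standard_normal(1000)})
        kme = signed_kme(df, pd.DataFrame({"m": e}))
        assert abs(kme.loc["noise", "m"]) < 0.1


class TestMergeRefine:
    def _two_module_table(self, cor_target, seed=0):
        # two 12-feature modules whose latent factors have a set correlation
        rng = np.random.default_rng(seed)
        n = 400
        f1 = rng.standard_normal(n)
        f2 = cor_target * f1 + np.sqrt(1 - cor_target**2) * rng.standard_normal(n)
        cols = {}
        for j in range(12):
            cols[f"a{j}"] = f1 + 0.05 * rng.standard_normal(n)
        for j in range(12):
            cols[f"b{j}"] = f2 + 0.05 * rng.standard_normal(n)
        df = pd.DataFrame(cols)
        labels = pd.Series([1] * 12 + [2] * 12, index=df.columns)
        return df, labels

    def test_similar_eigengenes_merged(self):
        df, labels = self._two_module_table(0.85)
        merged, history = merge_modules(df, labels, 0.25)
        assert merged.nunique() == 1
        assert history

    def test_distinct_eigengenes_not_merged(self):
        df, labels = self._two_module_table(0.60)
        merged, history = merge_modules(df, labels, 0.25)
        assert merged.nunique() == 2
        assert not history

    def test_fixed_point_no_close_pairs_survive(self):
        rng = np.random.default_rng(5)
        n = 300
        f = rng.standard_normal((n, 4))
        cols, labs = {}, []
        for m in range(4):
            for j in range(10):
                cols[f"m{m}_{j}"] = 0.7 * f[:, m] + 0.3 * rng.standard_normal(n)
        df = pd.DataFrame(cols)
        labels = pd.Series(np.repeat(np.arange(1, 5), 10), index=df.columns)
        merged, _ = merge_modules(df, labels, 0.25)
        from guildnet.network import _eigengene_frame
        mes = _eigengene_frame(df, merged)
        if mes.shape[1] >= 2:
            cor = np.corrcoef(mes.to_numpy(), rowvar=False)
            diss = 1 - cor[np.triu_indices(mes.shape[1], 1)]
            assert (diss > 0.25).all()

    def test_refine_threshold_is_inclusive(self):
        kme = pd.DataFrame({1: [0.29, 0.30, 0.95]},
                           index=["weak", "boundary", "strong"])
        labels = pd.Series([1, 1, 1], index=kme.index)
        refined = refine_membership(kme, labels, 0.30)
        assert refined["weak"] == 0
        assert refined["boundary"] == 1
        assert refined["strong"] == 1

    def test_completion_readmits_only_strong_members(self):
        kme = pd.DataFrame({1: [0.8, 0.2]}, index=["strong", "weak"])
        labels = pd.Series([0, 0], index=kme.index)
        joined = complete_membership(kme, labels, 0.40)
        assert joined["strong"] == 1
        assert joined["weak"] == 0


class TestFullPipeline:
    def test_deterministic_fit(self, cohort29):
        s1 = CoAbundanceNetwork(cohort29.features).fit(scan_powers=False)
        s2 = CoAbundanceNetwork(cohort29.features).fit(scan_powers=False)
        pd.testing.assert_series_equal(s1.labels, s2.labels)
        pd.testing.assert_frame_equal(s1.eigengenes, s2.eigengenes)

    def test_solution_invariants(self, solution60):
        sol = solution60
        # each feature is in exactly one module or unclassified
        assert set(sol.labels.unique()) <= set(sol.modules) | {"unclassified"}
        assert np.allclose(sol.eigengenes.std(ddof=1), 1.0)
        assert (sol.kme.abs() <= 1 + 1e-12).all().all()

    def test_summary_mentions_power_and_sizes(self, solution60):
        text = solution60.summary()
        assert "power: 10" in text
        assert "unclassified" in text
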