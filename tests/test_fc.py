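import numpy as np
import pytest

import flexatlas as fa
from flexatlas.errors import CoverageError, InsufficientDataError, PairingError
from flexatlas.fc import (
    NodeTimeSeries,
    compare_fc,
    extract_node_timeseries,
    fc_matrices,
    group_fc_stats,
    inner_node_signal,
    layer_fc,
    modulation_search,
)
from flexatlas.synth import BoldSpec, ToyAtlasSpec, make_synthetic_bold, make_toy_atlas


@pytest.fixture(scope="module")
def bold_setup():
    onto, vol, _ = make_toy_atlas(ToyAtlasSpec(n_grey_leaves=6, shape=(10, 10, 10), seed=21))
    base = fa.build_faa_base(onto, vol)
    sizes = fa.label_sizes(base.volume)
    leaves = [i for i in base.ontology.leaf_ids() if sizes.get(i, 0) > 0]
    return base, sizes, leaves


class TestExtraction:
    def test_single_voxel_node_verbatim(self, bold_setup):
        base, sizes, leaves = bold_setup
        rng = np.random.default_rng(0)
        bold = rng.random(base.volume.shape + (20,))
        ts = extract_node_timeseries(bold, base.volume, leaves)
        single = [i for i in leaves if sizes[i] == 1]
        for nid in single:
            idx = np.argwhere(base.volume.data == nid)[0]
            assert np.array_equal(ts.series[nid], bold[tuple(idx)])

    def test_two_voxel_mean(self):
        av = fa.LabeledVolume(np.zeros((2, 1, 1), dtype=np.int64).copy())
        av.data[:, 0, 0] = 7
        bold = np.zeros((2, 1, 1, 3))
        bold[0, 0, 0] = [1, 3, 5]
        bold[1, 0, 0] = [3, 1, 5]
        ts = extract_node_timeseries(bold, av, [7])
        assert np.array_equal(ts.series[7], [2, 2, 5])

    def test_grid_mismatch(self, bold_setup):
        base, _, leaves = bold_setup
        with pytest.raises(ValueError, match="grid"):
            extract_node_timeseries(np.zeros((2, 2, 2, 5)), base.volume, leaves)

    def test_voxelless_leaf_warns_and_skips(self, bold_setup):
        base, _, leaves = bold_setup
        bold = np.zeros(base.volume.shape + (5,))
        with pytest.warns(UserWarning, match="no voxels"):
            ts = extract_node_timeseries(bold, base.volume, leaves + [999])
        assert 999 not in ts.series


class TestInnerSignal:
    def test_weighted_average_arithmetic(self, branch_tree):
        # leaves sizes 2 and 1 with constant signals 1 and 4 -> (2*1+1*4)/3 = 2
        ts = NodeTimeSeries("r", {3: np.ones(5), 4: np.full(5, 4.0)})
        sig = inner_node_signal(ts, branch_tree, {3: 2, 4: 1}, 2)
        assert np.allclose(sig, 2.0)

    def test_single_leaf_inner_equals_leaf(self, branch_tree):
        ts = NodeTimeSeries("r", {6: np.arange(4.0)})
        sig = inner_node_signal(ts, branch_tree, {6: 3}, 5)
        assert np.array_equal(sig, np.arange(4.0))

    def test_missing_leaf_series(self, branch_tree):
        ts = NodeTimeSeries("r", {3: np.ones(5)})
        with pytest.raises(CoverageError):
            inner_node_signal(ts, branch_tree, {3: 2, 4: 1}, 2)

    def test_exactness_against_voxel_mean(self, bold_setup):
        # size-weighted leaf aggregation == direct voxel mean over the union
        base, sizes, leaves = bold_setup
        sim = make_synthetic_bold(base.ontology, base.volume, BoldSpec(
            blocks={i: 0 for i in leaves}, n_runs=1, n_timepoints=30,
            render_4d=True, noise_sigma=0.5, seed=3))
        bold = sim["volumes"][0]
        ts = extract_node_timeseries(bold, base.volume, leaves)
        for inner in base.ontology.inner_ids():
            union = np.zeros(base.volume.shape, dtype=bool)
            for l in base.ontology.leaves_under(inner):
                union |= base.volume.data == l
            if not union.any():
                continue
            direct = bold[union].mean(axis=0)
            derived = inner_node_signal(ts, base.ontology, sizes, inner)
            assert np.allclose(direct, derived, atol=1e-12)


class TestFCMatrices:
    def test_self_and_sign_correlations(self, bold_setup):
        base, sizes, leaves = bold_setup
        t = np.sin(np.linspace(0, 10, 50))
        ts = NodeTimeSeries("r", {leaves[0]: t, leaves[1]: -t,
                                  **{i: np.random.default_rng(i).random(50) for i in leaves[2:]}})
        ids, mats = fc_matrices([ts], leaves, base.ontology, sizes)
        r = mats[0]
        i0, i1 = ids.index(leaves[0]), ids.index(leaves[1])
        assert r[i0, i0] == pytest.approx(1.0)
        assert r[i0, i1] == pytest.approx(-1.0)
        assert np.allclose(r, r.T)

    def test_zero_variance_series_nan(self, bold_setup):
        base, sizes, leaves = bold_setup
        series = {i: np.random.default_rng(i).random(30) for i in leaves}
        series[leaves[0]] = np.ones(30)
        with pytest.warns(UserWarning, match="zero-variance"):
            ids, mats = fc_matrices([NodeTimeSeries("r", series)], leaves,
                                    base.ontology, sizes)
        i0 = ids.index(leaves[0])
        off = [k for k in range(len(ids)) if k != i0]
        assert np.isnan(mats[0][i0, off]).all()

    def test_block_covariance_recovered(self, bold_setup):
        base, sizes, leaves = bold_setup
        blocks = {nid: (0 if k < len(leaves) // 2 else 1) for k, nid in enumerate(leaves)}
        sim = make_synthetic_bold(base.ontology, base.volume, BoldSpec(
            blocks=blocks, rho_within=0.7, n_runs=13, n_timepoints=400, seed=4))
        ids, mats = fc_matrices(sim["runs"], leaves, base.ontology, sizes)
        mean_r = np.mean(mats, axis=0)
        same = [(a, b) for a in range(len(ids)) for b in range(a + 1, len(ids))
                if blocks[ids[a]] == blocks[ids[b]]]
        within = np.mean([mean_r[a, b] for a, b in same])
        assert abs(within - 0.7) < 0.05


class TestGroupStats:
    def test_null_runs_nothing_significant(self, bold_setup):
        base, sizes, leaves = bold_setup
        rng = np.random.default_rng(5)
        n = len(leaves)
        r_runs = []
        for _ in range(6):
            m = np.zeros((n, n))
            np.fill_diagonal(m, 1.0)
            r_runs.append(m)
        res = group_fc_stats(leaves, r_runs)
        assert not res.sig.any()
        off = ~np.eye(n, dtype=bool)
        assert (res.mean_r[off] == 0).all()

    def test_bh_brute_force_small_vector(self):
        # p = [.01,.02,.03,.04], m=4, alpha=.05: max k with p(k)<=k*alpha/m is 4
        from statsmodels.stats.multitest import multipletests

        rej, _, _, _ = multipletests([0.01, 0.02, 0.03, 0.04], alpha=0.05, method="fdr_bh")
        assert rej.all()

    def test_fisher_round_trip(self):
        assert np.tanh(np.arctanh(0.82)) == pytest.approx(0.82, abs=1e-15)

    def test_needs_two_runs(self, bold_setup):
        base, sizes, leaves = bold_setup
        with pytest.raises(InsufficientDataError):
            group_fc_stats(leaves, [np.eye(len(leaves))])

    def test_strong_fc_detected_and_mean_r_zeroing(self, bold_setup):
        base, sizes, leaves = bold_setup
        blocks = {nid: (0 if k < len(leaves) // 2 else 1) for k, nid in enumerate(leaves)}
        sim = make_synthetic_bold(base.ontology, base.volume, BoldSpec(
            blocks=blocks, rho_within=0.7, n_runs=13, n_timepoints=400, seed=6))
        ids, mats = fc_matrices(sim["runs"], leaves, base.ontology, sizes)
        res = group_fc_stats(ids, mats)
        same = [(a, b) for a in range(len(ids)) for b in range(a + 1, len(ids))
                if blocks[ids[a]] == blocks[ids[b]]]
        assert all(res.sig[a, b] for a, b in same)
        # every non-significant off-diagonal entry is zeroed in mean_r
        off = ~np.eye(len(ids), dtype=bool)
        assert (res.mean_r[off][~res.sig[off]] == 0).all()


class TestCompare:
    def test_identical_conditions_no_rejections(self):
        rng = np.random.default_rng(7)
        a = rng.uniform(-0.3, 0.3, size=(13, 10))
        out = compare_fc({"c1": a, "c2": a.copy()}, method="paired_t_fdr")
        assert not out["reject"].any()

    def test_large_shift_rejected_by_paired_t(self):
        rng = np.random.default_rng(8)
        base = rng.uniform(0.0, 0.2, size=(13, 6))
        shifted = np.tanh(np.arctanh(base) + 0.5 + 0.05 * rng.standard_normal((13, 6)))
        out = compare_fc({"lo": base, "hi": shifted}, method="paired_t_fdr")
        assert out["reject"].all()
        # analytic check on one feature: paired t on z-differences
        d = np.arctanh(shifted[:, 0]) - np.arctanh(base[:, 0])
        t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert out["stat"][0] == pytest.approx(-t_manual)

    def test_unpaired_shapes_rejected(self):
        with pytest.raises(PairingError):
            compare_fc({"a": np.zeros((5, 3)), "b": np.zeros((6, 3))},
                       method="paired_t_fdr")

    def test_tukey_flags_between_group_pairs(self):
        rng = np.random.default_rng(9)
        groups = {
            "within_supra": 0.8 + 0.02 * rng.standard_normal((13, 1)),
            "within_infra": 0.78 + 0.02 * rng.standard_normal((13, 1)),
            "between": 0.2 + 0.02 * rng.standard_normal((13, 1)),
        }
        out = compare_fc(groups, method="oneway_anova_tukey")
        assert out["p"][0] < 1e-6
        pw = out["pairwise_p"][0]
        assert pw[("within_supra", "between")] < 0.01
        assert pw[("within_infra", "between")] < 0.01
        assert pw[("within_supra", "within_infra")] > 0.05

    def test_rm_anova_agrees_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(10)
        data = {"a": 0.3 + 0.1 * rng.standard_normal((8, 1)),
                "b": 0.4 + 0.1 * rng.standard_normal((8, 1)),
                "c": 0.6 + 0.1 * rng.standard_normal((8, 1))}
        out = compare_fc(data, method="rm_anova_holm")
        z = {k: np.arctanh(v[:, 0]) for k, v in data.items()}
        long = pd.DataFrame({
            "y": np.concatenate(list(z.values())),
            "cond": np.repeat(list(z.keys()), 8),
            "subj": np.tile(np.arange(8), 3),
        })
        ref = pg.rm_anova(data=long, dv="y", within="cond", subject="subj")
        assert out["stat"][0] == pytest.approx(float(ref["F"][0]), rel=1e-6)
        assert out["p"][0] == pytest.approx(float(ref["p_unc"][0]), rel=1e-6)


class TestModulationSearch:
    @staticmethod
    def _fc_from_matrix(ids, mean_r):
        n = len(ids)
        return fa.FCResult(
            node_ids=list(ids), r_runs=[mean_r], mean_z=np.arctanh(np.clip(mean_r, -0.999, 0.999)),
            t=np.zeros((n, n)), p=np.zeros((n, n)), q=np.zeros((n, n)),
            sig=np.ones((n, n), dtype=bool), mean_r=mean_r, n_runs=1,
            index={nid: k for k, nid in enumerate(ids)},
        )

    def test_matches_exhaustive_oracle_on_random_matrices(self, bold_setup):
        base, sizes, leaves = bold_setup
        onto = base.ontology
        ids = sorted(set(leaves) | set(onto.inner_ids()))
        for seed in range(10):
            rng = np.random.default_rng(seed)
            m = rng.uniform(-0.5, 0.99, size=(len(ids), len(ids)))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 1.0)
            fcres = self._fc_from_matrix(ids, m)
            got = modulation_search(fcres, onto)["pairs"]
            # exhaustive triple loop, straight from the three criteria
            expected = []
            for s in ids:
                if not onto.nodes[s].is_leaf:
                    continue
                for a in ids:
                    if onto.nodes[a].is_leaf:
                        continue
                    if fcres.fc(s, a) <= 0.8:
                        continue
                    if a in onto.ancestors(s):
                        continue
                    descs = [b for b in onto.leaves_under(a) if b in fcres.index and b != s]
                    if descs and all(fcres.fc(s, a) > fcres.fc(s, b) for b in descs):
                        expected.append((s, a))
            assert got == sorted(expected)

    def test_ancestor_excluded_regardless_of_fc(self, bold_setup):
        base, sizes, leaves = bold_setup
        onto = base.ontology
        s = leaves[0]
        anc = onto.ancestors(s)[0]
        ids = sorted(set(leaves) | {anc})
        m = np.full((len(ids), len(ids)), 0.1)
        np.fill_diagonal(m, 1.0)
        k_s, k_a = ids.index(s), ids.index(anc)
        m[k_s, k_a] = m[k_a, k_s] = 0.95
        res = modulation_search(self._fc_from_matrix(ids, m), onto)
        assert (s, anc) not in res["pairs"]
        assert res["funnel"]["pass_fc_criterion"] >= 1
        assert res["funnel"]["pass_non_ancestor"] == 0

    def test_funnel_counts_monotone(self, bold_setup):
        base, sizes, leaves = bold_setup
        onto = base.ontology
        ids = sorted(set(leaves) | set(onto.inner_ids()))
        rng = np.random.default_rng(33)
        m = rng.uniform(0.5, 0.99, size=(len(ids), len(ids)))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        f = modulation_search(self._fc_from_matrix(ids, m), onto)["funnel"]
        assert (f["leaves_tested"] >= f["pass_fc_criterion"]
                >= f["pass_non_ancestor"] >= f["pass_exceeds_descendants"])


class TestLayerFC:
    def _layer_fixture(self):
        rho = np.array([
            [1.0, 0.8, 0.3, 0.3],   # L1
            [0.8, 1.0, 0.3, 0.3],   # L2/3
            [0.3, 0.3, 1.0, 0.85],  # L5
            [0.3, 0.3, 0.85, 1.0],  # L6a
        ])
        L = np.linalg.cholesky(rho)
        rng = np.random.default_rng(12)
        runs = []
        ids = [101, 102, 103, 104]
        for k in range(13):
            sig = L @ rng.standard_normal((4, 300))
            r = np.corrcoef(sig)
            runs.append(r)
        return ids, runs

    def test_supra_infra_block_structure_detected(self):
        ids, runs = self._layer_fixture()
        res = group_fc_stats(ids, runs)
        layers = {"L1": [101], "L2/3": [102], "L5": [103], "L6a": [104]}
        out = layer_fc(res, layers, method="oneway_anova_tukey")
        block = out["block"]
        assert block.loc["L1", "L2/3"] > block.loc["L2/3", "L6a"]
        assert block.loc["L5", "L6a"] > block.loc["L2/3", "L6a"]
        pw = out["comparison"]["pairwise_p"][0]

        def lookup(a, b):
            return pw[(a, b)] if (a, b) in pw else pw[(b, a)]

        assert lookup("L1|L2/3", "L2/3|L6a") < 0.05
        assert lookup("L5|L6a", "L2/3|L6a") < 0.05

    def test_two_layers_single_value_no_anova(self):
        ids, runs = self._layer_fixture()
        res = group_fc_stats(ids, runs)
        out = layer_fc(res, {"L1": [101], "L2/3": [102]})
        assert out["comparison"] is None
        assert out["block"].shape == (2, 2)

    def test_block_equals_direct_indexing_single_leaves(self):
        ids, runs = self._layer_fixture()
        res = group_fc_stats(ids, runs)
        out = layer_fc(res, {"L1": [101], "L2/3": [102], "L5": [103]})
        z = np.mean([np.arctanh(np.clip(r[0, 1], -1 + 1e-12, 1 - 1e-12)) for r in runs])
        assert out["block"].loc["L1", "L2/3"] == pytest.approx(np.tanh(z))
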