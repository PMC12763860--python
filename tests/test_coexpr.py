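"""Network construction against naive-loop oracles; module recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from homoeoexpress.coexpr import (NetworkParams, adjacency, cluster_modules,
                                  core_genes, filter_expressed, gene_scores,
                                  module_eigengenes, module_trait_cor,
                                  pick_soft_power, run_coexpr, tom_similarity)


def random_adjacency(rng, n):
    a = rng.uniform(0, 1, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


def tom_triple_loop(a):
    n = a.shape[0]
    k = a.sum(axis=0) - 1.0
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


def frame(values, prefix="g"):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(values,
                        index=[f"{prefix}{i}" for i in range(values.shape[0])],
                        columns=[f"s{j}" for j in range(values.shape[1])])


class TestFilter:
    def test_gene_with_a_zero_sample_dropped(self):
        x = frame([[1, 2, 3], [1, 0, 3], [4, 5, 6]])
        kept = filter_expressed(x)
        assert list(kept.index) == ["g0", "g2"]

    def test_all_positive_unchanged(self):
        x = frame(np.arange(1, 13).reshape(3, 4))
        pd.testing.assert_frame_equal(filter_expressed(x), x)

    def test_kept_count_matches_row_scan(self, rng):
        x = frame(rng.uniform(0, 1, size=(100, 6)) *
                  (rng.random(size=(100, 6)) > 0.1))
        kept = filter_expressed(x)
        expected = sum(1 for i in range(100) if (x.iloc[i] > 0).all())
        assert len(kept) == expected

    def test_empty_result_raises(self):
        with pytest.raises(ValueError):
            filter_expressed(frame([[0, 1], [1, 0]]))


class TestAdjacency:
    def test_identical_genes_full_weight(self):
        x = frame([[1, 2, 3, 4], [2, 4, 6, 8]])
        a = adjacency(x, NetworkParams(soft_power=7))
        assert a[0, 1] == pytest.approx(1.0)

    def test_orthogonal_profiles_zero(self):
        x = frame([[1, -1, 1, -1], [1, 1, -1, -1]])
        a = adjacency(x, NetworkParams(soft_power=6))
        assert a[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_naive_double_loop(self, rng):
        x = frame(rng.normal(size=(5, 8)))
        for net, beta in (("unsigned", 6), ("signed", 3)):
            a = adjacency(x, NetworkParams(soft_power=beta, network_type=net))
            for i in range(5):
                for j in range(5):
                    r = stats.pearsonr(x.iloc[i], x.iloc[j]).statistic
                    want = abs(r) ** beta if net == "unsigned" \
                        else ((1 + r) / 2) ** beta
                    assert a[i, j] == pytest.approx(want if i != j else 1.0)

    def test_constant_row_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            adjacency(frame([[1, 1, 1, 1], [1, 2, 3, 4]]), NetworkParams())


class TestTOM:
    def test_identity_adjacency(self):
        assert np.allclose(tom_similarity(np.eye(5)), np.eye(5))

    def test_complete_graph(self):
        a = np.ones((4, 4))
        assert np.allclose(tom_similarity(a), np.ones((4, 4)))

    def test_matches_triple_loop(self, rng):
        for _ in range(10):
            a = random_adjacency(rng, 12)
            assert np.allclose(tom_similarity(a), tom_triple_loop(a),
                               atol=1e-10)

    def test_bounds_and_symmetry(self, rng):
        a = random_adjacency(rng, 30)
        tom = tom_similarity(a)
        assert np.allclose(tom, tom.T)
        assert (tom >= 0).all() and (tom <= 1).all()
        assert np.allclose(np.diag(tom), 1.0)

    def test_asymmetric_rejected(self, rng):
        a = rng.uniform(0, 1, size=(4, 4))
        with pytest.raises(ValueError, match="symmetric"):
            tom_similarity(a)


class TestSoftPower:
    def test_single_candidate_returned(self, rng):
        x = frame(rng.normal(size=(30, 6)))
        assert pick_soft_power(x, candidate_powers=(6,), r2_target=0.0) == 6

    def test_zero_target_returns_smallest(self, rng):
        x = frame(rng.normal(size=(30, 6)))
        assert pick_soft_power(x, candidate_powers=(2, 4, 8), r2_target=0.0) == 2

    def test_agrees_with_independent_reimplementation(self, rng):
        # planted 3-block matrix; oracle recomputes the criterion from scratch
        blocks = []
        for _ in range(3):
            f = rng.normal(size=10)
            blocks.append(f + 0.5 * rng.normal(size=(15, 10)))
        x = frame(np.vstack(blocks + [rng.normal(size=(15, 10))]))
        candidates = tuple(range(1, 13))
        target = 0.8
        chosen = pick_soft_power(x, candidates, r2_target=target)

        def oracle():
            best, best_r2 = None, -np.inf
            for b in candidates:
                corr = np.corrcoef(x.to_numpy())
                a = np.abs(corr) ** b
                np.fill_diagonal(a, 1.0)
                k = a.sum(0) - 1
                k = k[k > 0]
                logk = np.log10(k)
                edges = np.linspace(logk.min(), logk.max() + 1e-12, 11)
                idx = np.digitize(logk, edges) - 1
                xs = [np.log10(np.mean(k[idx == u])) for u in range(10)
                      if (idx == u).sum()]
                ys = [np.log10((idx == u).sum()) for u in range(10)
                      if (idx == u).sum()]
                fit = stats.linregress(xs, ys)
                r2 = fit.rvalue ** 2
                if r2 >= target:
                    return b
                if r2 > best_r2:
                    best, best_r2 = b, r2
            return best

        assert chosen == oracle()


class TestModules:
    def test_planted_blocks_recovered(self, rng):
        from sklearn.metrics import adjusted_rand_score
        f1, f2 = rng.normal(size=10), rng.normal(size=10)
        x = frame(np.vstack([f1 + 0.3 * rng.normal(size=(25, 10)),
                             f2 + 0.3 * rng.normal(size=(25, 10))]))
        params = NetworkParams(min_module_size=10)
        tom = tom_similarity(adjacency(x, params))
        labels = cluster_modules(tom, params, genes=x.index)
        planted = [0] * 25 + [1] * 25
        assert adjusted_rand_score(planted, labels) == 1.0

    def test_min_module_size_larger_than_n(self, rng):
        a = random_adjacency(rng, 5)
        params = NetworkParams(min_module_size=10)
        with pytest.warns(UserWarning):
            labels = cluster_modules(tom_similarity(a), params)
        assert (labels == 0).all()

    def test_gene_order_invariance(self, rng):
        f1, f2 = rng.normal(size=8), rng.normal(size=8)
        x = frame(np.vstack([f1 + 0.3 * rng.normal(size=(20, 8)),
                             f2 + 0.3 * rng.normal(size=(20, 8))]))
        params = NetworkParams(min_module_size=5)
        base = cluster_modules(tom_similarity(adjacency(x, params)), params,
                               genes=x.index)
        perm = rng.permutation(len(x))
        xp = x.iloc[perm]
        permuted = cluster_modules(tom_similarity(adjacency(xp, params)),
                                   params, genes=xp.index)
        # identical partition up to module renumbering
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(base.loc[x.index], permuted.loc[x.index]) == 1.0


class TestEigengenes:
    def test_single_gene_module(self, rng):
        x = frame(rng.normal(size=(1, 6)))
        labels = pd.Series([1], index=x.index)
        eig = module_eigengenes(x, labels)
        z = (x.iloc[0] - x.iloc[0].mean()) / x.iloc[0].std(ddof=1)
        assert np.allclose(eig.loc["M1"], z) or np.allclose(eig.loc["M1"], -z)
        assert np.corrcoef(eig.loc["M1"], z)[0, 1] > 0  # sign convention

    def test_two_identical_genes(self, rng):
        row = rng.normal(size=6)
        x = frame(np.vstack([row, row * 2 + 1]))
        labels = pd.Series([1, 1], index=x.index)
        eig = module_eigengenes(x, labels)
        z = (row - row.mean()) / row.std(ddof=1)
        assert np.allclose(eig.loc["M1"].to_numpy(), z)

    def test_unit_variance_and_pc_optimality(self, rng):
        x = frame(rng.normal(size=(10, 8)))
        labels = pd.Series(1, index=x.index)
        eig = module_eigengenes(x, labels).loc["M1"].to_numpy()
        assert eig.std(ddof=1) == pytest.approx(1.0)
        z = ((x.T - x.mean(axis=1)) / x.std(axis=1, ddof=1)).T.to_numpy()
        var_pc = np.sum((z @ (eig / np.linalg.norm(eig))) ** 2)
        for g in range(10):
            u = z[g] / np.linalg.norm(z[g])
            assert var_pc >= np.sum((z @ u) ** 2) - 1e-9


class TestTraitAndScores:
    def test_proportional_eigengene_selected(self):
        trait = pd.Series([0, 0, 0, 1, 1, 1.0],
                          index=[f"s{j}" for j in range(6)])
        eig = pd.DataFrame([2 * trait - 1], index=["M1"])
        table = module_trait_cor(eig, trait)
        assert table.loc["M1", "r"] == pytest.approx(1.0)
        assert bool(table.loc["M1", "selected"])

    def test_p_value_matches_t_distribution(self, rng):
        trait = pd.Series(rng.normal(size=6), index=[f"s{j}" for j in range(6)])
        eig = pd.DataFrame(rng.normal(size=(1, 6)), index=["M1"],
                           columns=trait.index)
        table = module_trait_cor(eig, trait)
        r = table.loc["M1", "r"]
        t = r * np.sqrt((6 - 2) / (1 - r * r))
        p = 2 * stats.t.sf(abs(t), df=4)
        assert table.loc["M1", "p"] == pytest.approx(p, rel=1e-9)

    def test_orthogonal_trait_not_selected(self):
        trait = pd.Series([1, -1, 1, -1, 1, -1.0],
                          index=[f"s{j}" for j in range(6)])
        eig = pd.DataFrame([[1, 1, -1, -1, 1, -1.0]], index=["M1"],
                           columns=trait.index)
        table = module_trait_cor(eig, trait)
        assert abs(table.loc["M1", "r"]) < 0.5
        assert not bool(table.loc["M1", "selected"])

    def test_constant_trait_rejected(self):
        trait = pd.Series(1.0, index=[f"s{j}" for j in range(6)])
        eig = pd.DataFrame(np.arange(6.0)[None, :], index=["M1"],
                           columns=trait.index)
        with pytest.raises(ValueError, match="constant"):
            module_trait_cor(eig, trait)

    def test_gs_mm_match_naive_loops(self, rng):
        x = frame(rng.normal(size=(20, 8)))
        trait = pd.Series(rng.normal(size=8), index=x.columns)
        labels = pd.Series([1] * 10 + [2] * 10, index=x.index)
        eig = module_eigengenes(x, labels)
        gs, mm = gene_scores(x, trait, eig, labels)
        for i, g in enumerate(x.index):
            assert gs[g] == pytest.approx(
                abs(stats.pearsonr(x.loc[g], trait).statistic))
            own = eig.loc[f"M{labels[g]}"]
            assert mm[g] == pytest.approx(
                stats.pearsonr(x.loc[g], own).statistic)

    def test_gene_identical_to_trait(self):
        trait = pd.Series([0.0, 1, 2, 3, 4, 5], index=[f"s{j}" for j in range(6)])
        x = pd.DataFrame([trait.to_numpy()], index=["g0"], columns=trait.index)
        labels = pd.Series([1], index=x.index)
        eig = module_eigengenes(x, labels)
        gs, mm = gene_scores(x, trait, eig, labels)
        assert gs["g0"] == pytest.approx(1.0)
        assert mm["g0"] == pytest.approx(1.0)


class TestCoreGenes:
    def make_scores(self, rng, n=50):
        genes = [f"g{i}" for i in range(n)]
        gs = pd.Series(rng.uniform(0, 1, n), index=genes)
        mm = pd.Series(rng.uniform(-1, 1, n), index=genes)
        labels = pd.Series(rng.integers(1, 3, n), index=genes)
        table = pd.DataFrame({"r": [0.9, -0.9], "p": [0.01, 0.01],
                              "selected": [True, True]}, index=["M1", "M2"])
        return gs, mm, labels, table

    def test_zero_thresholds_keep_all_defined(self, rng):
        gs, mm, labels, table = self.make_scores(rng)
        core = core_genes(gs, mm, labels, table, gs_min=0.0, mm_min=-1.1)
        assert len(core["up"]) + len(core["down"]) == len(gs)

    def test_exact_threshold_excluded(self):
        gs = pd.Series([0.40], index=["g0"])
        mm = pd.Series([0.9], index=["g0"])
        labels = pd.Series([1], index=["g0"])
        table = pd.DataFrame({"r": [0.9], "p": [0.01], "selected": [True]},
                             index=["M1"])
        core = core_genes(gs, mm, labels, table)
        assert core["up"] == []

    def test_monotone_in_thresholds(self, rng):
        gs, mm, labels, table = self.make_scores(rng)
        sizes = []
        for g_min in (0.0, 0.2, 0.4, 0.6):
            core = core_genes(gs, mm, labels, table, gs_min=g_min, mm_min=0.5)
            sizes.append(len(core["up"]) + len(core["down"]))
        assert sizes == sorted(sizes, reverse=True)
        sizes = []
        for m_min in (-1.0, 0.0, 0.5, 0.9):
            core = core_genes(gs, mm, labels, table, gs_min=0.3, mm_min=m_min)
            sizes.append(len(core["up"]) + len(core["down"]))
        assert sizes == sorted(sizes, reverse=True)

    def test_direction_split_by_module_sign(self, rng):
        gs = pd.Series([0.9, 0.9], index=["g0", "g1"])
        mm = pd.Series([0.9, 0.9], index=["g0", "g1"])
        labels = pd.Series([1, 2], index=["g0", "g1"])
        table = pd.DataFrame({"r": [0.8, -0.8], "p": [0.01, 0.01],
                              "selected": [True, True]}, index=["M1", "M2"])
        core = core_genes(gs, mm, labels, table)
        assert core == {"up": ["g0"], "down": ["g1"]}


class TestEndToEnd:
    def test_driven_module_recovery(self, module_data):
        expr, groups, trait, truth = module_data
        result = run_coexpr(expr, trait)
        planted = set(truth.genes.loc[truth.genes["module"] == 1, "gene_id"])
        recovered = set(result.core["up"]) & planted
        assert len(recovered) / len(planted) >= 0.8
        assert result.selected.any()

    def test_pipeline_deterministic(self, module_data):
        expr, groups, trait, truth = module_data
        r1, r2 = run_coexpr(expr, trait), run_coexpr(expr, trait)
        pd.testing.assert_series_equal(r1.labels, r2.labels)
        pd.testing.assert_frame_equal(r1.eigengenes, r2.eigengenes)
        assert r1.core == r2.core
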