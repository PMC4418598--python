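"""Adjacency, TOM, soft-threshold scan, module detection, eigengenes."""

import numpy as np
import pandas as pd
import pytest

from corewire import prep, synth
from corewire.network import (
    CoexpressionNetwork,
    adjacency,
    detect_modules,
    eigengene,
    hubgenes,
    merge_modules,
    module_membership,
    pick_soft_threshold,
    tom,
)
from tests.conftest import make_expression


def brute_force_tom(a):
    """Triple-loop oracle for the topological overlap matrix."""
    n = a.shape[0]
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            ki = sum(a[i, u] for u in range(n) if u != i)
            kj = sum(a[j, u] for u in range(n) if u != j)
            out[i, j] = (l + a[i, j]) / (min(ki, kj) + 1 - a[i, j])
    return out


def random_adjacency(rng, n=20):
    c = rng.uniform(0, 1, size=(n, n))
    a = (c + c.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


class TestAdjacency:
    def test_matches_powered_correlation(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(10, 15))
        a = adjacency(vals, beta=6)
        c = np.corrcoef(vals)
        expected = np.abs(c) ** 6
        np.fill_diagonal(expected, 1.0)
        assert np.allclose(a, expected)

    def test_perfect_pair_and_negative_correlation(self):
        x = np.linspace(0, 1, 12)
        vals = np.vstack([x, 2 * x + 1, -x])
        a = adjacency(vals, beta=6)
        assert a[0, 1] == pytest.approx(1.0)
        assert a[0, 2] == pytest.approx(1.0)  # |cor| = 1 regardless of sign
        # |-0.5|^6 spot value via a constructed correlation
        assert abs(-0.5) ** 6 == pytest.approx(0.015625)

    def test_invalid_inputs(self):
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError, match="beta"):
            adjacency(rng.normal(size=(4, 10)), beta=0)
        with pytest.raises(ValueError, match="samples"):
            adjacency(rng.normal(size=(4, 3)), beta=6)
        with pytest.raises(ValueError, match="constant"):
            adjacency(np.vstack([np.ones(10), rng.normal(size=10)]), beta=6)


class TestTOM:
    def test_hand_example_full_adjacency(self):
        a = np.ones((3, 3))
        t = tom(a)
        assert t[0, 1] == pytest.approx(1.0)  # (1+1)/(2+1-1)

    def test_zero_adjacency(self):
        t = tom(np.eye(4))
        off = t[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 0.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            a = random_adjacency(rng)
            assert np.max(np.abs(tom(a) - brute_force_tom(a))) < 1e-10

    def test_asymmetric_rejected(self):
        a = np.eye(3)
        a[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            tom(a)


class TestSoftThreshold:
    def test_noise_has_no_scale_free_structure_at_small_powers(self):
        expr = make_expression(300, 30, seed=3)
        scan = pick_soft_threshold(expr.to_numpy(), powers=range(1, 7))
        assert (scan.table.query("power <= 3")["fit_index"] < 0.8).all()
        assert len(scan.table) == 6  # the scan itself is always returned

    def test_modular_data_recommends_moderate_power(self):
        recs = []
        for seed in range(3):
            cfg = synth.SynthConfig(seed=seed)
            study, _, _ = synth.generate_study(cfg)
            study = prep.filter_low_expression(study).with_size_factors()
            expr = prep.adjust_covariates(prep.vst(study), study.metadata)
            vals = expr.values.loc[:, study.mask_time("T0")].to_numpy()
            scan = pick_soft_threshold(vals, fit_target=0.7)
            recs.append(scan.recommended)
        assert all(r is not None and r <= 10 for r in recs)

    def test_mean_connectivity_strictly_decreasing(self):
        expr = make_expression(100, 20, seed=4)
        scan = pick_soft_threshold(expr.to_numpy(), powers=range(1, 10))
        assert scan.table["mean_k"].is_monotonic_decreasing

    def test_power_range_enforced(self):
        with pytest.raises(ValueError):
            pick_soft_threshold(make_expression(10, 10).to_numpy(), powers=[0, 1])


class TestDetectModules:
    def test_two_perfect_blocks(self):
        rng = np.random.default_rng(5)
        f1, f2 = rng.normal(size=20), rng.normal(size=20)
        vals = np.vstack(
            [np.outer(rng.uniform(0.5, 2, 50), f1), np.outer(rng.uniform(0.5, 2, 50), f2)]
        )
        a = adjacency(vals, beta=6)
        labels = detect_modules(tom(a), min_size=20)
        assert len(set(labels)) == 2
        assert 0 not in labels  # nothing unassigned
        assert len(set(labels[:50])) == 1 and len(set(labels[50:])) == 1

    def test_noise_is_mostly_grey(self):
        expr = make_expression(500, 22, seed=6)
        net = CoexpressionNetwork(expr).fit(beta=6, min_size=20)
        assert (net.labels == 0).mean() > 0.5

    def test_labels_sorted_by_size(self, t0_expression):
        expr, _ = t0_expression
        net = CoexpressionNetwork(expr).fit()
        sizes = net.module_sizes()
        assert sizes.sort_index().is_monotonic_decreasing

    def test_gene_order_invariance(self, t0_expression):
        expr, _ = t0_expression
        net1 = CoexpressionNetwork(expr).fit()
        shuffled = expr.sample(frac=1.0, random_state=8)
        net2 = CoexpressionNetwork(shuffled).fit()
        merged = pd.concat(
            [net1.labels.rename("a"), net2.labels.rename("b")], axis=1
        )
        assert (merged["a"] == merged["b"]).all()

    def test_min_size_validation(self):
        with pytest.raises(ValueError):
            detect_modules(np.eye(10), min_size=1)


class TestEigengene:
    def test_identical_gene_module(self):
        rng = np.random.default_rng(9)
        profile = rng.normal(size=18)
        vals = np.tile(profile, (5, 1))
        e = eigengene(vals, np.arange(5))
        z = (profile - profile.mean()) / profile.std()
        assert np.allclose(e, z / np.linalg.norm(z), atol=1e-10)
        mm = module_membership(vals, pd.DataFrame([e], index=[1]), list("abcde"))
        assert np.allclose(mm[1], 1.0)

    def test_pc1_explains_most_variance(self):
        rng = np.random.default_rng(10)
        vals = rng.normal(size=(8, 25))
        e = eigengene(vals, np.arange(8))
        z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, keepdims=True)
        var_e = ((z @ e) ** 2).sum()
        for g in range(8):
            member = z[g] / np.linalg.norm(z[g])
            assert var_e >= ((z @ member) ** 2).sum() - 1e-9

    def test_sign_orientation_under_global_flip(self):
        rng = np.random.default_rng(11)
        vals = np.outer(np.ones(6), rng.normal(size=20)) + 0.1 * rng.normal(size=(6, 20))
        e1 = eigengene(vals, np.arange(6))
        e2 = eigengene(-vals, np.arange(6))
        # orientation rule keeps mean member correlation positive either way
        from corewire.network import _row_cor_with

        assert np.nanmean(_row_cor_with(vals, e1)) > 0
        assert np.nanmean(_row_cor_with(-vals, e2)) > 0

    def test_singleton_module(self):
        rng = np.random.default_rng(12)
        vals = rng.normal(size=(3, 10))
        e = eigengene(vals, np.array([1]))
        z = (vals[1] - vals[1].mean()) / vals[1].std()
        assert np.allclose(np.abs(e), np.abs(z / np.linalg.norm(z)))


class TestMerge:
    def _split_module_data(self):
        rng = np.random.default_rng(13)
        f = rng.normal(size=22)
        vals = np.outer(np.ones(40), f) + 0.3 * rng.normal(size=(40, 22))
        labels = np.array([1] * 20 + [2] * 20)
        return vals, labels

    def test_highly_correlated_eigengenes_merged(self):
        vals, labels = self._split_module_data()
        merged = merge_modules(vals, labels, cut_height=0.25)
        assert len(set(merged)) == 1

    def test_distinct_modules_unchanged(self):
        rng = np.random.default_rng(14)
        f1, f2 = rng.normal(size=22), rng.normal(size=22)
        vals = np.vstack(
            [
                np.outer(np.ones(20), f1) + 0.2 * rng.normal(size=(20, 22)),
                np.outer(np.ones(20), f2) + 0.2 * rng.normal(size=(20, 22)),
            ]
        )
        labels = np.array([1] * 20 + [2] * 20)
        merged = merge_modules(vals, labels, cut_height=0.25)
        assert len(set(merged)) == 2

    def test_idempotent(self):
        vals, labels = self._split_module_data()
        once = merge_modules(vals, labels)
        twice = merge_modules(vals, once)
        assert np.array_equal(once, twice)


class TestMembershipAndHubs:
    def test_mm_bounded_and_orthogonal_near_zero(self):
        rng = np.random.default_rng(15)
        f = rng.normal(size=200)
        members = np.outer(np.ones(10), f) + 0.3 * rng.normal(size=(10, 200))
        stranger = rng.normal(size=(1, 200))
        vals = np.vstack([members, stranger])
        e = eigengene(vals, np.arange(10))
        mm = module_membership(vals, pd.DataFrame([e], index=[1]), range(11))
        assert mm.to_numpy().min() >= -1 and mm.to_numpy().max() <= 1
        assert abs(mm.loc[10, 1]) < 2 / np.sqrt(200) + 0.1

    def test_hubgene_ordering_by_absolute_mm(self):
        mm = pd.DataFrame({1: [0.99, -0.98, 0.5]}, index=["a", "b", "c"])
        labels = pd.Series([1, 1, 1], index=["a", "b", "c"])
        assert hubgenes(mm, labels, 1, top_n=2) == ["a", "b"]

    def test_small_module_returned_whole(self):
        mm = pd.DataFrame({1: [0.9, 0.8]}, index=["a", "b"])
        labels = pd.Series([1, 1], index=["a", "b"])
        assert hubgenes(mm, labels, 1, top_n=30) == ["a", "b"]

    def test_planted_hub_ranks_first(self):
        # ranking correlations needs enough samples: at n=22 the order
        # statistics of ~40 MM estimates swamp a 0.95-vs-0.6 loading gap
        wins = 0
        for seed in range(10):
            cfg = synth.SynthConfig(
                seed=seed + 200, n_subjects=100, n_genes=200, module_sizes=(40,),
                frac_de=0.0,
            )
            loadings = np.full(200, 0.6)
            loadings[0] = 0.95  # the hub
            study, _, truth = synth.generate_study(cfg, gene_loadings=loadings)
            study = prep.filter_low_expression(study).with_size_factors()
            expr = prep.adjust_covariates(prep.vst(study), study.metadata)
            E = expr.values.loc[:, study.mask_time("T0")]
            members = truth.module_of_gene[truth.module_of_gene == 1].index
            members = [g for g in members if g in E.index]
            vals = E.to_numpy()
            idx = E.index.get_indexer(members)
            e = eigengene(vals, idx)
            mm = module_membership(vals, pd.DataFrame([e], index=[1]), E.index)
            labels = pd.Series(0, index=E.index)
            labels.loc[members] = 1
            if hubgenes(mm, labels, 1, top_n=1)[0] == "G0001":
                wins += 1
        assert wins >= 9

    def test_hub_correlation_matrix_shape(self, t0_expression):
        expr, _ = t0_expression
        net = CoexpressionNetwork(expr).fit()
        if net.n_modules:
            sub = net.hub_correlations(1, top_n=10)
            assert sub.shape[0] == sub.shape[1] <= 10
            assert np.allclose(np.diag(sub), 1.0)
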