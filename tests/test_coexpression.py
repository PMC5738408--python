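"""Adjacency arithmetic, the TOM formula against a brute-force oracle,
module detection on planted structure, and module enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hipscpipe.coexpression import (
    detect_modules,
    module_enrichment,
    soft_adjacency,
    topological_overlap,
)
from hipscpipe.enrichment import GeneSetCollection


def _tom_bruteforce(a: np.ndarray) -> np.ndarray:
    """Direct double-loop evaluation of the TOM formula."""
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    t = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            k_i, k_j = a[i].sum(), a[j].sum()
            t[i, j] = (shared + a[i, j]) / (min(k_i, k_j) + 1 - a[i, j])
    return t


def _planted_expr(rng, sizes, r, n_noise, n_samples=40):
    blocks = []
    for size in sizes:
        f = rng.normal(0, 1, n_samples)
        blocks.append(np.sqrt(r) * f[None, :]
                      + np.sqrt(1 - r) * rng.normal(0, 1, (size, n_samples)))
    blocks.append(rng.normal(0, 1, (n_noise, n_samples)))
    X = np.vstack(blocks)
    return pd.DataFrame(X, index=[f"g{i:04d}" for i in range(X.shape[0])],
                        columns=[f"s{j}" for j in range(n_samples)])


class TestAdjacency:
    def test_power_arithmetic(self, rng):
        # two genes with known correlation 0.5 via construction is brittle;
        # instead verify the transform directly on the correlation matrix
        expr = pd.DataFrame(rng.normal(size=(10, 30)))
        adj = soft_adjacency(expr, beta=9)
        cor = np.corrcoef(expr.to_numpy())
        np.testing.assert_allclose(adj.to_numpy(), np.abs(cor) ** 9, atol=1e-12)
        assert 0.5 ** 9 == pytest.approx(0.001953125)

    def test_perfect_pair_and_symmetry(self, rng):
        x = rng.normal(size=30)
        expr = pd.DataFrame([x, 2 * x + 1, rng.normal(size=30)])
        adj = soft_adjacency(expr, beta=9)
        a = adj.to_numpy()
        assert a[0, 1] == pytest.approx(1.0)
        assert (a >= 0).all() and (a <= 1).all()
        np.testing.assert_allclose(a, a.T)

    def test_zero_variance_gene_rejected(self, rng):
        expr = pd.DataFrame(rng.normal(size=(5, 20)))
        expr.iloc[2] = 1.0
        with pytest.raises(ValueError):
            soft_adjacency(expr)

    def test_larger_beta_sparsifies(self, rng):
        expr = pd.DataFrame(rng.normal(size=(20, 25)))
        a9 = soft_adjacency(expr, 9).to_numpy()
        a12 = soft_adjacency(expr, 12).to_numpy()
        off = ~np.eye(20, dtype=bool)
        assert (a12[off] <= a9[off] + 1e-15).all()


class TestTom:
    def test_hand_worked_three_gene_example(self):
        adj = pd.DataFrame([[1.0, 0.5, 0.5],
                            [0.5, 1.0, 0.0],
                            [0.5, 0.0, 1.0]])
        tom = topological_overlap(adj).to_numpy()
        # TOM_23 = (0.5*0.5 + 0) / (min(0.5, 0.5) + 1 - 0) = 1/6
        assert tom[1, 2] == pytest.approx(1.0 / 6.0, abs=1e-12)

    def test_all_ones_network_gives_all_ones(self):
        adj = pd.DataFrame(np.ones((3, 3)))
        np.testing.assert_allclose(topological_overlap(adj), 1.0)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_bruteforce_on_random_networks(self, seed):
        rng = np.random.default_rng(seed)
        c = rng.uniform(-1, 1, (20, 20))
        a = np.abs((c + c.T) / 2) ** 3
        np.fill_diagonal(a, 1.0)
        tom = topological_overlap(pd.DataFrame(a)).to_numpy()
        np.testing.assert_allclose(tom, _tom_bruteforce(a), atol=1e-12)

    def test_nonnegative_symmetric(self, rng):
        expr = pd.DataFrame(rng.normal(size=(30, 25)))
        tom = topological_overlap(soft_adjacency(expr)).to_numpy()
        assert (tom >= 0).all()
        np.testing.assert_allclose(tom, tom.T, atol=1e-12)


class TestDetectModules:
    def test_two_planted_blocks_exactly_two_modules(self, rng):
        expr = _planted_expr(rng, [50, 50], 0.81, 60)
        mods = detect_modules(topological_overlap(soft_adjacency(expr)))
        assert len(mods.modules) == 2
        lab = mods.labels
        assert lab.iloc[:50].nunique() == 1 and lab.iloc[0] != "grey"
        assert lab.iloc[50:100].nunique() == 1 and lab.iloc[50] != "grey"
        assert (lab.iloc[100:] == "grey").all()

    def test_independent_genes_all_grey(self, rng):
        expr = _planted_expr(rng, [], 0.8, 120)
        with pytest.warns(UserWarning):
            mods = detect_modules(topological_overlap(soft_adjacency(expr)))
        assert (mods.labels == "grey").all()

    def test_block_below_min_size_goes_grey(self, rng):
        expr = _planted_expr(rng, [10], 0.81, 100)
        with pytest.warns(UserWarning):
            mods = detect_modules(topological_overlap(soft_adjacency(expr)),
                                  min_module_size=20)
        assert (mods.labels == "grey").all()

    def test_gene_order_invariance(self, rng):
        expr = _planted_expr(rng, [40, 30], 0.81, 40)
        tom = topological_overlap(soft_adjacency(expr))
        mods1 = detect_modules(tom)
        perm = rng.permutation(len(tom))
        mods2 = detect_modules(tom.iloc[perm, perm])
        assert mods1.labels.sort_index().equals(mods2.labels.sort_index())

    def test_largest_module_is_turquoise(self, rng):
        expr = _planted_expr(rng, [60, 30], 0.81, 40)
        mods = detect_modules(topological_overlap(soft_adjacency(expr)))
        sizes = mods.module_sizes
        assert sizes["turquoise"] >= sizes.drop("grey").max()


class TestModuleEnrichment:
    @pytest.fixture()
    def modules(self, rng):
        expr = _planted_expr(rng, [50, 40], 0.81, 50)
        return detect_modules(topological_overlap(soft_adjacency(expr)))

    def test_set_equal_to_module_flagged_minimal_p(self, modules):
        target = modules.modules[0]
        sets = GeneSetCollection(
            sets={"hit": set(modules.genes_in(target)),
                  "rand": set(modules.labels.index[::7])},
            universe=set(modules.labels.index))
        tab = module_enrichment(modules, sets)
        row = tab[(tab["module"] == target) & (tab["set"] == "hit")].iloc[0]
        assert row["significant"]
        assert row["p_value"] == tab["p_value"].min()

    def test_grey_module_included(self, modules):
        sets = GeneSetCollection(sets={"s": set(modules.labels.index[:30])},
                                 universe=set(modules.labels.index))
        tab = module_enrichment(modules, sets)
        assert "grey" in set(tab["module"])

    def test_null_sets_flag_rate_controlled(self, modules, rng):
        flags, total = 0, 0
        genes = list(modules.labels.index)
        for _ in range(100):
            s = set(rng.choice(genes, size=25, replace=False))
            tab = module_enrichment(
                modules, GeneSetCollection(sets={"s": s}, universe=set(genes)))
            flags += int(tab["significant"].sum())
            total += len(tab)
        assert flags / total <= 0.05
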