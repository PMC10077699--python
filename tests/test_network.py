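"""Co-expression network: adjacency, TOM, modules, eigengenes, hubs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from meripkit.datasets import load_ldm_hub_candidates
from meripkit.network import (
    adjacency,
    corr_pvalue,
    detect_modules,
    gene_module_stats,
    module_eigengene,
    module_trait_correlation,
    pick_soft_threshold,
    refine_modules_by_kme,
    screen_hub_genes,
    tom_similarity,
)


def block_expression(rng, n_blocks=3, block_size=50, n_samples=20, within=0.9):
    """Planted-block matrix: shared factor per block, no background genes."""
    rows, truth = [], []
    lam = np.sqrt(within)
    noise = np.sqrt(1 - within)
    for b in range(n_blocks):
        f = rng.normal(size=n_samples)
        for _ in range(block_size):
            rows.append(lam * f + noise * rng.normal(size=n_samples))
            truth.append(b + 1)
    idx = [f"g{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=idx), pd.Series(truth, index=idx)


class TestAdjacency:
    def test_perfect_correlation_is_one_at_any_power(self, rng):
        x = rng.normal(size=10)
        expr = pd.DataFrame([x, 2 * x + 5], index=["a", "b"])
        for beta in (1, 4, 9):
            assert adjacency(expr, beta).loc["a", "b"] == pytest.approx(1.0)

    def test_monotone_nonincreasing_in_power(self, rng):
        expr = pd.DataFrame(rng.normal(size=(5, 12)),
                            index=[f"g{i}" for i in range(5)])
        a2 = adjacency(expr, 2).to_numpy()
        a5 = adjacency(expr, 5).to_numpy()
        assert (a5 <= a2 + 1e-12).all()

    def test_hand_computed_powers(self, rng):
        expr = pd.DataFrame(rng.normal(size=(5, 15)),
                            index=[f"g{i}" for i in range(5)])
        cor = np.corrcoef(expr.to_numpy())
        byhand = np.abs(cor) ** 3
        np.fill_diagonal(byhand, 1.0)
        np.testing.assert_allclose(adjacency(expr, 3).to_numpy(), byhand)

    def test_zero_variance_rejected(self):
        expr = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["a", "b"])
        with pytest.raises(ValueError):
            adjacency(expr, 2)


def tom_bruteforce(a):
    """Triple-loop oracle for the topological overlap similarity."""
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 1.0)
    k = a.sum(axis=0) - 1.0
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            out[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return out


class TestTOM:
    def test_disconnected_stays_disconnected(self):
        a = np.eye(4)
        t = tom_similarity(a)
        assert np.allclose(t, np.eye(4))

    def test_three_gene_complete_graph_closed_form(self):
        a = np.ones((3, 3))
        t = tom_similarity(a)
        # (1 + 1) / (min(2,2) + 1 - 1) = 1
        assert np.allclose(t, 1.0)

    def test_random_instances_match_bruteforce(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 15))
            x = rng.normal(size=(n, 12))
            a = np.abs(np.corrcoef(x)) ** 2
            np.fill_diagonal(a, 1.0)
            t = tom_similarity(a)
            np.testing.assert_allclose(t, tom_bruteforce(a), atol=1e-10)
            assert t.min() >= 0 and t.max() <= 1
            np.testing.assert_allclose(t, t.T)

    def test_asymmetric_rejected(self):
        a = np.eye(3)
        a[0, 1] = 0.5
        with pytest.raises(ValueError):
            tom_similarity(a)


class TestSoftThreshold:
    def test_forced_single_candidate(self, rng):
        expr, _ = block_expression(rng)
        scan = pick_soft_threshold(expr, candidates=[7])
        assert scan.chosen == 7

    def test_fit_values_bounded(self, rng):
        expr, _ = block_expression(rng)
        scan = pick_soft_threshold(expr)
        assert all(-1 <= r <= 1 for r in scan.fit_r2)
        assert all(k >= 0 for k in scan.mean_connectivity)

    def test_matches_independent_reimplementation(self, rng):
        # independent oracle: same formulas written from scratch
        expr, _ = block_expression(rng, n_blocks=2, block_size=30, within=0.8)
        x = expr.to_numpy()
        cor = np.abs(np.corrcoef(x))
        np.fill_diagonal(cor, 0.0)
        scan = pick_soft_threshold(expr, candidates=[2, 5])
        for pos, b in enumerate([2, 5]):
            k = (cor ** b).sum(axis=1)
            edges = np.linspace(k.min(), k.max(), 11)
            which = np.clip(np.digitize(k, edges[1:-1]), 0, 9)
            xs, ps = [], []
            for bin_i in range(10):
                m = which == bin_i
                if m.any():
                    xs.append(k[m].mean())
                    ps.append(m.sum() / len(k))
            slope, _, r, _, _ = stats.linregress(np.log10(xs), np.log10(ps))
            expected = -np.sign(slope) * r ** 2
            assert scan.fit_r2[pos] == pytest.approx(expected)


class TestModules:
    def test_planted_blocks_recovered(self, rng):
        expr, truth = block_expression(rng, n_blocks=3, block_size=50, within=0.9)
        tom = tom_similarity(adjacency(expr, 6))
        labels = detect_modules(tom, min_module_size=20)
        assert labels.max() == 3
        assert adjusted_rand_score(truth, labels) >= 0.95

    def test_independent_noise_mostly_grey(self, rng):
        expr = pd.DataFrame(rng.normal(size=(150, 20)),
                            index=[f"g{i}" for i in range(150)])
        tom = tom_similarity(adjacency(expr, 6))
        labels = detect_modules(tom, min_module_size=20)
        assert (labels == 0).mean() > 0.5

    def test_labels_partition_genes(self, rng):
        expr, _ = block_expression(rng)
        tom = tom_similarity(adjacency(expr, 6))
        labels = detect_modules(tom)
        assert len(labels) == len(expr)
        assert labels.value_counts().sum() == len(expr)

    def test_kme_refinement_recovers_periphery(self, rng):
        expr, truth = block_expression(rng, n_blocks=2, block_size=40, within=0.8)
        tom = tom_similarity(adjacency(expr, 6))
        labels = detect_modules(tom, min_module_size=15)
        refined = refine_modules_by_kme(expr, labels)
        assert adjusted_rand_score(truth, refined) >= \
               adjusted_rand_score(truth, labels) - 1e-9


class TestEigengene:
    def test_identical_genes_give_their_profile(self, rng):
        x = rng.normal(size=12)
        expr = pd.DataFrame([x, x, x], index=["a", "b", "c"],
                            columns=[f"s{i}" for i in range(12)])
        labels = pd.Series([1, 1, 1], index=expr.index)
        eig = module_eigengene(expr, labels)
        r = np.corrcoef(eig.loc["ME1"], x)[0, 1]
        assert abs(r) == pytest.approx(1.0)
        assert r > 0  # oriented with mean expression

    def test_stable_under_gene_duplication(self, rng):
        expr, truth = block_expression(rng, n_blocks=1, block_size=30)
        labels = pd.Series(1, index=expr.index)
        e1 = module_eigengene(expr, labels).loc["ME1"]
        dup = pd.concat([expr, expr.iloc[[0]].rename(index={"g0": "g_dup"})])
        e2 = module_eigengene(dup, pd.Series(1, index=dup.index)).loc["ME1"]
        assert abs(np.corrcoef(e1, e2)[0, 1]) > 0.99

    def test_unit_norm(self, rng):
        expr, _ = block_expression(rng, n_blocks=2, block_size=20)
        labels = pd.Series([1] * 20 + [2] * 20, index=expr.index)
        eig = module_eigengene(expr, labels)
        np.testing.assert_allclose(np.linalg.norm(eig, axis=1), 1.0)


class TestModuleTrait:
    def test_trait_equal_to_eigengene(self, rng):
        expr, _ = block_expression(rng, n_blocks=1, block_size=30)
        labels = pd.Series(1, index=expr.index)
        eig = module_eigengene(expr, labels)
        traits = pd.DataFrame({"t": eig.loc["ME1"]}, index=eig.columns)
        r, p = module_trait_correlation(eig, traits)
        assert r.loc["ME1", "t"] == pytest.approx(1.0)
        assert p.loc["ME1", "t"] < 1e-10

    def test_textbook_formula_on_five_samples(self):
        eig = pd.DataFrame([[0.1, 0.3, 0.2, 0.5, 0.4]], index=["ME1"],
                           columns=list("abcde"))
        trait = pd.DataFrame({"t": [1.0, 2.0, 1.5, 3.0, 2.0]}, index=list("abcde"))
        r, p = module_trait_correlation(eig, trait)
        rv = np.corrcoef(eig.loc["ME1"], trait["t"])[0, 1]
        tstat = rv * np.sqrt(3 / (1 - rv ** 2))
        assert r.loc["ME1", "t"] == pytest.approx(rv)
        assert p.loc["ME1", "t"] == pytest.approx(2 * stats.t.sf(abs(tstat), 3))

    def test_perfect_linear_relation(self):
        eig = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["ME1"], columns=list("abcd"))
        trait = pd.DataFrame({"t": [2.0, 4.0, 6.0, 8.0]}, index=list("abcd"))
        r, _ = module_trait_correlation(eig, trait)
        assert r.loc["ME1", "t"] == pytest.approx(1.0)

    def test_zero_variance_trait_rejected(self, rng):
        eig = pd.DataFrame([rng.normal(size=5)], index=["ME1"], columns=list("abcde"))
        trait = pd.DataFrame({"t": [1.0] * 5}, index=list("abcde"))
        with pytest.raises(ValueError):
            module_trait_correlation(eig, trait)


class TestGeneStatsAndHubs:
    def test_mm_gs_sign_conventions(self, rng):
        x = rng.normal(size=20)
        expr = pd.DataFrame([x, -x, rng.normal(size=20)],
                            index=["a", "b", "c"],
                            columns=[f"s{i}" for i in range(20)])
        labels = pd.Series([1, 1, 0], index=expr.index)
        eig = module_eigengene(expr.loc[["a"]], pd.Series([1], index=["a"]))
        trait = pd.Series(x, index=expr.columns)
        st = gene_module_stats(expr, eig, labels, trait)
        assert st.loc["a", "MM"] == pytest.approx(1.0)
        assert st.loc["b", "MM"] == pytest.approx(-1.0)
        assert st.loc["a", "GS"] == pytest.approx(1.0)
        assert st.loc["b", "GS"] == pytest.approx(1.0)  # absolute value
        assert np.isnan(st.loc["c", "MM"])

    def test_screening_thresholds(self):
        tab = pd.DataFrame(
            {"module": [1, 1, 1], "MM": [0.874557699, 0.815256029, 0.5],
             "GS": [0.858025625, 0.246877132, 0.9]},
            index=["ADIPOQ", "ACE2", "weak"],
        )
        hubs = screen_hub_genes(tab, module=1)
        assert list(hubs.index) == ["ADIPOQ", "ACE2"]
        assert "weak" not in hubs.index

    def test_reference_hub_table_screens_to_twelve(self):
        tab = load_ldm_hub_candidates()
        hubs = screen_hub_genes(tab)
        assert len(hubs) == 12
        assert hubs.index[0] == "ADIPOQ"
        assert hubs["GS"].is_monotonic_decreasing


def test_corr_pvalue_matches_pearsonr(rng):
    x, y = rng.normal(size=15), rng.normal(size=15)
    r = np.corrcoef(x, y)[0, 1]
    assert corr_pvalue(np.array([r]), 15)[0] == pytest.approx(
        stats.pearsonr(x, y).pvalue)
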