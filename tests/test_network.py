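import numpy as np
import pandas as pd
import pytest

from concordex.network import (
    GeneNetwork,
    ModulePartition,
    adjacency,
    consensus_tom,
    cut_modules,
    detect_modules,
    eigengenes,
    kme,
    merge_close_modules,
    pick_soft_power,
    scale_free_fit,
    tom,
)


def _expr_from_cor(cor, n_samples, rng):
    """Gene expression with (approximately) the requested correlation."""
    L = np.linalg.cholesky(cor + 1e-9 * np.eye(len(cor)))
    x = L @ rng.normal(size=(len(cor), n_samples))
    return pd.DataFrame(x, index=[f"g{i}" for i in range(len(cor))])


def tom_oracle(a):
    """Literal double-loop TOM, independent of the vectorized implementation."""
    n = len(a)
    out = np.eye(n)
    k = [sum(a[i][u] for u in range(n) if u != i) for i in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(
                a[i][u] * a[u][j] for u in range(n) if u != i and u != j
            )
            out[i][j] = (shared + a[i][j]) / (min(k[i], k[j]) + 1 - a[i][j])
    return out


class TestAdjacency:
    def test_correlation_extremes(self):
        x = pd.DataFrame(
            [[1.0, 2, 3, 4, 5], [2, 4, 6, 8, 10], [-1, -2, -3, -4, -5]],
            index=["a", "b", "c"],
        )
        signed = adjacency(x, beta=4, signed=True).matrix
        assert signed[0, 1] == pytest.approx(1.0)
        assert signed[0, 2] == pytest.approx(0.0)
        unsigned = adjacency(x, beta=4, signed=False).matrix
        assert unsigned[0, 2] == pytest.approx(1.0)

    def test_half_correlation_hand_value(self):
        # two profiles with sample correlation exactly 0.5 by construction:
        # a and e are centered, orthogonal, equal-norm design vectors
        a = np.array([1.0, 1.0, -1.0, -1.0])
        e = np.array([1.0, -1.0, 1.0, -1.0])
        b = 0.5 * a + np.sqrt(0.75) * e
        x = pd.DataFrame([a, b], index=["g1", "g2"])
        net = adjacency(x, beta=6, signed=True)
        assert net.matrix[0, 1] == pytest.approx(0.75**6, abs=1e-6)
        assert 0.75**6 == pytest.approx(0.1780, abs=1e-4)

    def test_input_validation(self):
        x = pd.DataFrame([[1.0, 2, 3, 4], [5, 5, 5, 5]], index=["ok", "flat"])
        with pytest.raises(ValueError, match="flat"):
            adjacency(x, beta=2)
        with pytest.raises(ValueError, match="4 samples"):
            adjacency(x.iloc[:, :3], beta=2)
        with pytest.raises(ValueError, match="beta"):
            adjacency(x.iloc[[0, 0]], beta=0.5)


class TestSoftPower:
    def test_beta_from_candidates_and_fallback(self):
        rng = np.random.default_rng(1)
        x = pd.DataFrame(
            rng.normal(size=(80, 12)), index=[f"g{i}" for i in range(80)]
        )
        with pytest.warns(UserWarning):
            res = pick_soft_power(x, candidates=(1, 2), r2_target=0.999)
        assert res.warning
        assert res.beta in (1, 2)
        assert len(res.table) == 2

    def test_scale_free_fit_on_power_law(self):
        rng = np.random.default_rng(2)
        k = rng.pareto(2.0, size=4000) + 0.5
        assert scale_free_fit(k) > 0.8

    def test_too_few_bins(self):
        with pytest.raises(ValueError):
            scale_free_fit(np.ones(50))


class TestTom:
    def test_isolated_pair_identity(self):
        a = np.array([[1.0, 0.37], [0.37, 1.0]])
        net = GeneNetwork(a, ["a", "b"], "adjacency", 1, True)
        assert tom(net).matrix[0, 1] == pytest.approx(0.37, abs=1e-12)

    def test_complete_graph_saturates(self):
        a = np.ones((3, 3))
        net = GeneNetwork(a, list("abc"), "adjacency", 1, True)
        np.testing.assert_allclose(tom(net).matrix, 1.0)

    @pytest.mark.parametrize("n", [6, 7, 8, 9, 10])
    def test_matches_double_loop_oracle(self, n):
        rng = np.random.default_rng(n)
        a = rng.uniform(0, 1, size=(n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        net = GeneNetwork(a, [f"g{i}" for i in range(n)], "adjacency", 1, True)
        np.testing.assert_allclose(
            tom(net).matrix, tom_oracle(a.tolist()), atol=1e-12
        )

    def test_rejects_asymmetric(self):
        a = np.array([[1.0, 0.2], [0.5, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            tom(GeneNetwork(a, ["a", "b"], "adjacency", 1, True))


class TestConsensus:
    def _random_tom(self, n, rng, scale=0.5):
        m = rng.uniform(0, scale, size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        return GeneNetwork(m, [f"g{i}" for i in range(n)], "tom", 6, True)

    def test_idempotence(self):
        rng = np.random.default_rng(3)
        t = self._random_tom(8, rng)
        np.testing.assert_allclose(consensus_tom(t, t).matrix, t.matrix)

    def test_elementwise_minimum_bound(self):
        rng = np.random.default_rng(4)
        ta, tb = self._random_tom(8, rng), self._random_tom(8, rng)
        cons = consensus_tom(ta, tb).matrix
        assert np.all(cons <= ta.matrix + 1e-12)

    def test_doubled_tom_calibrates_back(self):
        rng = np.random.default_rng(5)
        ta = self._random_tom(10, rng, scale=0.45)
        doubled = ta.matrix * 2
        np.fill_diagonal(doubled, 1.0)
        tb = GeneNetwork(doubled, ta.genes, "tom", 6, True)
        np.testing.assert_allclose(
            consensus_tom(ta, tb).matrix, ta.matrix, atol=1e-12
        )

    def test_gene_mismatch(self):
        rng = np.random.default_rng(6)
        ta, tb = self._random_tom(4, rng), self._random_tom(4, rng)
        tb.genes = ["x0", "x1", "x2", "x3"]
        with pytest.raises(ValueError):
            consensus_tom(ta, tb)


def _block_dissim(block_sizes, within=0.1, between=0.9):
    n = sum(block_sizes)
    d = np.full((n, n), between)
    start = 0
    for s in block_sizes:
        d[start : start + s, start : start + s] = within
        start += s
    np.fill_diagonal(d, 0.0)
    return d


class TestCutModules:
    def test_two_blocks_recovered(self):
        d = _block_dissim([3, 3])
        part = cut_modules(d, [f"g{i}" for i in range(6)], min_size=3)
        labels = part.labels.to_numpy()
        assert len(part.module_ids) == 2
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_min_size_filters_blocks(self):
        d = _block_dissim([3, 3])
        part = cut_modules(d, [f"g{i}" for i in range(6)], min_size=4)
        assert part.module_ids == []
        assert (part.labels == 0).all()

    def test_structureless_input_all_background(self):
        d = _block_dissim([6], within=0.9)
        part = cut_modules(d, [f"g{i}" for i in range(6)], min_size=3)
        assert part.module_ids == []

    def test_min_size_validation(self):
        with pytest.raises(ValueError):
            cut_modules(np.zeros((3, 3)), list("abc"), min_size=1)


class TestEigengenesKme:
    def _partition(self, genes, labels):
        return ModulePartition(labels=pd.Series(labels, index=pd.Index(genes)))

    def test_identical_genes_have_unit_kme(self):
        rng = np.random.default_rng(7)
        profile = rng.normal(size=12)
        x = pd.DataFrame(
            [profile, profile, profile], index=["a", "b", "c"]
        )
        part = self._partition(["a", "b", "c"], [1, 1, 1])
        e = eigengenes(x, part)
        k = kme(x, e)
        np.testing.assert_allclose(k[1], 1.0, atol=1e-9)

    def test_negated_gene_has_negative_kme(self):
        rng = np.random.default_rng(8)
        profile = rng.normal(size=12)
        x = pd.DataFrame(
            [profile, profile + rng.normal(0, 0.05, 12), -profile],
            index=["a", "b", "neg"],
        )
        part = self._partition(["a", "b", "neg"], [1, 1, 1])
        k = kme(x, eigengenes(x, part))
        assert k.loc["neg", 1] == pytest.approx(-1.0, abs=0.02)

    def test_eigengene_orientation_and_variance_share(self):
        rng = np.random.default_rng(9)
        factor = rng.normal(size=16)
        x = pd.DataFrame(
            [0.8 * factor + rng.normal(0, 0.5, 16) for _ in range(10)],
            index=[f"g{i}" for i in range(10)],
        )
        part = self._partition(list(x.index), [1] * 10)
        e = eigengenes(x, part)
        assert np.linalg.norm(e[1]) == pytest.approx(1.0)
        # oriented along the module mean, so kME is mostly positive
        k = kme(x, e)
        assert (k[1] > 0).mean() >= 0.9
        # PC1 explains at least an average gene's share of variance
        z = ((x.T - x.T.mean()) / x.T.std()).T.to_numpy()
        sv = np.linalg.svd(z, compute_uv=False)
        assert sv[0] ** 2 / (sv**2).sum() >= 1 / 10

    def test_tiny_module_rejected(self):
        x = pd.DataFrame(np.random.default_rng(0).normal(size=(2, 8)), index=["a", "b"])
        part = self._partition(["a", "b"], [1, 2])
        with pytest.raises(ValueError):
            eigengenes(x, part)


class TestMerge:
    def _split_factor_data(self, rng, n_genes=40, n_samples=30):
        factor_a = rng.normal(size=n_samples)
        factor_b = rng.normal(size=n_samples)
        x = []
        for _ in range(n_genes):  # all driven by one factor
            x.append(0.9 * factor_a + rng.normal(0, 0.6, n_samples))
        for _ in range(10):
            x.append(0.9 * factor_b + rng.normal(0, 0.6, n_samples))
        genes = [f"g{i}" for i in range(len(x))]
        return pd.DataFrame(x, index=genes)

    def test_half_modules_driven_by_one_factor_merge(self):
        rng = np.random.default_rng(10)
        x = self._split_factor_data(rng)
        labels = [1] * 20 + [2] * 20 + [3] * 10  # modules 1,2 share a factor
        part = ModulePartition(labels=pd.Series(labels, index=x.index))
        merged = merge_close_modules(part, {"A": x}, merge_height=0.25)
        assert len(merged.module_ids) == 2
        lab = merged.labels
        assert len(set(lab.iloc[:40])) == 1
        assert lab.iloc[40] != lab.iloc[0]

    def test_zero_merge_height_is_identity(self):
        rng = np.random.default_rng(11)
        x = self._split_factor_data(rng)
        labels = [1] * 20 + [2] * 20 + [3] * 10
        part = ModulePartition(labels=pd.Series(labels, index=x.index))
        merged = merge_close_modules(part, {"A": x}, merge_height=0.0)
        assert len(merged.module_ids) == 3

    def test_merging_never_increases_module_count(self):
        rng = np.random.default_rng(12)
        x = self._split_factor_data(rng)
        labels = [1] * 20 + [2] * 20 + [3] * 10
        part = ModulePartition(labels=pd.Series(labels, index=x.index))
        for h in (0.0, 0.1, 0.25, 0.5):
            merged = merge_close_modules(part, {"A": x}, merge_height=h)
            assert len(merged.module_ids) <= 3


class TestGeneOrderInvariance:
    def test_detection_invariant_to_gene_permutation(self):
        """Permuting input gene order changes labels only by renaming."""
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(13)
        factors = rng.normal(size=(3, 40))
        rows, labels = [], []
        for m in range(3):
            for _ in range(25):
                rows.append(0.9 * factors[m] + rng.normal(0, 0.5, 40))
                labels.append(m)
        for _ in range(45):
            rows.append(rng.normal(0, 1, 40))
            labels.append(-1)
        genes = [f"g{i:03d}" for i in range(len(rows))]
        x = pd.DataFrame(rows, index=genes)

        def detect(expr):
            net = tom(adjacency(expr, beta=6))
            d = 1 - net.matrix
            np.fill_diagonal(d, 0.0)
            return detect_modules(
                d, net.genes, {"A": expr}, min_size=10, final_min_size=10
            )

        p1 = detect(x)
        perm = rng.permutation(len(genes))
        p2 = detect(x.iloc[perm])
        joint = pd.concat(
            [p1.labels.rename("a"), p2.labels.rename("b")], axis=1
        )
        assert adjusted_rand_score(joint["a"], joint["b"]) == pytest.approx(1.0)
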