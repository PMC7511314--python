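"""Network construction oracles: adjacency identities, TOM brute force,
eigengene SVD equivalence, soft-threshold regression, module detection on
separable blocks."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from coexpheno.expression import ExpressionMatrix
from coexpheno.network import (
    NetworkParams,
    adjacency,
    connectivity,
    detect_modules,
    module_eigengenes,
    pick_soft_threshold,
    scale_free_fit,
    tom_dissimilarity,
    tom_similarity,
)


def _expr(values):
    g, n = values.shape
    return ExpressionMatrix(
        values, [f"g{i}" for i in range(g)], [f"s{i}" for i in range(n)], scale="log2_cpm"
    )


def _two_block_expression(rng, sizes=(50, 40), n=60, noise=0.2):
    """Two planted blocks with strong within-block correlation, plus noise."""
    factors = rng.standard_normal((2, n))
    rows, truth = [], []
    for b, size in enumerate(sizes):
        for _ in range(size):
            rows.append(factors[b] + noise * rng.standard_normal(n))
            truth.append(b + 1)
    return _expr(np.asarray(rows)), np.asarray(truth)


class TestAdjacency:
    def test_power_one_unsigned_is_abs_cor(self, rng):
        x = _expr(rng.standard_normal((6, 30)))
        a = adjacency(x, NetworkParams(power=1))
        np.testing.assert_allclose(a, np.abs(np.corrcoef(x.values)), atol=1e-12)

    def test_anticorrelated_pair_unsigned(self):
        v = np.linspace(0, 1, 20)
        x = _expr(np.vstack([v, -v + 1.0]))
        for power in (1, 3, 6):
            a = adjacency(x, NetworkParams(power=power))
            assert a[0, 1] == pytest.approx(1.0)

    def test_matches_per_entry_brute_force(self, rng):
        x = _expr(rng.standard_normal((5, 25)))
        for network_type in ("unsigned", "signed"):
            a = adjacency(x, NetworkParams(power=4, network_type=network_type))
            for i in range(5):
                for j in range(5):
                    if i == j:
                        assert a[i, j] == 1.0
                        continue
                    c = np.corrcoef(x.values[i], x.values[j])[0, 1]
                    expected = abs(c) ** 4 if network_type == "unsigned" else ((1 + c) / 2) ** 4
                    assert abs(a[i, j] - expected) < 1e-12

    def test_constant_gene_raises(self):
        x = _expr(np.vstack([np.ones(10), np.arange(10.0)]))
        with pytest.raises(ValueError, match="constant"):
            adjacency(x, NetworkParams())

    def test_connectivity_monotone_in_power(self, rng):
        x = _expr(rng.standard_normal((20, 40)))
        k_prev = None
        for power in (1, 2, 4, 8):
            k = connectivity(adjacency(x, NetworkParams(power=power)))
            if k_prev is not None:
                assert np.all(k <= k_prev + 1e-12)
            k_prev = k


class TestTom:
    def test_hand_example_three_nodes(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 1.0)
        tom = tom_similarity(a)
        # (0.25 + 0.5) / (min(1,1) + 1 - 0.5)
        assert tom[0, 1] == pytest.approx(0.5)

    def test_identity_adjacency_gives_zero_overlap(self):
        tom = tom_similarity(np.eye(4))
        assert np.all(tom[~np.eye(4, dtype=bool)] == 0)
        assert np.all(np.diag(tom) == 1)

    def test_matches_brute_force_triple_loop(self, rng):
        b = rng.uniform(0, 1, size=(6, 6))
        a = (b + b.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = tom_similarity(a)
        k = a.sum(axis=1) - 1
        for i in range(6):
            for j in range(6):
                if i == j:
                    continue
                shared = sum(a[i, u] * a[u, j] for u in range(6) if u not in (i, j))
                expected = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
                assert tom[i, j] == pytest.approx(expected, abs=1e-12)

    def test_range_and_symmetry(self, rng):
        b = rng.uniform(0, 1, size=(30, 30))
        a = (b + b.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = tom_similarity(a)
        assert tom.min() >= 0 and tom.max() <= 1
        np.testing.assert_allclose(tom, tom.T, atol=1e-12)
        d = tom_dissimilarity(a)
        np.testing.assert_allclose(d, 1 - tom)

    def test_asymmetric_input_raises(self):
        a = np.eye(3)
        a[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            tom_similarity(a)


class TestSoftThreshold:
    def test_two_block_smoke(self, rng):
        x, _ = _two_block_expression(rng, sizes=(30, 30), n=40)
        power, table = pick_soft_threshold(x, candidate_powers=[1, 2, 4, 6])
        assert power >= 1
        assert set(table.power) == {1, 2, 4, 6}
        assert np.isfinite(table.r2).all()

    def test_r2_matches_brute_force_regression(self, rng):
        x = _expr(rng.standard_normal((80, 40)))
        a = adjacency(x, NetworkParams(power=6))
        k = connectivity(a)
        r2, slope = scale_free_fit(k, n_bins=10)
        # independent recomputation over the binned histogram
        edges = np.linspace(k.min(), k.max() + 1e-12, 11)
        idx = np.clip(np.digitize(k, edges) - 1, 0, 9)
        xs, ys = [], []
        for b in range(10):
            m = idx == b
            if m.sum() and k[m].mean() > 0:
                xs.append(np.log10(k[m].mean()))
                ys.append(np.log10(m.mean()))
        coef = np.polyfit(xs, ys, 1)
        pred = np.polyval(coef, xs)
        ss_res = np.sum((np.array(ys) - pred) ** 2)
        ss_tot = np.sum((np.array(ys) - np.mean(ys)) ** 2)
        assert r2 == pytest.approx(1 - ss_res / ss_tot, abs=1e-10)
        assert slope == pytest.approx(coef[0], abs=1e-10)


class TestDetectModules:
    def test_two_separable_blocks_exact(self, rng):
        x, truth = _two_block_expression(rng, noise=0.15)
        params = NetworkParams(power=6, min_module_size=10)
        d = tom_dissimilarity(adjacency(x, params))
        part = detect_modules(d, params, expression=x)
        assert part.n_modules == 2
        assert adjusted_rand_score(truth, part.labels) == pytest.approx(1.0)
        # labels ordered by decreasing size
        sizes = part.module_sizes
        assert sizes[1] >= sizes[2]

    def test_noise_genes_mostly_pruned(self, rng):
        x, truth = _two_block_expression(rng, sizes=(40, 30), n=100)
        noise = rng.standard_normal((100, 100))
        both = _expr(np.vstack([x.values, noise]))
        params = NetworkParams(power=6, min_module_size=10)
        d = tom_dissimilarity(adjacency(both, params))
        part = detect_modules(d, params, expression=both)
        noise_labels = part.labels[70:]
        assert (noise_labels == 0).mean() >= 0.9

    def test_fewer_genes_than_min_size_warns(self, rng):
        x = _expr(rng.standard_normal((5, 20)))
        params = NetworkParams(power=2, min_module_size=30)
        d = tom_dissimilarity(adjacency(x, params))
        with pytest.warns(UserWarning):
            part = detect_modules(d, params)
        assert (part.labels == 0).all()

    def test_deterministic(self, rng):
        x, _ = _two_block_expression(rng)
        params = NetworkParams(power=6, min_module_size=10)
        d = tom_dissimilarity(adjacency(x, params))
        a = detect_modules(d, params, expression=x)
        b = detect_modules(d, params, expression=x)
        np.testing.assert_array_equal(a.labels, b.labels)


class TestModuleEigengenes:
    def test_identical_genes_give_shared_profile(self, rng):
        profile = rng.standard_normal(30)
        x = _expr(np.vstack([profile, profile, profile]))
        from coexpheno.network import ModulePartition

        part = ModulePartition(np.array([1, 1, 1]), x.gene_ids)
        me = module_eigengenes(x, part)
        z = (profile - profile.mean()) / profile.std()
        np.testing.assert_allclose(me.values[:, 0], z, atol=1e-10)
        assert me.var_explained[0] == pytest.approx(1.0)

    def test_matches_full_svd_oracle(self, rng):
        from coexpheno.network import ModulePartition

        x = _expr(rng.standard_normal((40, 25)) + rng.standard_normal((1, 25)))
        part = ModulePartition(np.ones(40, dtype=int), x.gene_ids)
        me = module_eigengenes(x, part)
        z = (x.values - x.values.mean(axis=1, keepdims=True)) / x.values.std(
            axis=1, keepdims=True
        )
        v = np.linalg.svd(z, full_matrices=False)[2][0]
        v = v / v.std()
        diff = min(np.max(np.abs(me.values[:, 0] - v)), np.max(np.abs(me.values[:, 0] + v)))
        assert diff < 1e-10

    def test_sign_symmetry(self, rng, small_cohort):
        from coexpheno.network import ModulePartition
        from coexpheno.expression import cpm_normalize

        x = cpm_normalize(small_cohort.counts)
        part = ModulePartition(small_cohort.truth_modules, x.gene_ids)
        me = module_eigengenes(x, part)
        flipped_vals = x.values.copy()
        mask = small_cohort.truth_modules == 1
        flipped_vals[mask] = -flipped_vals[mask]
        x2 = ExpressionMatrix(flipped_vals, x.gene_ids, x.sample_ids, scale="log2_cpm")
        me2 = module_eigengenes(x2, part)
        f = small_cohort.truth_factors[:, 0]
        c1 = abs(np.corrcoef(me.values[:, 0], f)[0, 1])
        c2 = abs(np.corrcoef(me2.values[:, 0], f)[0, 1])
        assert c1 == pytest.approx(c2, abs=1e-10)

    def test_constant_module_raises(self):
        from coexpheno.network import ModulePartition

        x = _expr(np.vstack([np.ones(10), np.arange(10.0)]))
        part = ModulePartition(np.array([1, 1]), x.gene_ids)
        with pytest.raises(ValueError, match="constant"):
            module_eigengenes(x, part)

    def test_variance_explained_beats_random_projections(self, rng, small_cohort):
        from coexpheno.network import ModulePartition
        from coexpheno.expression import cpm_normalize

        x = cpm_normalize(small_cohort.counts)
        part = ModulePartition(small_cohort.truth_modules, x.gene_ids)
        me = module_eigengenes(x, part)
        sub = x.values[small_cohort.truth_modules == 1]
        z = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, keepdims=True)
        total = np.sum(z**2)
        for _ in range(100):
            w = rng.standard_normal(z.shape[0])
            w /= np.linalg.norm(w)
            proj = w @ z
            explained = np.sum(proj**2) / total
            assert explained <= me.var_explained[0] + 1e-12
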