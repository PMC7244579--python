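"""Co-expression networks: TOM oracle, module detection, merging, quality Z."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from omixlink import coexpression as cx


def brute_force_tom(a):
    n = a.shape[0]
    tom = np.ones((n, n))
    k = a.sum(axis=1) - 1.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


def make_block_values(n_modules, module_size, n_samples, intra_cor, seed,
                      n_noise=0):
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_modules):
        latent = rng.standard_normal(n_samples)
        for _ in range(module_size):
            rows.append(
                np.sqrt(intra_cor) * latent
                + np.sqrt(1 - intra_cor) * rng.standard_normal(n_samples)
            )
    for _ in range(n_noise):
        rows.append(rng.standard_normal(n_samples))
    n = n_modules * module_size + n_noise
    values = pd.DataFrame(rows, index=[f"f{i:03d}" for i in range(n)],
                          columns=[f"s{i:02d}" for i in range(n_samples)])
    truth = np.repeat(np.arange(1, n_modules + 1), module_size)
    truth = np.concatenate([truth, np.zeros(n_noise, dtype=int)])
    return values, truth


class TestNormalizeWithinGroup:
    def test_unit_variance_per_group(self, block_matrix):
        values, meta = block_matrix
        out = cx.normalize_within_group(values, meta, "time_h")
        for _, grp in meta.groupby("time_h"):
            block = out[grp["sample"]]
            assert np.allclose(block.mean(axis=1), 0, atol=1e-12)
            assert np.allclose(block.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_three_value_example(self):
        values = pd.DataFrame([[1.0, 2.0, 3.0]], index=["f"],
                              columns=["a", "b", "c"])
        meta = pd.DataFrame({"sample": ["a", "b", "c"], "condition": "control",
                             "time_h": 8.0, "replicate": [0, 1, 2]})
        out = cx.normalize_within_group(values, meta, "time_h")
        assert np.allclose(out.loc["f"], [-1, 0, 1])

    def test_constant_feature_becomes_zero(self, block_matrix):
        values, meta = block_matrix
        values = values.copy()
        values.iloc[0] = 5.0
        with pytest.warns(UserWarning):
            out = cx.normalize_within_group(values, meta, "time_h")
        assert (out.iloc[0] == 0).all()

    def test_singleton_group_rejected(self, block_matrix):
        values, meta = block_matrix
        meta = meta.copy()
        meta.loc[0, "time_h"] = 99.0
        with pytest.raises(ValueError):
            cx.normalize_within_group(values, meta, "time_h")


class TestNetwork:
    def test_soft_power_applied(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal(100)
        x = np.vstack([base, 0.5 * base + np.sqrt(0.75) * rng.standard_normal(100)])
        # direct check of the transform on a hand-set correlation
        assert 0.5**10 == pytest.approx(0.0009765625)
        adj = cx.adjacency_from_values(x, 10)
        r = np.corrcoef(x)[0, 1]
        assert adj[0, 1] == pytest.approx(abs(r) ** 10)

    def test_tom_hand_example(self):
        a = np.array([[1, 0.8, 0.2], [0.8, 1, 0.4], [0.2, 0.4, 1]])
        tom = cx.tom_from_adjacency(a)
        # (0.2*0.4 + 0.8) / (min(1.0, 1.2) + 1 - 0.8)
        assert tom[0, 1] == pytest.approx(0.88 / 1.2, rel=1e-12)

    def test_tom_matches_brute_force_random(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            c = rng.uniform(0, 1, size=(10, 10))
            a = (c + c.T) / 2
            np.fill_diagonal(a, 1.0)
            assert np.allclose(cx.tom_from_adjacency(a), brute_force_tom(a),
                               atol=1e-12)

    def test_perfect_pair_tom_one(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal(30)
        values = pd.DataFrame([base, 2 * base + 1, base * 0.5],
                              index=["a", "b", "c"],
                              columns=[f"s{i}" for i in range(30)])
        net = cx.build_network(values, soft_power=6)
        assert net.adjacency[0, 1] == pytest.approx(1.0)
        assert net.tom[0, 1] == pytest.approx(1.0)

    def test_symmetry_and_range(self):
        values, _ = make_block_values(2, 10, 20, 0.7, seed=3)
        net = cx.build_network(values, soft_power=6)
        for mat in (net.adjacency, net.tom):
            assert np.allclose(mat, mat.T, atol=1e-10)
            assert mat.min() >= 0 and mat.max() <= 1 + 1e-12

    def test_constant_feature_rejected(self):
        values = pd.DataFrame(
            [[1.0] * 8, np.arange(8.0)], index=["a", "b"],
            columns=[f"s{i}" for i in range(8)],
        )
        with pytest.raises(ValueError):
            cx.build_network(values, soft_power=2)


class TestDetectModules:
    def test_two_planted_blocks_recovered(self):
        recovered = 0
        for seed in range(10):
            values, truth = make_block_values(2, 40, 40, 0.8, seed=seed)
            net = cx.build_network(values, soft_power=10)
            modules = cx.detect_modules(net, min_module_size=20)
            ari = adjusted_rand_score(truth, modules.assignment.to_numpy())
            recovered += ari >= 0.9
        assert recovered >= 9

    def test_pure_noise_mostly_unassigned(self):
        frac_unassigned = []
        for seed in range(5):
            values, _ = make_block_values(0, 0, 40, 0.8, seed=seed, n_noise=80)
            net = cx.build_network(values, soft_power=10)
            with pytest.warns(UserWarning):
                modules = cx.detect_modules(net, min_module_size=20)
            frac_unassigned.append((modules.assignment == 0).mean())
        assert np.mean(frac_unassigned) >= 0.9

    def test_min_size_larger_than_n(self):
        values, _ = make_block_values(2, 10, 20, 0.8, seed=0)
        net = cx.build_network(values, soft_power=6)
        with pytest.warns(UserWarning):
            modules = cx.detect_modules(net, min_module_size=50)
        assert (modules.assignment == 0).all()

    def test_labels_ordered_by_size(self):
        rng = np.random.default_rng(5)
        rows, names = [], []
        for m, size in enumerate((30, 20)):
            latent = rng.standard_normal(40)
            for i in range(size):
                names.append(f"m{m}_{i}")
                rows.append(np.sqrt(0.8) * latent
                            + np.sqrt(0.2) * rng.standard_normal(40))
        values = pd.DataFrame(rows, index=names,
                              columns=[f"s{i}" for i in range(40)])
        net = cx.build_network(values, soft_power=10)
        modules = cx.detect_modules(net, min_module_size=10)
        sizes = modules.sizes()
        assert sizes[1] >= sizes[2]


class TestEigengene:
    def test_rank_one_recovers_profile(self):
        rng = np.random.default_rng(2)
        v = rng.standard_normal(20)
        values = pd.DataFrame([2 * v, -3 * v + 1, 0.5 * v],
                              index=["a", "b", "c"],
                              columns=[f"s{i}" for i in range(20)])
        eig = cx.module_eigengene(values, ["a", "b", "c"])
        vz = (v - v.mean()) / v.std(ddof=1)
        assert np.allclose(np.abs(np.corrcoef(eig, vz)[0, 1]), 1.0)
        assert eig.std(ddof=1) == pytest.approx(1.0)

    def test_orientation_tracks_mean_profile(self, block_matrix):
        # flipping the data flips the mean profile, so the oriented eigengene
        # flips with it while staying non-negatively correlated with it
        values, _ = block_matrix
        members = list(values.index[:10])
        eig = cx.module_eigengene(values, members)
        eig_flipped = cx.module_eigengene(-values, members)
        assert np.allclose(eig, -eig_flipped, atol=1e-8)
        for vals, e in ((values, eig), (-values, eig_flipped)):
            sub = vals.loc[members].to_numpy()
            z = (sub - sub.mean(1, keepdims=True)) / sub.std(1, ddof=1,
                                                             keepdims=True)
            assert np.corrcoef(e, z.mean(axis=0))[0, 1] >= 0

    def test_explained_variance_rank_one(self):
        rng = np.random.default_rng(3)
        v = rng.standard_normal(15)
        values = pd.DataFrame([v, 2 * v, 3 * v], index=["a", "b", "c"],
                              columns=[f"s{i}" for i in range(15)])
        sub = values.to_numpy()
        z = (sub - sub.mean(1, keepdims=True)) / sub.std(1, ddof=1, keepdims=True)
        svals = np.linalg.svd(z, compute_uv=False)
        assert svals[0] ** 2 / (svals**2).sum() == pytest.approx(1.0)


class TestMergeModules:
    def _modules_from_values(self, values, labels):
        return cx.ModuleSet(assignment=pd.Series(labels, index=values.index))

    def _correlated_modules(self, cor, seed=0):
        rng = np.random.default_rng(seed)
        n_samples = 60
        shared = rng.standard_normal(n_samples)
        rows, labels = [], []
        for m in range(2):
            own = rng.standard_normal(n_samples)
            latent = np.sqrt(cor) * shared + np.sqrt(1 - cor) * own
            for _ in range(15):
                rows.append(latent + 0.05 * rng.standard_normal(n_samples))
                labels.append(m + 1)
        values = pd.DataFrame(rows, index=[f"f{i}" for i in range(30)],
                              columns=[f"s{i}" for i in range(n_samples)])
        return values, labels

    def test_close_eigengenes_merge(self):
        values, labels = self._correlated_modules(0.93)
        modules = self._modules_from_values(values, labels)
        merged = cx.merge_modules(modules, values, 0.25)
        assert len(merged.labels) == 1

    def test_distant_eigengenes_stay(self):
        values, labels = self._correlated_modules(0.3)
        modules = self._modules_from_values(values, labels)
        merged = cx.merge_modules(modules, values, 0.25)
        assert len(merged.labels) == 2

    def test_fixed_point_no_close_pairs(self):
        rng = np.random.default_rng(9)
        values, truth = make_block_values(4, 12, 50, 0.7, seed=4)
        # random initial over-segmentation into 8 groups
        labels = rng.integers(1, 9, size=len(values))
        modules = self._modules_from_values(values, labels)
        merged = cx.merge_modules(modules, values, 0.25)
        eig = merged.eigengenes
        for i, a in enumerate(merged.labels):
            for b in merged.labels[i + 1:]:
                d = 1 - np.corrcoef(eig[a], eig[b])[0, 1]
                assert d >= 0.25 - 1e-9


class TestModuleQuality:
    def test_planted_module_high_z(self):
        values, truth = make_block_values(1, 30, 40, 0.8, seed=1, n_noise=60)
        modules = cx.ModuleSet(
            assignment=pd.Series(truth, index=values.index))
        stats = cx.module_quality(values, modules, soft_power=10,
                                  n_resamples=50, seed=0)
        assert stats.z_summary(1) > 10

    def test_random_module_near_zero_z(self):
        count_ok = 0
        for seed in range(5):
            values, _ = make_block_values(0, 0, 40, 0.8, seed=seed, n_noise=90)
            labels = np.zeros(90, dtype=int)
            labels[:30] = 1
            modules = cx.ModuleSet(
                assignment=pd.Series(labels, index=values.index))
            stats = cx.module_quality(values, modules, soft_power=10,
                                      n_resamples=50, seed=seed)
            count_ok += abs(stats.z_summary(1)) < 2
        assert count_ok >= 4

    def test_same_seed_identical(self):
        values, truth = make_block_values(1, 20, 30, 0.8, seed=2, n_noise=40)
        modules = cx.ModuleSet(assignment=pd.Series(truth, index=values.index))
        s1 = cx.module_quality(values, modules, 10, n_resamples=25, seed=5)
        s2 = cx.module_quality(values, modules, 10, n_resamples=25, seed=5)
        pd.testing.assert_frame_equal(s1.table, s2.table)

    def test_too_few_resamples_rejected(self):
        values, truth = make_block_values(1, 20, 30, 0.8, seed=2)
        modules = cx.ModuleSet(assignment=pd.Series(truth, index=values.index))
        with pytest.raises(ValueError):
            cx.module_quality(values, modules, 10, n_resamples=5, seed=0)
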