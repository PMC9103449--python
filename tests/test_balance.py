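import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import nrsurrogate as nr
from nrsurrogate.balance import SmoteSpec, standardize
from nrsurrogate.errors import InvalidSpecError


def table_of(X, y=None):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    names = tuple(f"f{j}" for j in range(X.shape[1]))
    return nr.FeatureTable(X=X, feature_names=names, y=y)


class TestCluster:
    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(0)
        a = rng.normal((0, 0), 0.1, size=(20, 2))
        b = rng.normal((10, 10), 0.1, size=(30, 2))
        t = table_of(np.vstack([a, b]))
        asg = nr.cluster(t, K=2, seed=0)
        truth = np.array([0] * 20 + [1] * 30)
        assert adjusted_rand_score(truth, asg.labels) == 1.0
        assert sorted(asg.sizes.tolist()) == [20, 30]

    def test_k_one_degenerate(self):
        t = table_of([[0.0, 1.0], [2.0, 3.0], [4.0, 5.0]])
        asg = nr.cluster(t, K=1, seed=0)
        assert set(asg.labels) == {0}
        Z, _, _ = standardize(t.X)
        assert np.allclose(asg.centroids[0], Z.mean(axis=0))

    def test_two_pair_optimum(self):
        # exhaustively optimal 2-partition of two tight pairs
        t = table_of([[0.0, 0.0], [0.0, 1.0], [10.0, 10.0], [10.0, 11.0]])
        asg = nr.cluster(t, K=2, seed=0)
        assert sorted(asg.sizes.tolist()) == [2, 2]
        assert asg.labels[0] == asg.labels[1]
        assert asg.labels[2] == asg.labels[3]
        Z, _, _ = standardize(t.X)
        expected = {tuple(np.round(Z[:2].mean(axis=0), 12)),
                    tuple(np.round(Z[2:].mean(axis=0), 12))}
        got = {tuple(np.round(c, 12)) for c in asg.centroids}
        assert got == expected

    def test_n_less_than_k_rejected(self):
        with pytest.raises(InvalidSpecError):
            nr.cluster(table_of([[0.0], [1.0]]), K=3)

    def test_zero_variance_feature_passes_through(self):
        t = table_of([[1.0, 0.0], [1.0, 1.0], [1.0, 10.0], [1.0, 11.0]])
        asg = nr.cluster(t, K=2, seed=0)
        assert sorted(asg.sizes.tolist()) == [2, 2]

    def test_deterministic(self, augmented):
        a = nr.cluster(augmented, K=2, seed=3)
        b = nr.cluster(augmented, K=2, seed=3)
        assert np.array_equal(a.labels, b.labels)


class TestDangerSet:
    def test_fully_separated_empty(self):
        rng = np.random.default_rng(1)
        minority = rng.normal((0, 0), 0.05, size=(10, 2))
        majority = rng.normal((50, 50), 0.05, size=(30, 2))
        t = table_of(np.vstack([minority, majority]))
        asg = nr.cluster(t, K=2, seed=0)
        danger = nr.danger_set(t, asg, SmoteSpec(k_neighbors=3, m_neighbors=5))
        assert danger.size == 0

    def test_hand_built_1d_example(self):
        # minority {0, 4}, majority {5, 6, 7, 8}, m = 4:
        #   0 -> neighbors {4,5,6,7}: 3 majority -> DANGER? 2 <= 3 < 4 yes...
        #   but 0's neighbors sorted by distance: 4(d4),5(d5),6(d6),7(d7) -> c=3 DANGER
        #   4 -> neighbors {5,6,7,8}? distances: 5:1,6:2,7:3,0:4(tie with 8:4)
        # Use the enumerated counts: 4 has c=3 (5,6,7 majority + 0 minority)
        X = np.array([[0.0], [4.0], [5.0], [6.0], [7.0], [8.0]])
        labels = np.array([0, 0, 1, 1, 1, 1])
        asg = nr.ClusterAssignment(K=2, labels=labels,
                                   centroids=np.array([[2.0], [6.5]]),
                                   sizes=np.array([2, 4]))
        t = table_of(X, y=np.arange(6.0))
        danger = nr.danger_set(t, asg, SmoteSpec(k_neighbors=2, m_neighbors=4))
        # 0.0: 4 nearest are {4,5,6,7}: c=3 -> danger; 4.0: {5,6,7,0 or 8}: c=3 -> danger
        assert set(X[danger].ravel()) == {0.0, 4.0}

    def test_noise_point_excluded(self):
        # one minority point surrounded entirely by majority
        X = np.array([[5.0], [0.0], [4.8], [5.2], [6.0], [-10.0]])
        labels = np.array([0, 0, 1, 1, 1, 1])
        asg = nr.ClusterAssignment(K=2, labels=labels,
                                   centroids=np.zeros((2, 1)),
                                   sizes=np.array([2, 4]))
        t = table_of(X)
        danger = nr.danger_set(t, asg, SmoteSpec(k_neighbors=2, m_neighbors=3))
        # 5.0's 3 nearest are 4.8, 5.2, 6.0 -> all majority -> NOISE
        assert 0 not in danger


class TestSmoteAugment:
    def test_no_op_when_ratio_met(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 1, (25, 2)), rng.normal(8, 1, (25, 2))])
        t = table_of(X, y=rng.uniform(size=50))
        asg = nr.cluster(t, K=2, seed=0)
        out = nr.smote_augment(t, asg, SmoteSpec(target_ratio=1.0), seed=0)
        assert out.n == t.n
        assert np.array_equal(out.X, t.X)

    def test_single_segment_shares_u(self):
        # two danger minority points; one synthetic lies on their segment
        # with the same coefficient for features and target
        X = np.array([[0.0, 0.0], [1.0, 1.0],
                      [0.4, 0.6], [0.5, 0.5], [0.6, 0.4], [0.55, 0.45]])
        y = np.array([0.0, 1.0, 5.0, 5.0, 5.0, 5.0])
        labels = np.array([0, 0, 1, 1, 1, 1])
        asg = nr.ClusterAssignment(K=2, labels=labels,
                                   centroids=np.zeros((2, 2)),
                                   sizes=np.array([2, 4]))
        t = table_of(X, y=y)
        spec = SmoteSpec(k_neighbors=1, m_neighbors=2, target_ratio=0.75)
        out = nr.smote_augment(t, asg, spec, seed=0)
        synth = out.n - t.n
        assert synth == 1
        z, yz = out.X[-1], out.y[-1]
        # z = x_d + u (x_nn - x_d) for the only minority pair
        u = (z[0] - X[0, 0]) / (X[1, 0] - X[0, 0])
        assert 0.0 <= u <= 1.0
        assert np.allclose(z, X[0] + u * (X[1] - X[0]), atol=1e-12)
        assert yz == pytest.approx(0.0 + u * (1.0 - 0.0))

    def test_benchmark_rows_are_convex_combinations(self, augmented):
        # per-row linear-system oracle over candidate (seed, neighbor) pairs
        asg = nr.cluster(augmented, K=2, seed=0)
        spec = SmoteSpec()
        out = nr.smote_augment(augmented, asg, spec, seed=0)
        smote_rows = out.X[out.provenance == "smote"]
        smote_y = out.y[out.provenance == "smote"]
        assert smote_rows.shape[0] > 0

        minority = asg.minority_label()
        seeds = nr.danger_set(augmented, asg, spec)
        min_idx = np.flatnonzero(asg.labels == minority)
        from nrsurrogate.balance import standardize
        from sklearn.neighbors import NearestNeighbors

        Z, _, _ = standardize(augmented.X)
        nn = NearestNeighbors(n_neighbors=spec.k_neighbors + 1).fit(Z[min_idx])
        _, local = nn.kneighbors(Z[seeds])
        pair_a, pair_b = [], []
        for i, s in enumerate(seeds):
            for j in min_idx[local[i]]:
                if j != s:
                    pair_a.append(s)
                    pair_b.append(j)
        A = augmented.X[pair_a]
        B = augmented.X[pair_b]
        ya, yb = augmented.y[pair_a], augmented.y[pair_b]
        D = B - A
        denom = (D * D).sum(axis=1)
        for z, yz in zip(smote_rows, smote_y):
            u = ((z - A) * D).sum(axis=1) / denom
            resid = np.linalg.norm(z - A - u[:, None] * D, axis=1)
            ok = (resid < 1e-9) & (u >= -1e-12) & (u <= 1 + 1e-12)
            assert ok.any()
            # target interpolated with the same coefficient
            k = np.flatnonzero(ok)
            assert np.any(np.abs(ya[k] + u[k] * (yb[k] - ya[k]) - yz) < 1e-9)

    def test_cluster_size_bounds(self, augmented):
        import math

        asg = nr.cluster(augmented, K=2, seed=0)
        spec = SmoteSpec(target_ratio=0.9)
        out = nr.smote_augment(augmented, asg, spec, seed=0)
        minority = asg.minority_label()
        n_min = asg.sizes[minority]
        n_maj = asg.sizes.max()
        n_min_after = n_min + (out.n - augmented.n)
        assert n_min_after >= n_min
        assert n_min_after <= math.ceil(spec.target_ratio * n_maj)

    def test_fallback_to_classic_smote_logged(self, caplog):
        # fully separated clusters -> empty danger set -> classic SMOTE
        import logging

        rng = np.random.default_rng(3)
        minority = rng.normal((0, 0), 0.05, size=(10, 2))
        majority = rng.normal((50, 50), 0.05, size=(30, 2))
        t = table_of(np.vstack([minority, majority]),
                     y=rng.uniform(size=40))
        asg = nr.cluster(t, K=2, seed=0)
        with caplog.at_level(logging.WARNING, logger="nrsurrogate.balance"):
            out = nr.smote_augment(t, asg, SmoteSpec(), seed=0)
        assert out.n == 40 + (30 - 10)
        assert any("classic SMOTE" in r.message for r in caplog.records)

    def test_spec_validation(self):
        with pytest.raises(InvalidSpecError):
            SmoteSpec(k_neighbors=0)
        with pytest.raises(InvalidSpecError):
            SmoteSpec(k_neighbors=5, m_neighbors=3)
        with pytest.raises(InvalidSpecError):
            SmoteSpec(target_ratio=1.5)
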