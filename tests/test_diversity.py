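"""Unit tests for distances, redundancy, clustering and ordination."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from gbscore import diversity as dv
from gbscore.markers import MarkerMatrix


def _dm(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"S{i}" for i in range(len(values))]
    return dv.DistanceMatrix(values=values, ids=ids)


def _frame(rows, samples=None):
    rows = np.asarray(rows, dtype=float)
    samples = samples or [f"S{i}" for i in range(rows.shape[1])]
    return pd.DataFrame(rows, columns=samples,
                        index=[f"m{i}" for i in range(rows.shape[0])])


def gower_oracle(df):
    """Brute-force double loop over sample pairs and variables."""
    X = df.to_numpy().T
    n = X.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = den = 0
            for v in range(X.shape[1]):
                if np.isnan(X[i, v]) or np.isnan(X[j, v]):
                    continue
                den += 1
                num += X[i, v] != X[j, v]
            out[i, j] = num / den
    return out


class TestGower:
    def test_identical_samples_have_zero_distance(self):
        D = dv.gower_distance(_frame([[1, 1], [0, 0], [1, 1]]))
        assert D.values[0, 1] == 0.0

    def test_missing_values_shrink_the_comparison_set(self):
        # x=(1,0,1,miss), y=(0,0,1,1): one mismatch among three shared
        df = _frame([[1, 0], [0, 0], [1, 1], [np.nan, 1]])
        D = dv.gower_distance(df)
        assert D.values[0, 1] == pytest.approx(1 / 3)
        assert D.shared[0, 1] == 3

    def test_matches_brute_force_oracle(self, rng):
        rows = rng.integers(0, 2, size=(50, 20)).astype(float)
        rows[rng.random(rows.shape) < 0.15] = np.nan
        df = _frame(rows)
        D = dv.gower_distance(df)
        np.testing.assert_allclose(D.values, gower_oracle(df), atol=1e-12)

    def test_disjoint_observation_error_names_the_pair(self):
        df = _frame([[1, np.nan], [np.nan, 0]], samples=["alpha", "beta"])
        with pytest.raises(ValueError, match="alpha.*beta"):
            dv.gower_distance(df)

    def test_triangle_inequality_on_complete_data(self, rng):
        rows = rng.integers(0, 2, size=(60, 12)).astype(float)
        D = dv.gower_distance(_frame(rows)).values
        n = len(D)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert D[i, j] <= D[i, k] + D[k, j] + 1e-12

    def test_asymmetric_treatment_ignores_joint_absence(self):
        df = _frame([[1, 1], [0, 0], [1, 0]])
        D = dv.gower_distance(df, treatment="asymmetric")
        # shared presences 1, mismatches 1; joint absence not counted
        assert D.values[0, 1] == pytest.approx(1 / 2)


class TestRedundancy:
    def test_exact_duplicates_group_at_epsilon_zero(self):
        d = np.zeros((5, 5))
        for i in (3, 4):
            for j in range(5):
                if i != j:
                    d[i, j] = d[j, i] = 0.5
        d[3, 4] = d[4, 3] = 0.4
        P = dv.find_redundant(_dm(d), epsilon=0.0)
        assert [sorted(g) for g in P.groups] == [["S0", "S1", "S2"]]
        assert sorted(P.unique_accessions) == ["S3", "S4"]

    def test_large_epsilon_connects_everything(self):
        d = np.array([[0, .2, .9], [.2, 0, .5], [.9, .5, 0]])
        P = dv.find_redundant(_dm(d), epsilon=1.0)
        assert len(P.groups) == 1 and len(P.groups[0]) == 3

    def test_monotone_coarsening_in_epsilon(self, rng):
        x = rng.random((12, 2))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        d /= d.max()
        prev = None
        for eps in (0.0, 0.1, 0.2, 0.4, 1.0):
            P = dv.find_redundant(_dm(d), eps)
            merged = {frozenset(g) for g in P.groups}
            if prev is not None:
                # every earlier group is contained in some later group
                for g in prev:
                    assert any(g <= h for h in merged) or len(g) == 1
            prev = merged | {frozenset([u]) for u in P.unique_accessions}

    def test_core_collection_size_identity(self):
        d = np.zeros((6, 6)) + 0.5
        np.fill_diagonal(d, 0)
        for a, b in ((0, 1), (2, 3), (3, 4)):
            d[a, b] = d[b, a] = 0.0
        P = dv.find_redundant(_dm(d), epsilon=0.0)
        core = dv.core_collection(P)
        n_total = 6
        assert len(core) == n_total - sum(len(g) - 1 for g in P.groups)
        assert len(core) == 3  # {group01 rep, group234 rep, S5}

    def test_single_group_collapses_to_one_representative(self):
        d = np.zeros((4, 4))
        P = dv.find_redundant(_dm(d), epsilon=0.0)
        assert dv.core_collection(P) == [P.representatives[0]]

    def test_calibration_uses_replicate_noise_with_floor(self):
        d = np.zeros((4, 4))
        d[0, 1] = d[1, 0] = 0.004
        D = _dm(d, ids=["A", "A_rep", "B", "C"])
        eps = dv.calibrate_epsilon(D, [("A", "A_rep")], inflation=2.0)
        assert eps == pytest.approx(0.008)
        eps = dv.calibrate_epsilon(D, [("A", "A_rep")], inflation=2.0,
                                   floor=0.02)
        assert eps == 0.02
        with pytest.raises(ValueError):
            dv.calibrate_epsilon(D, [("X", "Y")])


def hclust_oracle(values, ids):
    """Independent exhaustive agglomeration: complete-linkage distances
    recomputed from the original matrix at every step."""
    clusters = {i: (frozenset([i]), i, 1) for i in range(len(ids))}
    Z = []
    next_id = len(ids)
    while len(clusters) > 1:
        best = None
        for a in clusters:
            for b in clusters:
                if a >= b:
                    continue
                sa, _, _ = clusters[a]
                sb, _, _ = clusters[b]
                dist = max(values[i, j] for i in sa for j in sb)
                key = (dist, min(min(sa), min(sb)), max(min(sa), min(sb)))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        sa, na, ca = clusters.pop(a)
        sb, nb, cb = clusters.pop(b)
        Z.append([na, nb, best[0][0], ca + cb])
        clusters[next_id] = (sa | sb, next_id, ca + cb)
        next_id += 1
    return np.array(Z, dtype=float)


class TestHclust:
    def test_three_point_hand_example(self):
        D = _dm([[0, .1, .5], [.1, 0, .6], [.5, .6, 0]])
        tree = dv.hclust_complete(D)
        assert tree.linkage[0, :2].tolist() == [0, 1]
        assert tree.linkage[0, 2] == pytest.approx(0.1)
        assert tree.linkage[1, 2] == pytest.approx(0.6)  # root = max dist

    def test_matches_exhaustive_oracle_with_ties(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 13))
            # quantised distances force ties to exercise the tie-break
            d = np.round(rng.random((n, n)), 1)
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            ids = [f"S{i}" for i in range(n)]
            tree = dv.hclust_complete(_dm(d, ids))
            np.testing.assert_allclose(tree.linkage, hclust_oracle(d, ids))

    def test_matches_scipy_on_tie_free_instances(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 15))
            x = rng.random((n, 5))
            d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
            tree = dv.hclust_complete(_dm(d))
            ref = linkage(squareform(d, checks=False), method="complete")
            np.testing.assert_allclose(tree.linkage[:, 2], ref[:, 2],
                                       atol=1e-12)

    def test_ultrametric_input_reproduced_exactly(self):
        # heights 0.2 (S0,S1), 0.4 (with S2): a valid ultrametric
        d = np.array([[0, .2, .4], [.2, 0, .4], [.4, .4, 0]])
        tree = dv.hclust_complete(_dm(d))
        assert tree.heights.tolist() == [0.2, 0.4]
        assert (np.diff(tree.heights) >= 0).all()

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            dv.hclust_complete(_dm([[0.0]]))

    def test_newick_export_parses_and_keeps_leaves(self, tmp_path):
        import skbio

        D = _dm([[0, .1, .5], [.1, 0, .6], [.5, .6, 0]])
        tree = dv.hclust_complete(D)
        tree.supports = {3: 97.0, 4: 100.0}
        nwk = tree.to_newick(tmp_path / "t.nwk")
        parsed = skbio.TreeNode.read([nwk])
        assert {t.name for t in parsed.tips()} == {"S0", "S1", "S2"}


class TestBootstrap:
    def test_no_bootstrap_returns_plain_tree(self):
        df = _frame(np.eye(4))
        tree = dv.bootstrap_support(df, n_boot=0)
        assert tree.supports == {}

    def test_duplicated_marker_set_leaves_supports_stable(self, rng):
        # two 5-sample groups separated by 15 diagnostic markers plus
        # 15 noisy shared markers
        diag = np.hstack([np.ones((15, 5)), np.zeros((15, 5))])
        shared = (rng.random((15, 10)) < 0.5).astype(float)
        noise = (rng.random((30, 10)) < 0.05).astype(float)
        df = _frame(np.abs(np.vstack([diag, shared]) - noise))
        t1 = dv.bootstrap_support(df, n_boot=150, seed=1)
        df2 = pd.concat([df, df])
        t2 = dv.bootstrap_support(df2, n_boot=150, seed=2)
        s1 = sorted(t1.supports.values())
        s2 = sorted(t2.supports.values())
        assert np.allclose(s1[-3:], s2[-3:], atol=15)

    def test_seeded_supports_reproducible(self, rng):
        df = _frame(rng.integers(0, 2, size=(25, 8)).astype(float))
        t1 = dv.bootstrap_support(df, n_boot=60, seed=5)
        t2 = dv.bootstrap_support(df, n_boot=60, seed=5)
        assert t1.supports == t2.supports


class TestPCoA:
    def test_collinear_points_put_all_variance_on_axis_one(self):
        D = _dm([[0, 1, 2], [1, 0, 1], [2, 1, 0]])
        res = dv.pcoa(D)
        assert res.pave[0] == pytest.approx(1.0)

    def test_unit_square_splits_variance_evenly(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = dv.pcoa(_dm(d))
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])
        assert res.pave[:2].tolist() == pytest.approx([0.5, 0.5])

    def test_euclidean_roundtrip(self, rng):
        pts = rng.random((15, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = dv.pcoa(_dm(d))
        back = np.sqrt(((res.coordinates[:, None] - res.coordinates[None]) ** 2
                        ).sum(-1))
        np.testing.assert_allclose(back, d, atol=1e-8)

    def test_euclidean_input_has_no_material_negative_eigenvalues(self, rng):
        pts = rng.random((10, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        n = len(d)
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (d ** 2) @ J
        eig = np.linalg.eigvalsh(B)
        assert eig.min() > -1e-9

    def test_matches_reference_implementation(self, rng):
        import skbio

        rows = rng.integers(0, 2, size=(40, 10)).astype(float)
        D = dv.gower_distance(_frame(rows))
        mine = dv.pcoa(D)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(D.values, ids=D.ids))
        m = len(mine.eigenvalues)
        np.testing.assert_allclose(
            mine.eigenvalues, ref.eigvals.to_numpy()[:m], atol=1e-8)
        # coordinates agree up to per-axis sign
        for ax in range(min(3, m)):
            a = mine.coordinates[:, ax]
            b = ref.samples.to_numpy()[:, ax]
            assert (np.allclose(a, b, atol=1e-6)
                    or np.allclose(a, -b, atol=1e-6))

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            dv.pcoa(_dm(np.zeros((3, 3))))
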