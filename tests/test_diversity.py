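import io
import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from rumenage.diversity import (
    beta_diversity_matrix,
    faith_pd,
    kruskal_wallis,
    mann_whitney_u,
    pairwise_permanova,
    pcoa,
    permanova,
    unweighted_unifrac,
    weighted_unifrac,
    within_group_dissimilarity,
)
from rumenage.synthdata import simulate_tree
from conftest import THREE_TIP_TREE, make_metadata


def branch_sets(newick: str) -> dict[str, list[float]]:
    """Oracle: per-tip list of branch lengths on the path to the root."""
    tree = TreeNode.read(io.StringIO(newick))
    out = {}
    for tip in tree.tips():
        lengths, node = [], tip
        while node.parent is not None:
            lengths.append((id(node), node.length or 0.0))
            node = node.parent
        out[tip.name] = lengths
    return out


def oracle_unweighted_unifrac(newick: str, a: set, b: set) -> float:
    paths = branch_sets(newick)
    sub_a = {br for t in a for br in paths[t]}
    sub_b = {br for t in b for br in paths[t]}
    union = {br_id: l for br_id, l in sub_a | sub_b}
    shared = {br_id: l for br_id, l in sub_a & sub_b}
    total = sum(union.values())
    return (total - sum(shared.values())) / total


class TestFaithPD:
    @pytest.mark.parametrize("observed, expected", [
        ({"A": 1, "B": 1, "C": 1}, 10.0),
        ({"A": 1, "B": 0, "C": 0}, 4.0),   # A branch (1) + internal (3)
        ({"A": 1, "B": 1, "C": 0}, 6.0),
    ])
    def test_examples_root_inclusive(self, observed, expected):
        assert faith_pd(observed, THREE_TIP_TREE) == pytest.approx(expected)

    def test_missing_tip_listed(self):
        with pytest.raises(ValueError, match="Z"):
            faith_pd({"Z": 1}, THREE_TIP_TREE)

    def test_monotone_in_observed_tips(self):
        rng = np.random.default_rng(5)
        for seed in range(10):
            tips = [f"t{i}" for i in range(6)]
            nwk = simulate_tree(tips, seed=seed)
            present = set(rng.choice(tips, size=3, replace=False))
            base = faith_pd({t: int(t in present) for t in tips}, nwk)
            extra = present | {rng.choice([t for t in tips if t not in present])}
            more = faith_pd({t: int(t in extra) for t in tips}, nwk)
            assert more >= base - 1e-12


class TestUniFrac:
    def test_identical_presence_is_zero(self):
        assert unweighted_unifrac({"A": 1, "B": 1, "C": 0},
                                  {"A": 1, "B": 1, "C": 0},
                                  THREE_TIP_TREE) == pytest.approx(0.0)

    def test_disjoint_tips_is_one(self):
        assert unweighted_unifrac({"A": 1, "B": 0, "C": 0},
                                  {"A": 0, "B": 0, "C": 1},
                                  THREE_TIP_TREE) == pytest.approx(1.0)

    def test_nested_sample_matches_hand_computation(self):
        got = unweighted_unifrac({"A": 1, "B": 1, "C": 0},
                                 {"A": 1, "B": 0, "C": 0}, THREE_TIP_TREE)
        assert got == pytest.approx(1 / 3, abs=1e-9)

    def test_both_empty_errors(self):
        with pytest.raises(ValueError, match="empty"):
            unweighted_unifrac({"A": 0}, {"A": 0}, "(A:1,B:1);")

    def test_weighted_raw_two_tip_example(self):
        assert weighted_unifrac({"A": 10, "B": 0}, {"A": 0, "B": 10},
                                "(A:1,B:1);") == pytest.approx(2.0)

    def test_weighted_identical_composition_zero_and_symmetric(self):
        rng = np.random.default_rng(0)
        tips = [f"t{i}" for i in range(5)]
        nwk = simulate_tree(tips, seed=3)
        a = dict(zip(tips, rng.integers(1, 20, 5)))
        b = dict(zip(tips, rng.integers(1, 20, 5)))
        assert weighted_unifrac(a, a, nwk) == pytest.approx(0.0)
        assert weighted_unifrac(a, b, nwk) == pytest.approx(
            weighted_unifrac(b, a, nwk))

    def test_metric_axioms_vs_oracle_on_random_trees(self):
        rng = np.random.default_rng(11)
        tips = [f"t{i}" for i in range(5)]
        for seed in range(10):
            nwk = simulate_tree(tips, seed=seed)
            vecs = []
            while len(vecs) < 3:
                v = set(np.array(tips)[rng.random(5) > 0.5])
                if v:
                    vecs.append(v)
            d = {}
            for i, j in itertools.combinations(range(3), 2):
                pres_i = {t: int(t in vecs[i]) for t in tips}
                pres_j = {t: int(t in vecs[j]) for t in tips}
                dij = unweighted_unifrac(pres_i, pres_j, nwk)
                assert dij == pytest.approx(
                    oracle_unweighted_unifrac(nwk, vecs[i], vecs[j]), abs=1e-9)
                d[(i, j)] = d[(j, i)] = dij
            assert d[(0, 1)] <= d[(0, 2)] + d[(2, 1)] + 1e-9


class TestPCoA:
    def test_collinear_points_recovered_on_first_axis(self):
        pts = np.array([0.0, 3.0, 5.0])
        D = pd.DataFrame(np.abs(pts[:, None] - pts[None, :]),
                         index=list("abc"), columns=list("abc"))
        res = pcoa(D)
        ax1 = res.coordinates.iloc[:, 0].to_numpy()
        got = np.abs(ax1[:, None] - ax1[None, :])
        assert np.allclose(got, D.to_numpy(), atol=1e-8)
        assert np.all(res.eigenvalues[1:] < 1e-8)

    def test_zero_distances_give_zero_coordinates(self):
        D = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("abc"))
        assert pcoa(D).coordinates.shape[1] == 0

    def test_euclidean_distances_reconstructed(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(7, 3))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(7)]
        res = pcoa(pd.DataFrame(D, index=ids, columns=ids))
        C = res.coordinates.to_numpy()
        got = np.sqrt(((C[:, None] - C[None]) ** 2).sum(-1))
        assert np.allclose(got, D, atol=1e-8)

    def test_matches_skbio_eigenvalues(self):
        from skbio.stats.ordination import pcoa as skbio_pcoa
        from skbio import DistanceMatrix
        rng = np.random.default_rng(4)
        X = rng.normal(size=(6, 2))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(6)]
        ours = pcoa(pd.DataFrame(D, index=ids, columns=ids))
        theirs = skbio_pcoa(DistanceMatrix(D, ids=ids))
        assert np.allclose(sorted(ours.eigenvalues[ours.eigenvalues > 1e-10]),
                           sorted(e for e in theirs.eigvals if e > 1e-10),
                           atol=1e-8)

    def test_asymmetric_input_rejected(self):
        D = pd.DataFrame([[0, 1], [2, 0]], index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError, match="symmetric"):
            pcoa(D)


def _two_cluster_distance(gap: float, n: int = 6, seed: int = 0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n, 2)) * 0.1
    X[n:, 0] += gap
    D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
    ids = [f"s{i}" for i in range(2 * n)]
    labels = pd.Series(["a"] * n + ["b"] * n, index=ids)
    return pd.DataFrame(D, index=ids, columns=ids), labels


class TestPermanova:
    def test_separated_groups_reach_minimal_p(self):
        D, labels = _two_cluster_distance(gap=50.0)
        res = permanova(D, labels, n_permutations=199, seed=0)
        assert res.p_value == pytest.approx(1 / 200)

    def test_pseudo_f_invariant_to_label_names(self):
        D, labels = _two_cluster_distance(gap=2.0)
        a = permanova(D, labels, n_permutations=99, seed=1)
        b = permanova(D, labels.map({"a": "x", "b": "y"}), n_permutations=99, seed=1)
        assert a.pseudo_f == pytest.approx(b.pseudo_f)

    def test_pseudo_f_matches_direct_decomposition(self):
        # brute-force among/within sum-of-squares pseudo-F for two groups
        D, labels = _two_cluster_distance(gap=1.0, n=4, seed=3)
        res = permanova(D, labels, n_permutations=99, seed=0)
        d2 = D.to_numpy() ** 2
        n = len(labels)
        sst = d2[np.triu_indices(n, 1)].sum() / n
        ssw = 0.0
        for g in ("a", "b"):
            idx = np.flatnonzero(labels.to_numpy() == g)
            sub = d2[np.ix_(idx, idx)]
            ssw += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        ssa = sst - ssw
        f = (ssa / 1) / (ssw / (n - 2))
        assert res.pseudo_f == pytest.approx(f, rel=1e-8)

    def test_undersized_group_rejected(self):
        D, labels = _two_cluster_distance(gap=1.0, n=2)
        labels.iloc[0] = "c"
        with pytest.raises(ValueError):
            permanova(D.iloc[:3, :3], labels.iloc[:3])

    def test_pairwise_adjusts_p_values(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(12, 2))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(12)]
        labels = pd.Series(["a"] * 4 + ["b"] * 4 + ["c"] * 4, index=ids)
        res = pairwise_permanova(pd.DataFrame(D, index=ids, columns=ids),
                                 labels, n_permutations=99, seed=0)
        assert len(res) == 3
        for r in res:
            assert r.adjusted_p >= r.p_value - 1e-12


class TestRankTests:
    def test_mann_whitney_fully_separated(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0

    def test_kruskal_identical_groups_h_zero(self):
        h, _ = kruskal_wallis([1, 2, 3], [1, 2, 3])
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_all_identical_values_warn_p_one(self):
        with pytest.warns(UserWarning):
            _, p = kruskal_wallis([5, 5], [5, 5])
        assert p == 1.0

    def test_rank_invariance_under_monotone_transform(self):
        a, b = [1.0, 4.0, 9.0], [2.0, 3.0, 16.0]
        u1, p1 = mann_whitney_u(a, b)
        u2, p2 = mann_whitney_u(np.sqrt(a), np.sqrt(b))
        assert u1 == u2 and p1 == pytest.approx(p2)


class TestWithinGroupDissimilarity:
    def _metadata(self, ids, groups):
        return make_metadata(dict(zip(ids, groups)))

    def test_identical_samples_give_zero_means(self):
        ids = [f"s{i}" for i in range(4)]
        D = pd.DataFrame(np.zeros((4, 4)), index=ids, columns=ids)
        meta = self._metadata(ids, ["7d", "7d", "12y", "12y"])
        means, _, _ = within_group_dissimilarity(D, meta)
        assert (means == 0).all()

    def test_mean_invariant_to_within_group_ordering(self):
        rng = np.random.default_rng(1)
        ids = [f"s{i}" for i in range(6)]
        X = rng.normal(size=(6, 2))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        D = pd.DataFrame(D, index=ids, columns=ids)
        meta = self._metadata(ids, ["7d"] * 3 + ["12y"] * 3)
        m1, _, _ = within_group_dissimilarity(D, meta)
        shuffled = ["s1", "s2", "s0", "s5", "s3", "s4"]
        m2, _, _ = within_group_dissimilarity(D.loc[shuffled, shuffled], meta)
        pd.testing.assert_series_equal(m1, m2)

    def test_shrinking_spread_yields_negative_trend(self):
        # groups with geometrically shrinking within-group spread over age
        hits = 0
        groups = ["7d", "1m", "6m", "2y", "5y", "12y"]
        for seed in range(10):
            rng = np.random.default_rng(seed)
            ids, labels, pts = [], [], []
            for gi, g in enumerate(groups):
                for i in range(5):
                    ids.append(f"{g}_{i}")
                    labels.append(g)
                    pts.append(rng.normal(size=2) * (2.0 * 0.55**gi))
            X = np.array(pts)
            D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
            D = pd.DataFrame(D, index=ids, columns=ids)
            means, rho, p = within_group_dissimilarity(
                D, self._metadata(ids, labels))
            if rho < 0 and p < 0.05:
                hits += 1
        assert hits >= 9


class TestBetaMatrix:
    def test_unifrac_matrix_is_valid_distance(self, tiny_table):
        nwk = "(A:1,B:2);"
        D = beta_diversity_matrix(tiny_table, nwk, metric="weighted")
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0)


class TestPermanovaCrossCheck:
    def test_pseudo_f_matches_skbio(self):
        from skbio.stats.distance import permanova as skbio_permanova
        from skbio import DistanceMatrix
        D, labels = _two_cluster_distance(gap=1.5, n=5, seed=8)
        ours = permanova(D, labels, n_permutations=99, seed=0)
        theirs = skbio_permanova(DistanceMatrix(D.to_numpy(), ids=list(D.index)),
                                 labels.tolist(), permutations=99)
        assert ours.pseudo_f == pytest.approx(float(theirs["test statistic"]),
                                              rel=1e-10)
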