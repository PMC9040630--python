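"""Distances, ordination, PERMANOVA, distance-ratio statistic.

UniFrac is checked two independent ways: a naive per-branch oracle that
enumerates each branch's descendant tip set from scratch, and scikit-bio's
reference implementation.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix
from skbio.diversity.beta import unweighted_unifrac as skbio_uu
from skbio.diversity.beta import weighted_unifrac as skbio_wu
from skbio.stats.distance import permanova as skbio_permanova

from ogukit.commdiv import (
    beta_matrix,
    bray_curtis,
    jaccard,
    pcoa,
    permanova,
    pseudo_f,
    relative_distance_ratio,
    unweighted_unifrac,
    weighted_unifrac,
)
from ogukit.synthgen import random_phylogeny
from ogukit.tables import FeatureTable


# ----------------------------------------------------------------- oracles


def naive_unifrac(tree, x, y, features, kind, normalized=False):
    """Brute force: enumerate every branch's descendant tips explicitly."""
    counts = dict(zip(features, zip(x, y)))
    xs, ys = sum(x), sum(y)
    num = den = unique = total = 0.0
    for node in tree.traverse():
        if node.parent is None:
            continue
        length = node.length or 0.0
        tips = [node.name] if node.is_tip() else [t.name for t in node.tips()]
        cx = sum(counts.get(t, (0, 0))[0] for t in tips)
        cy = sum(counts.get(t, (0, 0))[1] for t in tips)
        if kind == "unweighted":
            if cx > 0 or cy > 0:
                total += length
                if (cx > 0) != (cy > 0):
                    unique += length
        else:
            px, py = cx / xs, cy / ys
            num += length * abs(px - py)
            den += length * (px + py)
    if kind == "unweighted":
        return unique / total if total else 0.0
    return num / den if normalized else num


def naive_pseudo_f(d, labels):
    """PERMANOVA pseudo-F via explicit pairwise loops."""
    n = len(labels)
    groups = sorted(set(labels))
    a = len(groups)
    ss_total = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        ss_within += sum(
            d[i, j] ** 2 for i in idx for j in idx if i < j
        ) / len(idx)
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def random_tree_and_counts(seed, max_tips=16):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, max_tips + 1))
    tree = random_phylogeny(n, seed=seed)
    features = [t.name for t in tree.tips()]
    x = rng.integers(0, 12, size=n).astype(float)
    y = rng.integers(0, 12, size=n).astype(float)
    if x.sum() == 0:
        x[0] = 1
    if y.sum() == 0:
        y[-1] = 1
    return tree, features, x, y


# ---------------------------------------------------------------- metrics


class TestTreeFreeMetrics:
    def test_bray_curtis_formula(self):
        assert bray_curtis([2, 2], [1, 3]) == pytest.approx(0.25)

    def test_bray_curtis_identity_and_disjoint(self):
        assert bray_curtis([3, 1], [3, 1]) == 0.0
        assert bray_curtis([3, 0], [0, 5]) == 1.0

    def test_jaccard_set_arithmetic(self):
        assert jaccard([1, 2, 0], [0, 5, 3]) == pytest.approx(2 / 3)
        assert jaccard([1, 1, 0], [2, 9, 0]) == 0.0
        assert jaccard([1, 0], [0, 1]) == 1.0

    def test_all_zero_pair_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [0, 0])
        with pytest.raises(ValueError):
            jaccard([0, 0], [0, 0])

    def test_scale_invariance_on_relative_abundance(self):
        x = np.array([3.0, 1.0, 6.0])
        y = np.array([1.0, 5.0, 4.0])
        rx, ry = x / x.sum(), y / y.sum()
        assert bray_curtis(rx, ry) == pytest.approx(bray_curtis(rx, 7.3 * ry / (7.3 * ry).sum()))


class TestUniFrac:
    def test_two_tip_tree_extremes(self):
        tree = random_phylogeny(2, seed=0)
        for t in tree.tips():
            t.length = 1.0
        feats = [t.name for t in tree.tips()]
        assert unweighted_unifrac(tree, [1, 0], [0, 1], feats) == 1.0
        assert unweighted_unifrac(tree, [1, 1], [2, 5], feats) == 0.0
        assert weighted_unifrac(tree, [1, 0], [0, 1], feats) == pytest.approx(2.0)
        assert weighted_unifrac(tree, [1, 0], [0, 1], feats, normalized=True) == pytest.approx(1.0)

    def test_proportional_samples_are_zero(self):
        tree, feats, x, _ = random_tree_and_counts(3)
        assert weighted_unifrac(tree, x, 4 * x, feats) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_naive_per_branch_oracle(self, seed):
        tree, feats, x, y = random_tree_and_counts(seed)
        assert unweighted_unifrac(tree, x, y, feats) == pytest.approx(
            naive_unifrac(tree, x, y, feats, "unweighted"), abs=1e-9
        )
        assert weighted_unifrac(tree, x, y, feats) == pytest.approx(
            naive_unifrac(tree, x, y, feats, "weighted"), abs=1e-9
        )
        assert weighted_unifrac(tree, x, y, feats, normalized=True) == pytest.approx(
            naive_unifrac(tree, x, y, feats, "weighted", normalized=True), abs=1e-9
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scikit_bio(self, seed):
        tree, feats, x, y = random_tree_and_counts(seed, max_tips=10)
        assert unweighted_unifrac(tree, x, y, feats) == pytest.approx(
            float(skbio_uu(x, y, taxa=feats, tree=tree)), abs=1e-9
        )
        assert weighted_unifrac(tree, x, y, feats) == pytest.approx(
            float(skbio_wu(x, y, taxa=feats, tree=tree)), abs=1e-9
        )

    def test_star_tree_identity_with_manhattan(self):
        rng = np.random.default_rng(12)
        from skbio import TreeNode

        n = 8
        feats = [f"f{i}" for i in range(n)]
        star = TreeNode(children=[TreeNode(name=f, length=1.0) for f in feats])
        for _ in range(25):
            x = rng.integers(0, 20, size=n).astype(float)
            y = rng.integers(0, 20, size=n).astype(float)
            if x.sum() == 0 or y.sum() == 0:
                continue
            manhattan = np.abs(x / x.sum() - y / y.sum()).sum()
            assert weighted_unifrac(star, x, y, feats) == pytest.approx(manhattan, abs=1e-9)
            # equivalently twice the Bray-Curtis of relative abundances
            assert manhattan == pytest.approx(2 * bray_curtis(x / x.sum(), y / y.sum()), abs=1e-9)

    def test_missing_feature_named_in_error(self):
        tree = random_phylogeny(3, seed=1)
        with pytest.raises(ValueError, match="ghost"):
            unweighted_unifrac(tree, [1, 0, 0, 2], [0, 1, 0, 0],
                               [t.name for t in tree.tips()] + ["ghost"])

    def test_scale_invariance(self):
        tree, feats, x, y = random_tree_and_counts(9)
        for fn in (unweighted_unifrac, weighted_unifrac):
            assert fn(tree, x, y, feats) == pytest.approx(fn(tree, 3 * x, 11 * y, feats), abs=1e-12)


class TestBetaMatrix:
    def test_matches_per_pair_calls_and_symmetry(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.integers(0, 9, size=(5, 4)).astype(float),
                          index=[f"G{i}" for i in range(5)],
                          columns=list("WXYZ"))
        table = FeatureTable(df, "rounded_int")
        dm = beta_matrix(table, "braycurtis")
        for i, j in itertools.combinations(range(4), 2):
            expect = bray_curtis(df.iloc[:, i], df.iloc[:, j])
            assert dm.data[i, j] == pytest.approx(expect)
        assert np.allclose(dm.data, dm.data.T, atol=1e-12)
        assert np.all(np.diag(dm.data) == 0)

    def test_duplicate_sample_distance_zero(self):
        df = pd.DataFrame({"A": [1.0, 2.0], "B": [1.0, 2.0]}, index=["G1", "G2"])
        dm = beta_matrix(FeatureTable(df, "rounded_int"), "braycurtis")
        assert dm["A", "B"] == 0.0

    def test_unifrac_requires_tree(self, concept_fixture):
        with pytest.raises(ValueError, match="tree"):
            beta_matrix(concept_fixture.table, "weighted-unifrac")


class TestPcoa:
    def test_equilateral_triangle(self):
        dm = DistanceMatrix([[0, 1, 1], [1, 0, 1], [1, 1, 0]], ids=list("abc"))
        res = pcoa(dm)
        pos = res.eigenvalues[res.eigenvalues > 1e-10]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1])
        assert res.proportion_explained == pytest.approx([0.5, 0.5])

    def test_euclidean_embedding_recovered(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(6, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(6)])
        res = pcoa(dm)
        coords = res.coordinates.to_numpy()
        d2 = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        assert np.allclose(d2, d, atol=1e-9)

    def test_duplicated_point_coincides(self):
        d = np.array([[0, 0, 1.0], [0, 0, 1.0], [1.0, 1.0, 0]])
        res = pcoa(DistanceMatrix(d, ids=list("abc")))
        assert np.allclose(res.coordinates.loc["a"], res.coordinates.loc["b"], atol=1e-9)

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(7, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        res = pcoa(DistanceMatrix(d, ids=[f"s{i}" for i in range(7)]))
        assert res.proportion_explained.sum() == pytest.approx(1.0)

    def test_matches_scikit_bio_proportions(self):
        rng = np.random.default_rng(14)
        pts = rng.normal(size=(6, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(6)])
        from skbio.stats.ordination import pcoa as skbio_pcoa

        ref = skbio_pcoa(dm, dimensions=0)
        mine = pcoa(dm)
        k = len(mine.proportion_explained)
        assert np.allclose(
            mine.proportion_explained, ref.proportion_explained.to_numpy()[:k], atol=1e-9
        )


class TestPermanova:
    def two_cluster_dm(self, n_per=3, sep=10.0, seed=0):
        rng = np.random.default_rng(seed)
        pts = np.vstack([
            rng.normal(0, 0.1, size=(n_per, 2)),
            rng.normal(sep, 0.1, size=(n_per, 2)),
        ])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        ids = [f"s{i}" for i in range(2 * n_per)]
        labels = ["g1"] * n_per + ["g2"] * n_per
        return DistanceMatrix(d, ids=ids), labels

    def test_separated_clusters_maximal_f_exhaustive(self):
        # observed F is maximal over all relabelings of this configuration:
        # of the C(6,3) = 20 distinct label sequences only the true one and
        # its group-swapped mirror reach it, so the exhaustive p is 2/20
        dm, labels = self.two_cluster_dm()
        res = permanova(dm, labels, exhaustive=True)
        assert res.n_permutations == 20
        assert res.p_value == pytest.approx(2 / 20)

    def test_monte_carlo_minimal_p(self):
        # with 10+10 samples a random relabeling essentially never recreates
        # the observed split, so the +1-corrected p hits its floor
        dm, labels = self.two_cluster_dm(n_per=10)
        res = permanova(dm, labels, n_permutations=999, seed=1)
        assert res.p_value == pytest.approx(1 / 1000)
        assert res.p_value >= 1 / (res.n_permutations + 1)

    @pytest.mark.parametrize("seed", range(4))
    def test_pseudo_f_matches_naive_and_scikit_bio(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(8, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        ids = [f"s{i}" for i in range(8)]
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 2
        dm = DistanceMatrix(d, ids=ids)
        f_mine = pseudo_f(dm, labels)
        assert f_mine == pytest.approx(naive_pseudo_f(d, labels), abs=1e-9)
        ref = skbio_permanova(dm, list(labels), permutations=9, seed=0)
        assert f_mine == pytest.approx(float(ref["test statistic"]), abs=1e-9)

    def test_exhaustive_agrees_with_monte_carlo(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(7, 2))
        pts[:3] += 1.5
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(7)])
        labels = ["a"] * 3 + ["b"] * 4
        exact = permanova(dm, labels, exhaustive=True)
        mc = permanova(dm, labels, n_permutations=20000, seed=3)
        assert mc.p_value == pytest.approx(exact.p_value, abs=0.02)

    def test_invariant_to_label_renaming_and_order(self):
        dm, labels = self.two_cluster_dm(seed=6)
        renamed = ["X" if l == "g1" else "Y" for l in labels]
        assert pseudo_f(dm, labels) == pytest.approx(pseudo_f(dm, renamed))
        perm = np.random.default_rng(0).permutation(len(dm.ids))
        dm2 = DistanceMatrix(dm.data[np.ix_(perm, perm)], ids=[dm.ids[i] for i in perm])
        grouping = dict(zip(dm.ids, labels))
        assert pseudo_f(dm2, grouping) == pytest.approx(pseudo_f(dm, grouping))

    def test_single_group_rejected(self):
        dm, _ = self.two_cluster_dm()
        with pytest.raises(ValueError):
            permanova(dm, ["g"] * 6, n_permutations=9, seed=0)

    def test_deterministic_given_seed(self):
        dm, labels = self.two_cluster_dm(sep=0.5, seed=2)
        a = permanova(dm, labels, n_permutations=99, seed=42)
        b = permanova(dm, labels, n_permutations=99, seed=42)
        assert a.p_value == b.p_value


class TestRelativeDistanceRatio:
    def test_equal_distances_give_unit_ratio(self):
        n = 6
        d = np.ones((n, n)) - np.eye(n)
        ids = [f"s{i}" for i in range(n)]
        sites = dict(zip(ids, ["o1", "o1", "o2", "o2", "x", "y"]))
        dm = DistanceMatrix(d, ids=ids)
        ratios = relative_distance_ratio(dm, sites, {"o1", "o2"})
        assert np.allclose(ratios, 1.0)

    def test_halved_in_group_distance(self):
        ids = ["a", "b", "c", "d"]
        sites = {"a": "o1", "b": "o2", "c": "x", "d": "x"}
        d = np.array([
            [0, 1, 2, 2.0],
            [1, 0, 2, 2.0],
            [2, 2, 0, 2.0],
            [2, 2, 2, 0.0],
        ])
        ratios = relative_distance_ratio(DistanceMatrix(d, ids=ids), sites, {"o1", "o2"})
        assert np.allclose(ratios, 0.5)

    def test_hand_built_matrix(self):
        # 6 samples, focal sites o1 = {a, b}, o2 = {c}; background z = {e, f}
        ids = ["a", "b", "c", "e", "f", "g"]
        sites = {"a": "o1", "b": "o1", "c": "o2", "e": "z", "f": "z", "g": "z"}
        d = np.zeros((6, 6))
        vals = {("a", "b"): 0.1, ("a", "c"): 0.3, ("b", "c"): 0.5,
                ("a", "e"): 0.8, ("a", "f"): 0.6, ("a", "g"): 1.0,
                ("b", "e"): 0.9, ("b", "f"): 0.7, ("b", "g"): 0.8,
                ("c", "e"): 0.6, ("c", "f"): 0.6, ("c", "g"): 0.9,
                ("e", "f"): 0.2, ("e", "g"): 0.2, ("f", "g"): 0.2}
        idx = {s: i for i, s in enumerate(ids)}
        for (u, v), val in vals.items():
            d[idx[u], idx[v]] = d[idx[v], idx[u]] = val
        ratios = relative_distance_ratio(DistanceMatrix(d, ids=ids), sites, {"o1", "o2"})
        # sample a: to other focal sites = {c} -> 0.3; to z -> (0.8+0.6+1.0)/3
        assert ratios["a"] == pytest.approx(0.3 / (2.4 / 3))
        assert ratios["b"] == pytest.approx(0.5 / (0.9 + 0.7 + 0.8) * 3)
        # own-site samples excluded: c's numerator uses a and b only
        assert ratios["c"] == pytest.approx(((0.3 + 0.5) / 2) / (2.1 / 3))

    def test_missing_counterparts_error(self):
        ids = ["a", "b"]
        d = np.array([[0, 1.0], [1.0, 0]])
        sites = {"a": "o1", "b": "o2"}
        with pytest.raises(ValueError, match="non-focal"):
            relative_distance_ratio(DistanceMatrix(d, ids=ids), sites, {"o1", "o2"})
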