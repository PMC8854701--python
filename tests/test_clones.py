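"""Clone clustering, spatial mapping, sharing, NJ and parsimony."""

import itertools

import numpy as np
import pandas as pd
import pytest

from glandevo.clones import (
    CloneCluster,
    MafMatrix,
    classify_sharing,
    cluster_glands,
    hamming_matrix,
    map_clusters_to_grid,
    nj_tree,
    parsimony_score,
    select_informative_mutations,
)


def _matrix(data, glands=None):
    frame = pd.DataFrame(data).T if isinstance(data, dict) else pd.DataFrame(data)
    if glands is not None:
        frame.columns = glands
    return MafMatrix(values=frame)


class TestInformativeSelection:
    def test_single_gland_site_dropped(self):
        m = _matrix({"s1": [0.5, 0.0, 0.0]}, glands=["a", "b", "c"])
        assert select_informative_mutations(m).values.empty

    def test_two_gland_site_kept(self):
        m = _matrix({"s1": [0.5, 0.5, 0.0]}, glands=["a", "b", "c"])
        out = select_informative_mutations(m)
        assert list(out.values.index) == ["s1"]

    def test_only_one_clonal_gland_dropped(self):
        m = _matrix({"s1": [0.30, 0.12, 0.0]}, glands=["a", "b", "c"])
        assert select_informative_mutations(m).values.empty

    def test_share_maf_supporting_glands_annotated(self):
        m = _matrix({"s1": [0.5, 0.30, 0.12]}, glands=["a", "b", "c"])
        out = select_informative_mutations(m)
        assert int(out.site_meta.loc["s1", "n_supporting"]) == 3

    def test_blood_contaminated_site_excluded(self):
        m = _matrix({"s1": [0.5, 0.5, 0.5]}, glands=["a", "b", "c"])
        blood = pd.Series({"s1": 0.06})
        assert select_informative_mutations(m, blood_maf=blood).values.empty

    def test_no_sites_pass_warns_not_raises(self):
        m = _matrix({"s1": [0.1, 0.1, 0.1]}, glands=["a", "b", "c"])
        with pytest.warns(UserWarning):
            out = select_informative_mutations(m)
        assert out.values.empty


class TestClusterGlands:
    def test_two_disjoint_clones_recovered(self):
        glands = ["a1", "a2", "a3", "b1", "b2"]
        rows = {}
        for i in range(3):
            rows[f"A{i}"] = [0.5, 0.5, 0.5, 0.0, 0.0]
        for i in range(3):
            rows[f"B{i}"] = [0.0, 0.0, 0.0, 0.5, 0.5]
        clusters, _ = cluster_glands(_matrix(rows, glands=glands))
        multi = sorted(
            frozenset(c.members) for c in clusters if c.size >= 2
        )
        assert multi == [frozenset({"a1", "a2", "a3"}), frozenset({"b1", "b2"})]

    def test_identical_columns_single_cluster(self):
        rows = {f"s{i}": [0.5, 0.5, 0.5] for i in range(4)}
        clusters, _ = cluster_glands(_matrix(rows, glands=["a", "b", "c"]))
        assert len(clusters) == 1 and clusters[0].size == 3

    def test_pure_noise_yields_no_multigland_cluster(self):
        rng = np.random.default_rng(0)
        rows = {f"s{i}": rng.uniform(0, 0.09, 4) for i in range(20)}
        clusters, _ = cluster_glands(_matrix(rows, glands=list("abcd")))
        assert all(c.size == 1 for c in clusters)

    def test_defining_mutations_clonal_in_all_members(self):
        glands = ["a", "b", "c"]
        rows = {"s1": [0.5, 0.6, 0.0], "s2": [0.4, 0.5, 0.0],
                "s3": [0.5, 0.1, 0.0]}
        clusters, _ = cluster_glands(_matrix(rows, glands=glands))
        cluster = next(c for c in clusters if c.size >= 2)
        assert set(cluster.defining_mutations) == {"s1", "s2"}


class TestGridMapping:
    def test_footprint_of_five_adjacent_grids(self):
        # lattice laid out so the five grids form a connected cross
        layout = {"3": (0, 1), "11": (1, 1), "12": (1, 2), "14": (2, 0),
                  "15": (2, 1)}
        cluster = CloneCluster("c1", members=("g1", "g2", "g3", "g4", "g5"))
        gland_grid = {f"g{i + 1}": g for i, g in enumerate(layout)}
        [fp] = map_clusters_to_grid([cluster], gland_grid, layout)
        assert len(fp.grids) == 5
        assert fp.contiguous is True

    def test_single_grid_trivially_contiguous(self):
        cluster = CloneCluster("c1", members=("g1", "g2"))
        [fp] = map_clusters_to_grid(
            [cluster], {"g1": "A", "g2": "A"}, {"A": (0, 0)}
        )
        assert fp.grids == {"A"} and fp.contiguous is True

    def test_non_adjacent_grids_not_contiguous(self):
        cluster = CloneCluster("c1", members=("g1", "g2"))
        [fp] = map_clusters_to_grid(
            [cluster], {"g1": "A", "g2": "B"}, {"A": (0, 0), "B": (2, 2)}
        )
        assert fp.contiguous is False

    def test_missing_grid_assignment_warns(self):
        cluster = CloneCluster("c1", members=("g1", "g2"))
        with pytest.warns(UserWarning):
            [fp] = map_clusters_to_grid(
                [cluster], {"g1": "A"}, {"A": (0, 0)}
            )
        assert fp.grids == {"A"}


class TestSharing:
    def test_public_partial_private_labels(self):
        glands = list("abcde")
        rows = {
            "pub": [0.5] * 5,
            "part": [0.5, 0.5, 0.0, 0.0, 0.0],
            "priv": [0.5, 0.0, 0.0, 0.0, 0.0],
        }
        cluster = CloneCluster("c1", members=tuple(glands))
        profile = classify_sharing(cluster, _matrix(rows, glands=glands))
        assert profile.labels == {"pub": "public", "part": "partial",
                                  "priv": "private"}
        assert (profile.mb_pub, profile.mb_ps, profile.mb_priv) == (1, 1, 1)

    def test_partition_property(self, small_cohort):
        from glandevo.io import maf_matrix_from_glands

        glands, clinical, _ = small_cohort
        subject = clinical[0].subject_id
        matrix = maf_matrix_from_glands(glands, subject_id=subject)
        members = tuple(matrix.values.columns)
        cluster = CloneCluster("c1", members=members)
        profile = classify_sharing(cluster, matrix)
        present = (matrix.values >= 0.25).any(axis=1).sum()
        assert profile.total == present == len(profile.labels)

    def test_planted_counts_recovered(self, small_cohort):
        from glandevo.io import maf_matrix_from_glands

        glands, clinical, truth = small_cohort
        subject = clinical[0].subject_id
        matrix = maf_matrix_from_glands(glands, subject_id=subject)
        cluster = CloneCluster("c1", members=tuple(matrix.values.columns))
        profile = classify_sharing(cluster, matrix)
        planted = truth.mutations.query("subject_id == @subject")
        expected = planted.category.value_counts()
        # depth 100: binomial misclassification is negligible but not
        # impossible, so allow a one-count slack
        assert abs(profile.mb_pub - expected.get("public", 0)) <= 1
        assert abs(profile.mb_ps - expected.get("partial", 0)) <= 1
        assert abs(profile.mb_priv - expected.get("private", 0)) <= 1

    def test_requires_two_members(self):
        with pytest.raises(ValueError):
            classify_sharing(
                CloneCluster("c", members=("a",)), _matrix({"s": [0.5]}, ["a"])
            )


class TestHamming:
    def test_basic_distances(self):
        profiles = np.array([[1, 0, 1], [0, 0, 1], [0, 1, 0]])
        D = hamming_matrix(profiles)
        assert D[0, 0] == 0
        assert D[0, 1] == 1
        assert D[0, 2] == 3  # complement vectors
        np.testing.assert_array_equal(D, D.T)

    def test_triangle_inequality(self, rng):
        P = rng.integers(0, 2, size=(6, 40))
        D = hamming_matrix(P)
        for i, j, k in itertools.permutations(range(6), 3):
            assert D[i, j] <= D[i, k] + D[k, j] + 1e-12


def random_additive_matrix(rng, n_taxa):
    """Additive matrix built from an explicit random tree."""
    # represent tree as leaf -> path to root (list of branch lengths)
    paths = {i: [] for i in range(n_taxa)}
    groups = [[i] for i in range(n_taxa)]
    while len(groups) > 1:
        i, j = sorted(rng.choice(len(groups), 2, replace=False))
        gb = groups.pop(j)
        ga = groups.pop(i)
        la, lb = rng.uniform(0.5, 4.0, 2)
        for leaf in ga:
            paths[leaf].append(la)
        for leaf in gb:
            paths[leaf].append(lb)
        groups.append(ga + gb)
    depth = {leaf: sum(p) for leaf, p in paths.items()}
    D = np.zeros((n_taxa, n_taxa))
    for a in range(n_taxa):
        for b in range(a + 1, n_taxa):
            # shared path length from root: compare suffixes
            pa, pb = paths[a][::-1], paths[b][::-1]
            shared = 0.0
            for x, y in zip(pa, pb):
                if x == y:
                    shared += x
                else:
                    break
            D[a, b] = D[b, a] = depth[a] + depth[b] - 2 * shared
    return D


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 4.0], [4.0, 4.0, 0.0]])
        tree = nj_tree(D, ["A", "B", "C"])
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    def test_additive_four_taxon_exact_recovery(self, rng):
        D = random_additive_matrix(rng, 4)
        tree = nj_tree(D, [str(i) for i in range(4)])
        tip_dist = tree.tip_tip_distances()
        for a in range(4):
            for b in range(4):
                assert tip_dist[str(a), str(b)] == pytest.approx(
                    D[a, b], abs=1e-9
                )

    def test_star_tree_zero_internal_branch(self):
        D = np.ones((4, 4)) * 2.0
        np.fill_diagonal(D, 0.0)
        tree = nj_tree(D, list("ABCD"))
        internal = [
            n.length for n in tree.non_tips() if n.length is not None
        ]
        assert all(abs(x) < 1e-12 for x in internal)

    def test_matches_scikit_bio_reference(self, rng):
        # independent route: scikit-bio's own NJ on the same matrix
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        D = random_additive_matrix(rng, 6)
        ids = [str(i) for i in range(6)]
        ours = nj_tree(D, ids).tip_tip_distances()
        theirs = skbio_nj(DistanceMatrix(D, ids)).tip_tip_distances()
        for a in ids:
            for b in ids:
                assert ours[a, b] == pytest.approx(theirs[a, b], abs=1e-9)

    def test_negative_branch_clamped_with_warning(self):
        D = np.array(
            [
                [0.0, 1.0, 8.0, 8.0],
                [1.0, 0.0, 1.5, 8.0],
                [8.0, 1.5, 0.0, 1.0],
                [8.0, 8.0, 1.0, 0.0],
            ]
        )
        with pytest.warns(UserWarning):
            tree = nj_tree(D, list("ABCD"))
        assert all(
            (n.length or 0.0) >= 0.0 for n in tree.traverse() if n.length is not None
        )

    def test_fewer_than_three_taxa_errors(self):
        with pytest.raises(ValueError):
            nj_tree(np.zeros((2, 2)), ["A", "B"])


def brute_force_parsimony(tree, characters):
    """Oracle: minimize changes over all internal 0/1 labelings."""
    internals = [n for n in tree.traverse() if not n.is_tip()]
    leaves = [n for n in tree.tips()]
    n_char = len(next(iter(characters.values())))
    total = 0
    for pos in range(n_char):
        best = np.inf
        for states in itertools.product([0, 1], repeat=len(internals)):
            assign = {id(n): s for n, s in zip(internals, states)}
            for leaf in leaves:
                assign[id(leaf)] = int(characters[leaf.name][pos])
            cost = 0
            for node in tree.traverse():
                for child in node.children:
                    cost += assign[id(node)] != assign[id(child)]
            best = min(best, cost)
        total += int(best)
    return total


class TestParsimony:
    def test_identical_leaves_zero(self):
        D = np.ones((4, 4)) - np.eye(4)
        tree = nj_tree(D, list("ABCD"))
        chars = {name: [1, 0, 1] for name in "ABCD"}
        assert parsimony_score(tree, chars) == 0

    def test_single_divergent_leaf_one_change(self):
        D = np.ones((4, 4)) - np.eye(4)
        tree = nj_tree(D, list("ABCD"))
        chars = {name: [0] for name in "ABC"}
        chars["D"] = [1]
        assert parsimony_score(tree, chars) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        profiles = rng.integers(0, 2, size=(5, 8))
        labels = [f"L{i}" for i in range(5)]
        tree = nj_tree(hamming_matrix(profiles).astype(float), labels)
        chars = {lab: profiles[i] for i, lab in enumerate(labels)}
        assert parsimony_score(tree, chars) == brute_force_parsimony(tree, chars)

    def test_leaf_mismatch_errors(self):
        tree = nj_tree(np.ones((3, 3)) - np.eye(3), list("ABC"))
        with pytest.raises(ValueError):
            parsimony_score(tree, {"A": [0], "B": [1], "X": [0]})
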