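"""Simpson/Jaccard coefficients, Ward clustering, tree cuts, Baker's Gamma."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from chemotax import (
    Dendrogram,
    bakers_gamma,
    build_matrix,
    build_network,
    cut_tree,
    cut_tree_heights,
    distance_matrix,
    dpclus,
    filter_plants,
    jaccard,
    simpson,
    taxon_enrichment,
    ward_cluster,
)
from chemotax.plant_clustering import PlantPartition


def v(*bits):
    return np.array(bits, dtype=np.uint8)


class TestCoefficients:
    def test_simpson_substitution(self):
        # a=1, b=1, c=1 -> 1 / min(2, 2)
        assert simpson(v(1, 1, 0, 0), v(1, 0, 1, 0)) == pytest.approx(0.5)

    def test_simpson_nested_profile_is_one(self):
        assert simpson(v(1, 1, 0, 0), v(1, 1, 1, 0)) == 1.0

    def test_simpson_identical_is_one(self):
        assert simpson(v(0, 1, 1), v(0, 1, 1)) == 1.0

    def test_simpson_all_zero_errors(self):
        with pytest.raises(ValueError):
            simpson(v(0, 0, 0), v(1, 0, 0))

    def test_jaccard_substitution(self):
        assert jaccard(v(1, 1, 0, 0), v(1, 0, 1, 0)) == pytest.approx(1 / 3)

    def test_jaccard_identical_is_one(self):
        assert jaccard(v(1, 0, 1), v(1, 0, 1)) == 1.0

    def test_jaccard_disjoint_is_zero(self):
        assert jaccard(v(1, 1, 0, 0), v(0, 0, 1, 1)) == 0.0

    def test_jaccard_both_zero_errors(self):
        with pytest.raises(ValueError):
            jaccard(v(0, 0), v(0, 0))

    def test_simpson_dominates_jaccard(self, rng):
        for _ in range(200):
            x = (rng.random(30) < 0.4).astype(np.uint8)
            y = (rng.random(30) < 0.4).astype(np.uint8)
            if x.sum() == 0 or y.sum() == 0:
                continue
            assert simpson(x, y) >= jaccard(x, y) - 1e-12

    def test_column_permutation_invariance(self, rng):
        x = (rng.random(40) < 0.5).astype(np.uint8)
        y = (rng.random(40) < 0.5).astype(np.uint8)
        perm = rng.permutation(40)
        assert simpson(x, y) == pytest.approx(simpson(x[perm], y[perm]))
        assert jaccard(x, y) == pytest.approx(jaccard(x[perm], y[perm]))


class TestDistanceMatrix:
    def test_identical_rows_distance_zero(self):
        df = pd.DataFrame([[1, 0, 1], [1, 0, 1]], index=["p", "q"])
        D = distance_matrix(df, "simpson")
        assert D.loc["p", "q"] == 0.0

    def test_disjoint_rows_distance_one(self):
        df = pd.DataFrame([[1, 1, 0, 0], [0, 0, 1, 1]], index=["p", "q"])
        for coeff in ("simpson", "jaccard"):
            assert distance_matrix(df, coeff).loc["p", "q"] == 1.0

    def test_matches_elementwise_recomputation(self, rng):
        X = (rng.random((12, 25)) < 0.4).astype(np.uint8)
        X[X.sum(axis=1) == 0, 0] = 1
        df = pd.DataFrame(X, index=[f"p{i}" for i in range(12)])
        for coeff, fn in (("simpson", simpson), ("jaccard", jaccard)):
            D = distance_matrix(df, coeff)
            for i in range(12):
                for j in range(12):
                    expected = 0.0 if i == j else 1 - fn(X[i], X[j])
                    assert D.iloc[i, j] == pytest.approx(expected)
            assert np.allclose(D, D.T)

    def test_zero_row_errors(self):
        df = pd.DataFrame([[1, 0], [0, 0]], index=["p", "q"])
        with pytest.raises(ValueError, match="all-zero"):
            distance_matrix(df)


def lance_williams_ward(D):
    """Brute-force Ward linkage on raw distances (the ward.D recurrence)."""
    D = {(i, j): D[i][j] for i in range(len(D)) for j in range(len(D)) if i < j}
    sizes = {i: 1 for i in set(itertools.chain(*D))}
    active = sorted(sizes)
    next_id = max(active) + 1
    merges = []
    while len(active) > 1:
        (i, j) = min(
            ((a, b) for a, b in itertools.combinations(active, 2)),
            key=lambda p: (D[p], p),
        )
        h = D[(i, j)]
        merges.append((i, j, h))
        ni, nj = sizes[i], sizes[j]
        for k in active:
            if k in (i, j):
                continue
            dik = D[tuple(sorted((i, k)))]
            djk = D[tuple(sorted((j, k)))]
            nk = sizes[k]
            new = ((ni + nk) * dik + (nj + nk) * djk - nk * h) / (ni + nj + nk)
            D[tuple(sorted((k, next_id)))] = new
        sizes[next_id] = ni + nj
        active = [a for a in active if a not in (i, j)] + [next_id]
        next_id += 1
    return merges


class TestWardCluster:
    def test_first_merge_joins_closest_pair(self):
        D = np.array([[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]])
        t = ward_cluster(D)
        assert {int(t.Z[0, 0]), int(t.Z[0, 1])} == {0, 1}

    def test_single_item_errors(self):
        with pytest.raises(ValueError):
            ward_cluster(np.zeros((1, 1)))

    def test_two_items_single_merge_at_distance(self):
        D = np.array([[0.0, 0.4], [0.4, 0.0]])
        t = ward_cluster(D, dialect="ward.D")
        assert len(t.Z) == 1
        assert t.Z[0, 2] == pytest.approx(0.4)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            ward_cluster(np.array([[0, 0.1], [0.3, 0]]))
        with pytest.raises(ValueError, match="non-negative"):
            ward_cluster(np.array([[0, -0.1], [-0.1, 0]]))
        with pytest.raises(ValueError, match="diagonal"):
            ward_cluster(np.array([[0.2, 0.1], [0.1, 0.2]]))

    def test_matches_lance_williams_oracle(self, rng):
        """Merge order and heights match a brute-force Ward implementation
        using the Lance-Williams update on raw distances."""
        n = 6
        X = rng.random((n, 4))
        A = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                A[i, j] = np.abs(X[i] - X[j]).sum()
        t = ward_cluster(A, dialect="ward.D")
        oracle = lance_williams_ward(A.tolist())
        for stage, (i, j, h) in enumerate(oracle):
            assert {int(t.Z[stage, 0]), int(t.Z[stage, 1])} == {i, j}
            assert t.Z[stage, 2] == pytest.approx(h)

    def test_heights_monotone(self, rng):
        A = np.abs(rng.random((15, 15)))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0)
        for dialect in ("ward.D", "ward.D2"):
            h = ward_cluster(A, dialect=dialect).heights()
            assert (np.diff(h) >= -1e-10).all()


@pytest.fixture
def six_leaf_tree(rng):
    A = np.abs(rng.random((6, 6)))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 0)
    return ward_cluster(pd.DataFrame(A, index=list("abcdef"), columns=list("abcdef")))


class TestCutTree:
    def test_k_equals_n_all_singletons(self, six_leaf_tree):
        part = cut_tree(six_leaf_tree, 6)
        assert part.k == 6

    def test_k_one_single_group(self, six_leaf_tree):
        part = cut_tree(six_leaf_tree, 1)
        assert part.k == 1

    def test_invalid_k(self, six_leaf_tree):
        for k in (0, 7, -1):
            with pytest.raises(ValueError):
                cut_tree(six_leaf_tree, k)

    def test_height_cut_matches_k_cut_at_global_threshold(self, six_leaf_tree):
        h = six_leaf_tree.heights()
        thr = (h[-2] + h[-1]) / 2  # between the last two merges -> 2 groups
        part = cut_tree_heights(six_leaf_tree, thr)
        assert part.groups() == cut_tree(six_leaf_tree, 2).groups()

    def test_subtree_override_refines_one_side(self, six_leaf_tree):
        t = six_leaf_tree
        n = t.n_leaves
        root = n + len(t.Z) - 1
        left = int(t.Z[-1, 0])
        thr = (t.heights()[-2] + t.heights()[-1]) / 2
        base = cut_tree_heights(t, thr)
        refined = cut_tree_heights(t, thr, {left: -1.0})
        # cutting the left root subtree at height -1 explodes it to leaves
        assert refined.k > base.k

    def test_invalid_node_id(self, six_leaf_tree):
        with pytest.raises(ValueError):
            cut_tree_heights(six_leaf_tree, 0.5, {99: 0.1})


def brute_force_gamma(t1: Dendrogram, t2: Dendrogram) -> float:
    """Exhaustive pair enumeration: co-clustering level of every leaf pair
    via k-cuts, then Spearman correlation."""
    def levels(t):
        n = t.n_leaves
        out = {}
        for a, b in itertools.combinations(sorted(t.labels), 2):
            for k in range(n, 0, -1):
                part = cut_tree(t, k)
                if part.assignment[a] == part.assignment[b]:
                    out[(a, b)] = k
                    break
        return out

    l1, l2 = levels(t1), levels(t2)
    pairs = sorted(l1)
    return spearmanr([l1[p] for p in pairs], [l2[p] for p in pairs]).statistic


def chain_tree(labels, heights):
    """Caterpillar dendrogram merging labels left to right."""
    n = len(labels)
    Z = np.array(
        [[0, 1, heights[0], 2]]
        + [[n + s - 1, s + 1, heights[s], s + 2] for s in range(1, n - 1)],
        dtype=float,
    )
    return Dendrogram(Z=Z, labels=list(labels))


class TestBakersGamma:
    def test_identical_tree_scores_one(self, six_leaf_tree):
        assert bakers_gamma(six_leaf_tree, six_leaf_tree) == pytest.approx(1.0)

    def test_symmetric(self, six_leaf_tree, rng):
        other = chain_tree("abcdef", [0.1, 0.2, 0.3, 0.4, 0.5])
        g1 = bakers_gamma(six_leaf_tree, other)
        g2 = bakers_gamma(other, six_leaf_tree)
        assert g1 == pytest.approx(g2)
        assert -1.0 <= g1 <= 1.0

    def test_matches_exhaustive_pair_enumeration(self):
        # caterpillar ((a,b),c),d against a differently shaped 4-leaf tree
        t1 = chain_tree("abcd", [0.1, 0.2, 0.3])
        Z2 = np.array([[2, 3, 0.1, 2], [1, 4, 0.2, 3], [0, 5, 0.3, 4]])
        t2 = Dendrogram(Z=Z2, labels=list("abcd"))  # (a,(b,(c,d)))
        assert bakers_gamma(t1, t2) == pytest.approx(brute_force_gamma(t1, t2))

    def test_newick_and_linkage_agree(self, six_leaf_tree):
        nwk = six_leaf_tree.to_newick()
        assert bakers_gamma(nwk, six_leaf_tree) == pytest.approx(1.0)

    def test_invariant_under_monotone_height_transform(self, six_leaf_tree):
        other = chain_tree("abcdef", [0.1, 0.2, 0.3, 0.4, 0.5])
        stretched = Dendrogram(
            Z=np.column_stack(
                [other.Z[:, :2], other.Z[:, 2] ** 3 * 10 + 1, other.Z[:, 3]]
            ),
            labels=other.labels,
        )
        assert bakers_gamma(six_leaf_tree, other) == pytest.approx(
            bakers_gamma(six_leaf_tree, stretched)
        )

    def test_mismatched_leaf_sets_error(self, six_leaf_tree):
        other = chain_tree("abcdeg", [0.1, 0.2, 0.3, 0.4, 0.5])
        with pytest.raises(ValueError, match="leaf sets"):
            bakers_gamma(six_leaf_tree, other)


class TestTaxonEnrichment:
    def test_same_genus_group_all_co_taxon(self):
        part = PlantPartition({f"p{i}": "P01" for i in range(6)})
        taxonomy = {f"p{i}": ("Citrus", "Rutaceae") for i in range(6)}
        per_group, fraction = taxon_enrichment(part, taxonomy)
        assert per_group["P01"]["co_taxon"] == 6
        assert fraction == 1.0

    def test_all_singleton_groups_zero(self):
        part = PlantPartition({f"p{i}": f"P{i:02d}" for i in range(4)})
        taxonomy = {f"p{i}": ("G", "F") for i in range(4)}
        _, fraction = taxon_enrichment(part, taxonomy)
        assert fraction == 0.0

    def test_missing_taxonomy_names_plant(self):
        part = PlantPartition({"p0": "P01", "p1": "P01"})
        with pytest.raises(ValueError, match="p1"):
            taxon_enrichment(part, {"p0": ("G", "F")})

    def test_planted_taxa_fully_enriched_without_missingness(self, synthetic_clean):
        ds = synthetic_clean
        groups = dpclus(build_network(ds.fingerprints))
        M = build_matrix(filter_plants(ds.relations, 1), groups)
        tree = ward_cluster(distance_matrix(M, "simpson"))
        part = cut_tree(tree, ds.truth["config"]["n_taxa"])
        _, fraction = taxon_enrichment(part, ds.taxonomy)
        assert fraction >= 0.9
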