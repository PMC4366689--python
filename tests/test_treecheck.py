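"""p-distances, neighbor joining, bootstrap support, support categories."""

import numpy as np
import pytest

from barcodiag import (
    DistanceMatrix,
    LabeledAlignment,
    LabeledSequence,
    bootstrap_support,
    classify_support,
    is_monophyletic,
    neighbor_joining,
    p_distance_matrix,
    split_support,
)

from conftest import BROWN


def random_additive_matrix(n, rng):
    """Distances generated on a random binary tree with positive lengths.

    Returns the matrix and the set of nontrivial splits of the generating
    tree (canonicalised as the side not containing taxon 0).
    """
    clusters = [{i: 0.0} for i in range(n)]  # leaf -> distance to cluster root
    D = np.zeros((n, n))
    splits = set()
    full = frozenset(range(n))
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        li, lj = rng.uniform(0.1, 1.0, size=2)
        a, b = clusters[i], clusters[j]
        for u, du in a.items():
            for v, dv in b.items():
                D[u, v] = D[v, u] = du + li + dv + lj
        merged = {u: du + li for u, du in a.items()}
        merged.update({v: dv + lj for v, dv in b.items()})
        if 2 <= len(merged) <= n - 2:
            s = frozenset(merged)
            splits.add(s if 0 not in s else full - s)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return D, splits


def two_cluster_alignment(n_per_cluster=4, n_fixed=20):
    """Two groups separated by many fixed differences (plus a shared tail)."""
    block_a = "A" * n_fixed
    block_b = "T" * n_fixed
    tail = "ACGT" * 5
    # one private site per taxon so no two sequences are identical
    records = []
    for i in range(n_per_cluster):
        seq = list(block_a + tail + "A" * 2 * n_per_cluster)
        seq[n_fixed + len(tail) + i] = "G"
        records.append(LabeledSequence(f"a{i}", "groupA", "".join(seq)))
    for i in range(n_per_cluster):
        seq = list(block_b + tail + "A" * 2 * n_per_cluster)
        seq[n_fixed + len(tail) + n_per_cluster + i] = "G"
        records.append(LabeledSequence(f"b{i}", "groupB", "".join(seq)))
    return LabeledAlignment(records)


class TestPDistance:
    def test_identical_sequences_all_zero(self):
        aln = LabeledAlignment(
            [LabeledSequence(f"s{i}", "X", "ACGTACGT") for i in range(4)]
        )
        dm = p_distance_matrix(aln)
        assert np.allclose(dm.matrix, 0.0)

    def test_focal_pair_distance_zero(self, ursus_alignment):
        focal = LabeledAlignment(list(ursus_alignment.queries))
        extra = LabeledAlignment(
            list(focal) + [ursus_alignment.by_species(BROWN)[0]]
        )
        dm = p_distance_matrix(extra)
        assert dm.matrix[0, 1] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_pairwise_counting(self, seed):
        rng = np.random.default_rng(seed)
        n, L = int(rng.integers(3, 8)), int(rng.integers(10, 30))
        records = [
            LabeledSequence(f"s{i}", "X", "".join(rng.choice(list("ACGTN"), size=L)))
            for i in range(n)
        ]
        aln = LabeledAlignment(records)
        dm = p_distance_matrix(aln)
        for i in range(n):
            for j in range(n):
                comparable = diff = 0
                for a, b in zip(records[i].sequence, records[j].sequence):
                    if a in "ACGT" and b in "ACGT":
                        comparable += 1
                        diff += a != b
                assert dm.matrix[i, j] == pytest.approx(
                    0.0 if i == j else diff / comparable
                )

    def test_pair_without_comparable_sites_rejected(self):
        aln = LabeledAlignment(
            [LabeledSequence("a", "X", "ANN"), LabeledSequence("b", "X", "NAC")]
        )
        with pytest.raises(ValueError, match="comparable"):
            p_distance_matrix(aln)


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_recovers_tree(self):
        # tree: ((A:1,B:2):1,(C:3,D:4)) -> additive distances
        labels = ("A", "B", "C", "D")
        D = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        tree = neighbor_joining(DistanceMatrix(labels, D))
        assert set(tree.splits) == {frozenset({"C", "D"})}
        # branch lengths are exact on additive input: check via dendropy
        import dendropy

        t = dendropy.Tree.get(data=tree.newick, schema="newick")
        pdm = t.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in t.taxon_namespace}
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(D[i, j])

    @pytest.mark.parametrize("seed", range(10))
    def test_recovers_random_additive_topologies(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        D, true_splits = random_additive_matrix(n, rng)
        labels = tuple(f"t{i}" for i in range(n))
        tree = neighbor_joining(DistanceMatrix(labels, D))
        named = {frozenset(labels[i] for i in s) for s in true_splits}
        assert set(tree.splits) == named

    @pytest.mark.parametrize("seed", range(5))
    def test_splits_agree_with_skbio(self, seed):
        import skbio

        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(4, 9))
        D, _ = random_additive_matrix(n, rng)
        labels = tuple(f"t{i}" for i in range(n))
        mine = neighbor_joining(DistanceMatrix(labels, D))
        sk = skbio.tree.nj(skbio.DistanceMatrix(D, ids=labels))
        full = frozenset(labels)
        sk_splits = set()
        for node in sk.non_tips(include_self=False):
            clade = frozenset(t.name for t in node.tips())
            if 2 <= len(clade) <= n - 2:
                sk_splits.add(clade if labels[0] not in clade else full - clade)
        assert set(mine.splits) == sk_splits

    def test_star_matrix_runs(self):
        labels = ("a", "b", "c", "d")
        D = np.ones((4, 4)) - np.eye(4)
        tree = neighbor_joining(DistanceMatrix(labels, D))
        assert tree.newick.endswith(";")

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(("a", "b"), np.zeros((2, 2))))


class TestBootstrap:
    def test_fixed_differences_get_full_support(self):
        aln = two_cluster_alignment()
        tree = bootstrap_support(aln, n_replicates=50, seed=1)
        group_a = frozenset(r.id for r in aln if r.species == "groupA")
        assert split_support(tree, group_a) == 100.0
        assert is_monophyletic(tree, group_a)

    def test_single_replicate_supports_are_all_or_nothing(self):
        aln = two_cluster_alignment()
        tree = bootstrap_support(aln, n_replicates=1, seed=3)
        assert set(tree.splits.values()) <= {0.0, 100.0}

    def test_deterministic_given_seed(self):
        aln = two_cluster_alignment()
        a = bootstrap_support(aln, n_replicates=20, seed=7)
        b = bootstrap_support(aln, n_replicates=20, seed=7)
        assert a.splits == b.splits
        assert a.newick == b.newick

    def test_supports_are_percentages(self, ursus_alignment):
        species_only = LabeledAlignment(
            [r for r in ursus_alignment if not r.is_query]
        )
        tree = bootstrap_support(species_only, n_replicates=20, seed=5)
        assert all(0.0 <= v <= 100.0 for v in tree.splits.values())

    def test_bear_species_split_absent_or_negligible(self, ursus_alignment):
        """A shared haplotype at distance zero defeats reciprocal monophyly."""
        species_only = LabeledAlignment(
            [r for r in ursus_alignment if not r.is_query]
        )
        tree = bootstrap_support(species_only, n_replicates=100, seed=11)
        brown_ids = frozenset(
            r.id for r in species_only if r.species == BROWN
        )
        sup = split_support(tree, brown_ids)
        assert sup is None or classify_support(sup) == "negligible"


class TestClassifySupport:
    @pytest.mark.parametrize(
        ("value", "category"),
        [
            (100, "strong"),
            (75, "strong"),
            (74.9, "moderate"),
            (50.1, "moderate"),
            (50, "negligible"),
            (0, "negligible"),
        ],
    )
    def test_bootstrap_thresholds(self, value, category):
        assert classify_support(value, "bootstrap_pct") == category

    @pytest.mark.parametrize(
        ("value", "category"),
        [
            (1.0, "strong"),
            (0.95, "strong"),
            (0.94, "moderate"),
            (0.90, "moderate"),
            (0.89, "negligible"),
            (0.0, "negligible"),
        ],
    )
    def test_posterior_thresholds(self, value, category):
        assert classify_support(value, "posterior_prob") == category

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_support(101, "bootstrap_pct")
        with pytest.raises(ValueError):
            classify_support(1.5, "posterior_prob")
        with pytest.raises(ValueError):
            classify_support(0.5, "parsimony")


class TestMonophyly:
    def test_cluster_labels_are_monophyletic(self):
        aln = two_cluster_alignment()
        tree = bootstrap_support(aln, n_replicates=5, seed=2)
        group_b = frozenset(r.id for r in aln if r.species == "groupB")
        assert is_monophyletic(tree, group_b)

    def test_mixed_label_set_is_not(self):
        aln = two_cluster_alignment()
        tree = bootstrap_support(aln, n_replicates=5, seed=2)
        mixed = frozenset(["a0", "a1", "b0"])
        assert not is_monophyletic(tree, mixed)

    def test_singletons_are_trivially_monophyletic(self):
        aln = two_cluster_alignment()
        tree = neighbor_joining(p_distance_matrix(aln))
        assert is_monophyletic(tree, frozenset(["a0"]))

    def test_unknown_labels_rejected(self):
        aln = two_cluster_alignment()
        tree = neighbor_joining(p_distance_matrix(aln))
        with pytest.raises(ValueError):
            is_monophyletic(tree, frozenset(["nope"]))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bipartition_enumeration_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        n = int(rng.integers(4, 8))
        D, true_splits = random_additive_matrix(n, rng)
        labels = tuple(f"t{i}" for i in range(n))
        tree = neighbor_joining(DistanceMatrix(labels, D))
        full = frozenset(labels)
        named_splits = {frozenset(labels[i] for i in s) for s in true_splits}
        # every subset of taxa, checked against the generating tree's splits
        from itertools import combinations

        for k in range(1, n):
            for combo in combinations(labels, k):
                s = frozenset(combo)
                expected = (
                    len(s) in (1, n - 1)
                    or s in named_splits
                    or (full - s) in named_splits
                )
                assert is_monophyletic(tree, s) == expected
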