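"""Marker extraction, progressive alignment, distances, NJ, rooting,
bootstrap."""

import math

import dendropy
import numpy as np
import pandas as pd
import pytest

from ptmbgc.mining import MiningConfig
from ptmbgc.phylogeny import (
    Msa,
    bootstrap_support,
    distance_matrix,
    extract_marker,
    nj_tree,
    progressive_align,
    read_newick,
    root_tree,
    write_newick,
)
from ptmbgc.simulate import (
    assemble_genome,
    diverge,
    marker_reference,
    random_protein,
    simulate_tree,
)

from .conftest import make_genome


def _topology(tree: dendropy.Tree) -> frozenset:
    """Unrooted topology as the set of non-trivial splits."""
    leaves = frozenset(
        n.taxon.label for n in tree.leaf_node_iter() if n.taxon is not None
    )
    splits = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(
            n.taxon.label for n in node.leaf_iter() if n.taxon is not None
        )
        if 1 < len(side) < len(leaves) - 1:
            splits.add(frozenset((side, leaves - side)))
    return frozenset(splits)


class TestExtractMarker:
    def test_exact_marker_copy_found(self):
        rpo = marker_reference("rpoB")
        genome = make_genome({"x1": random_protein(3, 200), "rpo": rpo}, "g1")
        gene = extract_marker(genome, rpo, marker="rpoB")
        assert gene is not None and gene.gene_id == "rpo"

    def test_decoy_genome_returns_absent_with_warning(self, caplog):
        genome = make_genome(
            {f"d{i}": random_protein(100 + i, 300) for i in range(5)}, "g2"
        )
        with caplog.at_level("WARNING"):
            gene = extract_marker(genome, marker_reference("rpoB"), marker="rpoB")
        assert gene is None
        assert any("no rpoB marker" in r.message for r in caplog.records)

    def test_paralog_pair_returns_higher_scorer(self):
        rng = np.random.default_rng(71)
        rpo = marker_reference("rpoB")
        close = diverge(rpo, 0.05, rng)
        far = diverge(rpo, 0.3, rng)
        genome = make_genome({"far": far, "close": close}, "g3")
        gene = extract_marker(genome, rpo, marker="rpoB")
        assert gene.gene_id == "close"

    def test_ikaA_threshold_reachable_by_exemplar(self):
        ika = marker_reference("ikaA")
        genome = make_genome({"ika": ika, "x": random_protein(5, 300)}, "g4")
        gene = extract_marker(genome, ika, MiningConfig(), marker="ikaA")
        assert gene is not None and gene.gene_id == "ika"


class TestProgressiveAlign:
    def test_identical_sequences_align_gap_free(self):
        seq = "MKVLWAALLVTFLAGCQA"
        msa = progressive_align([("a", seq), ("b", seq), ("c", seq)])
        assert msa.rows == [seq] * 3

    def test_two_sequences_equal_pairwise_global(self):
        msa = progressive_align([("a", "MKVLWAACQA"), ("b", "MKVLWAA")])
        assert msa.n_seqs == 2
        assert msa.rows[0] == "MKVLWAACQA"
        assert msa.rows[1].replace("-", "") == "MKVLWAA"
        assert msa.rows[1].count("-") == 3

    def test_engineered_insertion_aligned_as_contiguous_gap(self):
        base = "MKVLWAALLVTFLAGCQAMKVLWAALLV"
        with_ins = base[:14] + "GGG" + base[14:]
        msa = progressive_align([("a", base), ("b", with_ins), ("c", base)])
        for label, row in zip(msa.labels, msa.rows):
            if label in ("a", "c"):
                assert "---" in row
                assert row.count("-") == 3
            else:
                assert "-" not in row

    def test_fewer_than_two_sequences_rejected(self):
        with pytest.raises(ValueError):
            progressive_align([("a", "MKVL")])


class TestDistances:
    def test_identical_rows_distance_zero(self):
        msa = Msa(["a", "b"], ["MKVLWAALLV", "MKVLWAALLV"])
        d = distance_matrix(msa)
        assert d.at["a", "b"] == 0.0

    def test_single_difference_closed_form(self):
        msa = Msa(["a", "b"], ["MKVLWAALLV", "MKVLWAALLA"])
        p = distance_matrix(msa, "p_distance").at["a", "b"]
        assert p == pytest.approx(0.1)
        poisson = distance_matrix(msa, "poisson").at["a", "b"]
        assert poisson == pytest.approx(-math.log(0.9), abs=1e-5)

    def test_matrix_symmetric_nonnegative_zero_diagonal(self):
        rng = np.random.default_rng(73)
        rows = [random_protein(rng, 50) for _ in range(4)]
        d = distance_matrix(Msa(list("abcd"), rows)).to_numpy()
        assert np.allclose(d, d.T)
        assert (d >= 0).all()
        assert np.allclose(np.diag(d), 0)

    def test_no_comparable_columns_is_error(self):
        msa = Msa(["a", "b"], ["MK--", "--VL"])
        with pytest.raises(ValueError, match="a.*b|no comparable"):
            distance_matrix(msa)


def _additive_matrix_from_tree(tree: dendropy.Tree) -> pd.DataFrame:
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    data = [
        [
            0.0 if a == b else pdm.distance(
                tree.taxon_namespace.get_taxon(a), tree.taxon_namespace.get_taxon(b)
            )
            for b in labels
        ]
        for a in labels
    ]
    return pd.DataFrame(data, index=labels, columns=labels)


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) gives these pairwise path lengths
        d = pd.DataFrame(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            index=list("ABCD"),
            columns=list("ABCD"),
            dtype=float,
        )
        tree = nj_tree(d)
        leaves = frozenset("ABCD")
        assert frozenset((frozenset("AB"), frozenset("CD"))) in _topology(tree)
        lengths = {
            n.taxon.label: n.edge.length
            for n in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0})

    def test_three_taxa_unique_topology(self):
        d = pd.DataFrame(
            [[0, 2, 3], [2, 0, 5], [3, 5, 0]],
            index=list("abc"), columns=list("abc"), dtype=float,
        )
        tree = nj_tree(d)
        assert len(tree.seed_node.child_nodes()) == 3

    def test_equidistant_taxa_deterministic(self):
        d = pd.DataFrame(
            np.ones((4, 4)) - np.eye(4), index=list("abcd"), columns=list("abcd")
        )
        assert write_newick(nj_tree(d)) == write_newick(nj_tree(d))

    def test_nonsymmetric_matrix_rejected(self):
        d = pd.DataFrame(
            [[0, 1, 2], [1.5, 0, 1], [2, 1, 0]],
            index=list("abc"), columns=list("abc"), dtype=float,
        )
        with pytest.raises(ValueError):
            nj_tree(d)

    def test_random_additive_matrices_recover_topology(self):
        """NJ reconstructs the generating topology from the additive matrix
        of 20 random 6-taxon trees."""
        for seed in range(20):
            true = simulate_tree(6, seed=seed)
            d = _additive_matrix_from_tree(true)
            rebuilt = nj_tree(d)
            assert _topology(rebuilt) == _topology(true), f"seed {seed}"


class TestRooting:
    @pytest.fixture
    def tree(self):
        d = pd.DataFrame(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            index=list("ABCD"), columns=list("ABCD"), dtype=float,
        )
        return nj_tree(d)

    def test_outgroup_is_sister_to_rest(self, tree):
        rooted = root_tree(tree, "D")
        children = rooted.seed_node.child_nodes()
        assert len(children) == 2
        leaf_sets = [
            {n.taxon.label for n in c.leaf_iter() if n.taxon} for c in children
        ]
        assert {"D"} in leaf_sets

    def test_ingroup_splits_unchanged(self, tree):
        rooted = root_tree(tree, "D")
        assert frozenset(
            (frozenset("AB"), frozenset("CD"))
        ) in _topology(rooted)

    def test_unknown_outgroup_raises(self, tree):
        with pytest.raises(ValueError):
            root_tree(tree, "Z")

    def test_rerooting_twice_is_idempotent(self, tree):
        once = root_tree(tree, "D")
        twice = root_tree(once, "D")
        assert write_newick(once) == write_newick(twice)


class TestBootstrap:
    def _structured_msa(self):
        rng = np.random.default_rng(79)
        clade1 = random_protein(rng, 120)
        clade2 = random_protein(rng, 120)
        return Msa(
            ["a1", "a2", "a3", "b1", "b2", "b3"],
            [clade1, clade1, clade1, clade2, clade2, clade2],
        )

    def test_same_seed_gives_identical_supports(self):
        msa = self._structured_msa()
        t1 = bootstrap_support(msa, n_reps=20, seed=5)
        t2 = bootstrap_support(msa, n_reps=20, seed=5)
        assert write_newick(t1) == write_newick(t2)

    def test_single_replicate_supports_are_zero_or_hundred(self):
        msa = self._structured_msa()
        tree = bootstrap_support(msa, n_reps=1, seed=7)
        supports = [
            n.bootstrap_pct
            for n in tree.preorder_node_iter()
            if hasattr(n, "bootstrap_pct")
        ]
        assert supports and all(s in (0.0, 100.0) for s in supports)

    def test_unambiguous_clades_get_full_support(self):
        """Two internally identical, mutually distant clades: the true
        split is supported in 100% of 100 replicates."""
        msa = self._structured_msa()
        tree = bootstrap_support(msa, n_reps=100, seed=11)
        true_split = frozenset(
            (frozenset(["a1", "a2", "a3"]), frozenset(["b1", "b2", "b3"]))
        )
        found = False
        leaves = frozenset(msa.labels)
        for node in tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            side = frozenset(
                n.taxon.label for n in node.leaf_iter() if n.taxon is not None
            )
            if frozenset((side, leaves - side)) == true_split:
                assert node.bootstrap_pct == 100.0
                found = True
        assert found


class TestNewick:
    def test_write_read_write_byte_stable(self):
        tree = simulate_tree(6, seed=3)
        text = write_newick(tree)
        again = write_newick(read_newick(text))
        assert text == again


class TestIndependentOracle:
    def test_nj_agrees_with_scikit_bio_on_perturbed_matrices(self):
        """Topologies match an independent NJ implementation on noisy
        (non-additive) 6-taxon matrices, where the answer is not forced by
        consistency alone."""
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(0)
        for seed in range(8):
            true = simulate_tree(6, seed=900 + seed)
            d = _additive_matrix_from_tree(true)
            noise = rng.uniform(0.0, 0.02, d.shape)
            noise = (noise + noise.T) / 2
            np.fill_diagonal(noise, 0)
            dn = d + noise
            mine = _topology(nj_tree(dn))
            sk = skbio_nj(DistanceMatrix(dn.to_numpy(), ids=list(dn.index)))
            leaves = frozenset(dn.index)
            sk_splits = set()
            for node in sk.non_tips(include_self=False):
                side = frozenset(n.name for n in node.tips())
                if 1 < len(side) < len(leaves) - 1:
                    sk_splits.add(frozenset((side, leaves - side)))
            assert mine == frozenset(sk_splits), f"seed {seed}"
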