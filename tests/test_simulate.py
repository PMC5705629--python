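"""Synthetic-data generator: determinism, scripted events, ground truth."""

import json

import numpy as np
import pytest

from ptmbgc.chemotype import bundled_compounds, match_ion_list
from ptmbgc.families import EnzymeFamily
from ptmbgc.genome_io import parse_genbank
from ptmbgc.mining import mine_genomes
from ptmbgc.phylogeny import write_newick
from ptmbgc.simulate import (
    EventScript,
    ScriptEvent,
    SimConfig,
    assemble_genome,
    branch_ids,
    emit_ground_truth,
    evolve_protein,
    make_reference_bgc,
    simulate_dataset,
    simulate_ion_list,
    simulate_tree,
    synthesize_bgc_variants,
)

from .test_mining import template_sim_genes


class TestSimulateTree:
    def test_two_taxa_is_single_cherry(self):
        tree = simulate_tree(2, seed=1)
        assert len(tree.seed_node.child_nodes()) == 2
        assert all(c.is_leaf() for c in tree.seed_node.child_nodes())

    def test_same_seed_same_newick(self):
        assert write_newick(simulate_tree(6, 42)) == write_newick(simulate_tree(6, 42))

    def test_eight_taxa_has_seven_internal_nodes(self):
        tree = simulate_tree(8, seed=9)
        internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
        leaves = [n for n in tree.leaf_node_iter()]
        assert len(leaves) == 8
        assert len(internals) == 7

    def test_one_taxon_rejected(self):
        with pytest.raises(ValueError):
            simulate_tree(1, seed=0)


class TestEvolveProtein:
    def test_rate_zero_is_identity(self):
        assert evolve_protein("MKVLWAALLV", 1.0, 0.0, 5) == "MKVLWAALLV"

    def test_same_seed_same_output(self):
        seq = "MKVLWAALLVTFLAGCQAMKVL" * 10
        assert evolve_protein(seq, 1.0, 0.1, 7) == evolve_protein(seq, 1.0, 0.1, 7)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            evolve_protein("", 1.0, 0.1, 1)

    def test_substitution_count_is_poisson_with_expected_mean(self):
        """200-aa protein, expected 20 substitution draws: the mean hit
        count over 200 seeded replicates sits within 20 +/- 1."""
        rng = np.random.default_rng(83)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 200))
        diffs = []
        for rep in range(200):
            out = evolve_protein(seq, 1.0, 0.1, 10_000 + rep)
            diffs.append(sum(a != b for a, b in zip(seq, out)))
        observed = float(np.mean(diffs))
        # repeat hits and identity-like swaps make observed diffs sit just
        # below the Poisson draw mean; allow the sampling band around the
        # expectation corrected for double hits: 200*(1-exp(-0.1)) ~ 19.03
        assert 18.0 < observed <= 21.0


class TestSynthesizeBgcVariants:
    @pytest.fixture(scope="class")
    def tree(self):
        return simulate_tree(6, seed=17)

    def test_empty_script_keeps_template_content(self, tree):
        result = synthesize_bgc_variants(
            tree, make_reference_bgc(), EventScript([]), rate=0.02, seed=3
        )
        template_content = sorted(
            {g.family.value for g in template_sim_genes()}
        )
        for leaf, content in result.leaf_content.items():
            assert content == template_content

    def test_scripted_loss_recorded_and_applied(self, tree):
        leaf = sorted(
            n.taxon.label for n in tree.leaf_node_iter()
        )[0]
        script = EventScript([ScriptEvent(leaf, EnzymeFamily.OXR, "loss")])
        result = synthesize_bgc_variants(
            tree, make_reference_bgc(), script, rate=0.02, seed=5
        )
        assert "OXR" not in result.leaf_content[leaf]
        assert [e for e in result.applied_events if e["kind"] == "L"] == [
            {"branch": leaf, "family": "OXR", "kind": "L", "via": "loss"}
        ]

    def test_dh2_duplication_yields_dh3_content(self, tree):
        leaf = sorted(n.taxon.label for n in tree.leaf_node_iter())[1]
        script = EventScript([ScriptEvent(leaf, EnzymeFamily.DH2, "duplicate")])
        result = synthesize_bgc_variants(
            tree, make_reference_bgc(), script, rate=0.02, seed=7
        )
        assert "DH3" in result.leaf_content[leaf]
        # the subfamily classifier confirms the copy on the output
        from ptmbgc.families import classify_enzyme
        from ptmbgc.simulate import make_family_references

        copy = next(
            g for g in result.leaf_genes[leaf] if g.family is EnzymeFamily.DH3
        )
        assert classify_enzyme(copy.protein, make_family_references()) is EnzymeFamily.DH3

    def test_loss_of_absent_family_rejected(self, tree):
        leaf = sorted(n.taxon.label for n in tree.leaf_node_iter())[0]
        script = EventScript([ScriptEvent(leaf, EnzymeFamily.DH3, "loss")])
        with pytest.raises(ValueError, match="absent"):
            synthesize_bgc_variants(
                tree, make_reference_bgc(), script, rate=0.02, seed=9
            )

    def test_unknown_branch_rejected(self, tree):
        script = EventScript([ScriptEvent("zz9", EnzymeFamily.SD, "loss")])
        with pytest.raises(ValueError, match="unknown branch"):
            synthesize_bgc_variants(
                tree, make_reference_bgc(), script, rate=0.02, seed=11
            )


class TestAssembleGenome:
    def test_construction_counts_and_locus(self):
        genes = template_sim_genes()
        genome = assemble_genome(genes, n_decoys=40, insertion_index=20, seed=13,
                                 genome_id="asm")
        all_genes = list(genome.genes())
        assert len(all_genes) == 46
        ids = [g.gene_id for g in all_genes]
        assert ids[20:26] == [f"asm_{g.label}" for g in genes]

    def test_genbank_roundtrip_preserves_content(self, tmp_path):
        path = tmp_path / "asm.gbk"
        genome = assemble_genome(
            template_sim_genes(), 10, 5, seed=15, genome_id="rt", path=path
        )
        back = parse_genbank(path, genome_id="rt")
        assert [(g.gene_id, g.protein) for g in back.genes()] == [
            (g.gene_id, g.protein) for g in genome.genes()
        ]

    def test_mining_recovers_implanted_locus(self):
        genome = assemble_genome(template_sim_genes(), 40, 20, seed=17,
                                 genome_id="e2e")
        calls = mine_genomes([genome], make_reference_bgc())
        assert len(calls) == 1
        assert calls[0].status == "orthologous"
        assert calls[0].neighborhood.anchor.gene_id == "e2e_ref_ikaB"

    def test_invalid_insertion_index_rejected(self):
        with pytest.raises(ValueError):
            assemble_genome(template_sim_genes(), 10, 11, seed=19)


class TestIonSimulation:
    def test_zero_noise_reproduces_nominal_ions(self):
        ions = simulate_ion_list(bundled_compounds(), 0.0, seed=1)
        assert ions == [511.0, 509.0, 493.0, 491.0]

    def test_same_seed_identical(self):
        a = simulate_ion_list(bundled_compounds(), 0.1, seed=21)
        b = simulate_ion_list(bundled_compounds(), 0.1, seed=21)
        assert a == b

    def test_noisy_ions_always_recovered_at_half_dalton_tolerance(self):
        """0.1 Da noise vs 0.5 Da tolerance: all four assignments recovered
        across 100 seeds (a 5-sigma margin)."""
        compounds = bundled_compounds()
        for seed in range(100):
            ions = simulate_ion_list(compounds, 0.1, seed=seed)
            report = match_ion_list(compounds, ions, tolerance=0.5)
            assert len(report.matches) == 4 and not report.unmatched


class TestDatasetAndTruth:
    @pytest.fixture(scope="class")
    def dataset(self, tmp_path_factory):
        out = tmp_path_factory.mktemp("sim")
        cfg = SimConfig(n_taxa=4, seed=23, rate=0.02, n_decoys=12,
                        insertion_index=6)
        return simulate_dataset(cfg, out_dir=out), out

    def test_truth_json_roundtrip_and_content(self, dataset):
        ds, out = dataset
        truth = json.loads((out / "truth.json").read_text())
        assert truth == emit_ground_truth(ds)
        assert set(truth["leaf_content"]) == {"t1", "t2", "t3", "t4"}
        assert truth["compounds"]["1"]["nominal_mz"] == 511

    def test_truth_matrix_equals_scripted_content(self, dataset):
        ds, _ = dataset
        for ev in ds.bgc.applied_events:
            leaf_or_branch = ev["branch"]
            # every scripted default event lands on a pendant branch here
            if ev["kind"] == "L":
                assert ev["family"] not in ds.bgc.leaf_content[leaf_or_branch]
            else:
                assert ev["family"] in ds.bgc.leaf_content[leaf_or_branch]

    def test_two_runs_identical(self, dataset, tmp_path):
        ds, _ = dataset
        cfg = SimConfig(n_taxa=4, seed=23, rate=0.02, n_decoys=12,
                        insertion_index=6)
        again = simulate_dataset(cfg)
        assert emit_ground_truth(again) == emit_ground_truth(ds)

    def test_genomes_contain_rpoB_marker(self, dataset):
        ds, _ = dataset
        for genome in ds.genomes:
            assert any(g.gene_id.endswith("rpoB") for g in genome.genes())
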