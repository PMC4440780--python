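import filecmp
import json

import numpy as np
import pytest

from iscutrace.phylo import reconstruct
from iscutrace.simulate import (
    SimulationConfig,
    SimulationError,
    assign_phyla,
    evolve_presence,
    evolve_sequences,
    pick_clade_node,
    plan_residue_108,
    simulate_corpus,
    simulate_tree,
)
from iscutrace import seeds as seedlib
from iscutrace.profiles import build_profile


@pytest.fixture(scope="module")
def demo():
    cfg = SimulationConfig(n_taxa=40, seed=123)
    genomes, truth, tree = simulate_corpus(cfg)
    return cfg, genomes, truth, tree


class TestSimulateTree:
    def test_leaf_count_and_binary_internals(self):
        tree = simulate_tree(8, seed=5)
        leaves = [nd for nd in tree.leaf_node_iter()]
        internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
        assert len(leaves) == 8
        assert len(internals) == 7
        assert all(len(nd.child_nodes()) == 2 for nd in internals)

    def test_fixed_seed_gives_identical_newick(self):
        a = simulate_tree(12, seed=9).as_string(schema="newick")
        b = simulate_tree(12, seed=9).as_string(schema="newick")
        assert a == b

    def test_too_few_taxa_rejected(self):
        with pytest.raises(SimulationError):
            simulate_tree(2)

    def test_root_split_matches_yule_expectation(self):
        # under a pure-birth process the root split of an n-leaf tree is
        # uniform on {1..n-1}: mean n/2
        sizes = []
        for s in range(200):
            tree = simulate_tree(8, seed=s)
            left = tree.seed_node.child_nodes()[0]
            sizes.append(sum(1 for _ in left.leaf_iter()))
        assert abs(np.mean(sizes) - 4.0) < 0.5


class TestAssignPhyla:
    def test_partition_covers_all_leaves(self):
        tree = simulate_tree(30, seed=3)
        phyla = assign_phyla(tree, 5)
        assert len(phyla) == 30
        assert len(set(phyla.values())) >= 2

    def test_phyla_are_clades(self):
        tree = simulate_tree(30, seed=3)
        phyla = assign_phyla(tree, 5)
        for name in set(phyla.values()):
            members = [t for t in tree.taxon_namespace if phyla[t.label] == name]
            if len(members) == 1:
                continue
            mrca = tree.mrca(taxa=members)
            clade = {nd.taxon.label for nd in mrca.leaf_iter()}
            assert clade == {m.label for m in members}


class TestEvolvePresence:
    def test_no_dependency_violations_across_replicates(self):
        # >= 10,000 leaf draws under active gain/loss dynamics
        tree = simulate_tree(40, seed=77)
        cfg = SimulationConfig(
            n_taxa=40, iscu_loss_rate=0.3, cyay_loss_rate=0.3,
            iscu_gain_rate=0.3, cyay_gain_rate=0.5,
        )
        violations = 0
        for rep in range(260):
            rng = np.random.default_rng(rep)
            leaf_states, _, _ = evolve_presence(tree, cfg, rng)
            for t in leaf_states["cyaY"]:
                if leaf_states["cyaY"][t] and not leaf_states["iscU"][t]:
                    violations += 1
        assert violations == 0

    def test_zero_loss_gain_at_root_fills_every_leaf(self):
        tree = simulate_tree(20, seed=1)
        cfg = SimulationConfig(n_taxa=20)
        leaf_states, node_states, events = evolve_presence(
            tree, cfg, np.random.default_rng(0)
        )
        assert all(leaf_states["iscU"].values())
        assert sum(1 for e in events["iscU"] if e["type"] == "gain") == 1

    def test_forced_scenario_round_trip_with_reconstruction(self):
        # plant a gain on a stem and a forced loss on a nested subclade:
        # Dollo recovers both branches exactly
        tree = simulate_tree(24, seed=42)
        phyla = assign_phyla(tree, 4)
        gain_node = pick_clade_node(tree, 12)
        # the lost clade must be strictly nested (not a whole child of the
        # gain node), so present leaves remain on both sides of the gain
        children = gain_node.child_nodes()
        loss_node = None
        for nd in gain_node.preorder_iter():
            if nd is gain_node or nd.is_leaf() or nd in children:
                continue
            size = sum(1 for _ in nd.leaf_iter())
            lost = {x.taxon.label for x in nd.leaf_iter()}
            sides_ok = all(
                any(l.taxon.label not in lost for l in ch.leaf_iter()) for ch in children
            )
            if 2 <= size <= 6 and sides_ok:
                loss_node = nd
                break
        assert loss_node is not None
        cfg = SimulationConfig(n_taxa=24)
        leaf_states, node_states, events = evolve_presence(
            tree, cfg, np.random.default_rng(0),
            cyay_gain_node=gain_node, forced_losses={"cyaY": [loss_node]},
        )
        rec = reconstruct(tree, leaf_states["cyaY"], mode="dollo")
        from iscutrace.phylo import node_id

        assert rec.gains[0][1] == node_id(gain_node)
        assert len(rec.losses) == 1
        assert rec.losses[0][1] == node_id(loss_node)
        assert rec.cost == 2


class TestEvolveSequences:
    def test_zero_substitution_rate_keeps_consensus(self):
        tree = simulate_tree(10, seed=2)
        profile = build_profile(seedlib.iscu_seed())
        cfg = SimulationConfig(n_taxa=10, subst_rate=0.0)
        seqs = evolve_sequences(tree, profile, cfg, np.random.default_rng(0))
        assert set(seqs.values()) == {profile.consensus}

    def test_constrained_columns_never_change(self):
        tree = simulate_tree(15, seed=4)
        profile = build_profile(seedlib.iscu_seed())
        cfg = SimulationConfig(n_taxa=15, subst_rate=2.0)
        seqs = evolve_sequences(
            tree, profile, cfg, np.random.default_rng(1),
            constrained_refs=seedlib.ISCU_CONSTRAINED_REFS,
        )
        for seq in seqs.values():
            assert seq[98:103] == "LPPVK"
            for ref in seedlib.ISCU_CYS_REFS:
                assert seq[ref - 1] == "C"

    def test_met_clade_forced_at_position_108(self, demo):
        cfg, genomes, truth, tree = demo
        by_taxon = {g.taxon_id: g for g in genomes}
        n_met = 0
        for taxon, aa in truth.residue_108.items():
            locus = next(l for l, lab in truth.labels[taxon].items() if lab == "iscU")
            seq = by_taxon[taxon].gene(locus).protein
            assert seq[107] == aa
            n_met += aa == "M"
        assert n_met > 0
        assert set(truth.residue_108.values()) <= {"M", "I", "L", "V"}

    def test_divergence_increases_with_path_length(self):
        # average pairwise distance correlates positively with patristic
        # distance (Monte-Carlo, averaged over replicates)
        profile = build_profile(seedlib.cyay_seed())
        corrs = []
        for rep in range(5):
            tree = simulate_tree(15, seed=300 + rep)
            cfg = SimulationConfig(n_taxa=15, subst_rate=0.3)
            seqs = evolve_sequences(tree, profile, cfg, np.random.default_rng(rep))
            pdm = tree.phylogenetic_distance_matrix()
            taxa = {t.label: t for t in tree.taxon_namespace}
            xs, ys = [], []
            labels = sorted(seqs)
            for i in range(len(labels)):
                for j in range(i + 1, len(labels)):
                    a, b = seqs[labels[i]], seqs[labels[j]]
                    diff = sum(1 for x, y in zip(a, b) if x != y) / len(a)
                    xs.append(pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]]))
                    ys.append(diff)
            corrs.append(np.corrcoef(xs, ys)[0, 1])
        assert np.mean(corrs) > 0.3


class TestCorpusAssembly:
    def test_same_seed_byte_identical_corpus(self, tmp_path):
        cfg1 = SimulationConfig(n_taxa=12, seed=55)
        cfg2 = SimulationConfig(n_taxa=12, seed=55)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_corpus(cfg1, outdir=d1)
        simulate_corpus(cfg2, outdir=d2)
        for rel in ["genes.tsv", "taxonomy.tsv", "tree.nwk", "truth.json"]:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes(), rel
        fastas1 = sorted(p.name for p in (d1 / "proteomes").glob("*.fasta"))
        fastas2 = sorted(p.name for p in (d2 / "proteomes").glob("*.fasta"))
        assert fastas1 == fastas2
        for name in fastas1:
            assert (d1 / "proteomes" / name).read_bytes() == (
                d2 / "proteomes" / name
            ).read_bytes()

    def test_truth_labels_match_emitted_proteins(self, demo):
        cfg, genomes, truth, tree = demo
        by_taxon = {g.taxon_id: g for g in genomes}
        for taxon, loci in truth.labels.items():
            genome = by_taxon[taxon]
            locus_ids = {g.locus_id for g in genome.genes}
            for locus in loci:
                assert locus in locus_ids

    def test_dependency_invariant_in_truth(self, demo):
        cfg, genomes, truth, tree = demo
        for t in truth.presence["cyaY"]:
            if truth.presence["cyaY"][t]:
                assert truth.presence["iscU"][t]

    def test_full_context_probability_places_isc_neighbors(self, demo):
        cfg, genomes, truth, tree = demo
        from iscutrace.classify import DEFAULT_ISC_GENES

        by_taxon = {g.taxon_id: g for g in genomes}
        for taxon, loci in truth.labels.items():
            for locus, label in loci.items():
                if label != "iscU":
                    continue
                gene = by_taxon[taxon].gene(locus)
                neighbors = [
                    g
                    for g in by_taxon[taxon].genes
                    if g.locus_id != locus
                    and abs(g.order_index - gene.order_index) <= cfg.window
                ]
                assert any(g.annotation_label in DEFAULT_ISC_GENES for g in neighbors)

    def test_hgt_events_are_cross_phylum_and_activated(self, demo):
        cfg, genomes, truth, tree = demo
        assert len(truth.hgt_events) == cfg.n_hgt
        for e in truth.hgt_events:
            assert truth.phyla[e["donor"]] != truth.phyla[e["recipient"]]
            assert truth.presence["cyaY"][e["recipient"]]

    def test_hgt_without_activation_is_an_error(self):
        cfg = SimulationConfig(n_taxa=20, seed=8, hgt_activates=False)
        with pytest.raises(SimulationError):
            simulate_corpus(cfg)

    def test_invalid_residue_state_rejected(self):
        cfg = SimulationConfig(n_taxa=10, residue_108_states=("B",))
        with pytest.raises(SimulationError):
            cfg.validate()
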