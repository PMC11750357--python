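import hashlib
import os
from collections import Counter

import dendropy
import numpy as np
import pytest

from paleofv.io import read_hits, read_tip_metadata
from paleofv.scenarios import (
    ALL_SPECIES, POSITIVE_SPECIES, RHOPT, empty_scenario, two_event_scenario,
)
from paleofv.simulate import (
    ConfigurationError, EventSpec, ScenarioConfig, TreeNoise,
    generate_scenario, plan_layout, simulate_codon_alignment, simulate_gene_tree,
)
from paleofv.trees import TYPE_I, TYPE_II, TYPE_III, UNCLASSIFIED, parse_support


def tree_hash(root):
    h = hashlib.sha256()
    for dirpath, _, files in sorted(os.walk(root)):
        for name in sorted(files):
            h.update(name.encode())
            with open(os.path.join(dirpath, name), "rb") as fh:
                h.update(fh.read())
    return h.hexdigest()


class TestScenarioTruth:
    def test_reference_scenario_counts(self, two_event_dataset):
        truth = two_event_dataset.truth
        assert len(truth.loci) == 153
        assert len({l.species for l in truth.loci}) == 6
        assert {l.species for l in truth.loci} == set(POSITIVE_SPECIES)

    def test_event_gene_sets_and_overlap(self, two_event_dataset):
        events = two_event_dataset.truth.events
        fams = {eid: set(ev["families"]) for eid, ev in events.items()}
        assert sorted(len(f) for f in fams.values()) == [9, 18]
        a, b = fams.values()
        assert len(a & b) == 5

    def test_orphan_loci_count(self, two_event_dataset):
        orphans = [l for l in two_event_dataset.truth.loci if l.event_id is None]
        assert len(orphans) == 3

    def test_true_topology_type_tally(self, two_event_dataset):
        counts = Counter(two_event_dataset.truth.family_types.values())
        assert counts == {TYPE_I: 12, TYPE_II: 3, TYPE_III: 5, UNCLASSIFIED: 5}

    def test_recent_event_pseudogenization(self, two_event_dataset):
        recent = two_event_dataset.truth.event_loci("recent")
        assert len(recent) == 16
        assert sum(l.orf_status == "premature_stop" for l in recent) == 7
        assert all(l.species == RHOPT for l in recent)


class TestFileConsistency:
    def test_every_truth_locus_has_an_exact_coordinate_hit(self, two_event_dataset):
        hits = read_hits(two_event_dataset.viral_hits_tsv)
        hit_keys = {(h.qseqid, h.start, h.end, h.strand) for h in hits}
        for locus in two_event_dataset.truth.loci:
            assert (locus.scaffold, locus.start, locus.end, locus.strand) in hit_keys

    def test_host_only_scaffolds_carry_no_passing_hits(self, two_event_dataset):
        eve_scaffolds = {l.scaffold for l in two_event_dataset.truth.loci}
        for h in read_hits(two_event_dataset.viral_hits_tsv):
            if h.qseqid not in eve_scaffolds:
                assert h.evalue > 1e-3  # decoys only

    def test_tip_metadata_covers_every_truth_tip(self, two_event_dataset):
        meta = read_tip_metadata(two_event_dataset.tip_metadata_tsv)
        for locus in two_event_dataset.truth.loci:
            assert meta[locus.tip].kind == "wasp"
            assert meta[locus.tip].species == locus.species

    def test_alignment_contains_planted_premature_stops(self, two_event_dataset):
        stops = {"TAA", "TAG", "TGA"}
        from Bio import SeqIO

        for fam in ("orf105", "integrase"):
            path = two_event_dataset.alignment_dir / f"{fam}.fasta"
            pseudo_tips = {
                l.tip for l in two_event_dataset.truth.loci
                if l.family == fam and l.orf_status == "premature_stop"
            }
            assert pseudo_tips
            for rec in SeqIO.parse(str(path), "fasta"):
                seq = str(rec.seq)
                codons = {seq[i:i + 3] for i in range(0, len(seq), 3)}
                if rec.id in pseudo_tips:
                    assert codons & stops
                else:
                    assert not (codons & stops)


class TestDeterminism:
    def test_same_seed_is_byte_identical(self, tmp_path):
        cfg = two_event_scenario(seed=11)
        generate_scenario(cfg, tmp_path / "a")
        generate_scenario(cfg, tmp_path / "b")
        assert tree_hash(tmp_path / "a") == tree_hash(tmp_path / "b")

    def test_different_seeds_differ(self, tmp_path):
        generate_scenario(two_event_scenario(seed=11), tmp_path / "a")
        generate_scenario(two_event_scenario(seed=12), tmp_path / "c")
        assert tree_hash(tmp_path / "a") != tree_hash(tmp_path / "c")


class TestEmptyScenario:
    def test_no_events_means_no_hits_and_empty_truth(self, tmp_path):
        ds = generate_scenario(empty_scenario(), tmp_path / "empty")
        assert ds.truth.loci == []
        assert read_hits(ds.viral_hits_tsv) == []


class TestGeneTreeSimulation:
    def test_single_event_family_shows_ancestral_pattern(self):
        cfg = two_event_scenario()
        rng = np.random.default_rng(0)
        newick, _ = simulate_gene_tree("dnapol", cfg, rng)
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True,
                                 suppress_internal_node_taxa=True)
        tree.is_rooted = True
        labels = {l.taxon.label for l in tree.leaf_node_iter()}
        wasp = {l for l in labels if "|" in l}
        assert wasp and all(l.split("|")[0] in POSITIVE_SPECIES for l in wasp)
        # the wasp tips form one clade whose sister is the LhFV tip
        mrca = tree.mrca(taxa=[t for t in tree.taxon_namespace if t.label in wasp])
        assert {l.taxon.label for l in mrca.leaf_iter()} == wasp
        sister = [
            l.taxon.label
            for c in mrca.parent_node.child_nodes() if c is not mrca
            for l in c.leaf_iter()
        ]
        assert sister == ["LhFV"]

    def test_shared_family_has_two_attachments(self):
        cfg = two_event_scenario()
        rng = np.random.default_rng(0)
        newick, _ = simulate_gene_tree("pif-3", cfg, rng)
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True,
                                 suppress_internal_node_taxa=True)
        tree.is_rooted = True
        wasp = [l.taxon.label for l in tree.leaf_node_iter() if "|" in l.taxon.label]
        rhopt = [l for l in wasp if l.startswith(RHOPT)]
        others = [l for l in wasp if not l.startswith(RHOPT)]
        assert rhopt and others
        # recent copies attach next to LbFV, not inside the ancestral clade
        mrca = tree.mrca(taxa=[t for t in tree.taxon_namespace if t.label in others])
        ancestral_tips = {l.taxon.label for l in mrca.leaf_iter()}
        assert not (set(rhopt) & ancestral_tips)

    def test_support_floor_yields_parsable_max_supports(self):
        cfg = two_event_scenario()
        cfg = ScenarioConfig(
            **{**cfg.__dict__, "tree_noise": TreeNoise(
                true_boot=(100.0, 100.0), low_boot=(100.0, 100.0),
                true_alrt=(100.0, 100.0), low_alrt=(100.0, 100.0),
            )}
        )
        newick, _ = simulate_gene_tree("dnapol", cfg, np.random.default_rng(0))
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True,
                                 suppress_internal_node_taxa=True)
        supports = [parse_support(n.label) for n in tree.preorder_internal_node_iter()
                    if n.label]
        assert supports and all(s == 100.0 for s in supports)

    def test_unknown_family_is_an_error(self):
        with pytest.raises(ValueError, match="no planned copies"):
            simulate_gene_tree("not-a-family", two_event_scenario(),
                               np.random.default_rng(0))


class TestCodonAlignmentSimulation:
    def test_zero_branch_lengths_give_identical_sequences(self):
        guide = dendropy.Tree.get(data="(a:0.0,b:0.0,c:0.0);", schema="newick")
        seqs = simulate_codon_alignment(guide, omega=0.5, n_codons=60, seed=3)
        assert len(set(seqs.values())) == 1

    def test_alignment_length_and_no_stops(self):
        guide = dendropy.Tree.get(data="(a:0.3,b:0.3);", schema="newick")
        seqs = simulate_codon_alignment(guide, omega=1.0, n_codons=80, seed=3)
        stops = {"TAA", "TAG", "TGA"}
        for seq in seqs.values():
            assert len(seq) == 240
            assert not any(seq[i:i + 3] in stops for i in range(0, 240, 3))

    def test_preconditions(self):
        guide = dendropy.Tree.get(data="(a:0.1,b:0.1);", schema="newick")
        with pytest.raises(ValueError):
            simulate_codon_alignment(guide, omega=0.5, n_codons=10, seed=0)
        with pytest.raises(ValueError):
            simulate_codon_alignment(guide, omega=-1.0, n_codons=60, seed=0)


class TestConfigValidation:
    def test_unknown_donor_lineage_names_the_field(self):
        cfg = two_event_scenario()
        bad_event = EventSpec(
            event_id="x", donor_lineage="no-such-lineage",
            recipient_species=(RHOPT,), gene_families=("dnapol",),
        )
        bad = ScenarioConfig(**{**cfg.__dict__, "events": (bad_event,)})
        with pytest.raises(ConfigurationError, match="lineage"):
            bad.validate()

    def test_family_missing_from_donor_repertoire(self):
        cfg = two_event_scenario()
        bad_event = EventSpec(
            event_id="x", donor_lineage="LhFV-like",
            recipient_species=(RHOPT,), gene_families=("made-up-gene",),
        )
        bad = ScenarioConfig(**{**cfg.__dict__, "events": (bad_event,)})
        with pytest.raises(ConfigurationError, match="repertoire"):
            bad.validate()

    def test_colocation_groups_must_partition_copies(self):
        cfg = two_event_scenario()
        ev = cfg.events[1]
        broken = EventSpec(**{**ev.__dict__, "colocation_groups": (
            (RHOPT, (("orf10",),)),
        )})
        bad = ScenarioConfig(**{**cfg.__dict__, "events": (cfg.events[0], broken)})
        with pytest.raises(ConfigurationError, match="partition"):
            bad.validate()

    def test_layout_copy_indices_follow_placement_order(self):
        layout = plan_layout(two_event_scenario())
        seen: dict[tuple, int] = {}
        for sp in ALL_SPECIES:
            for group in layout[sp]:
                for locus in group:
                    key = (locus.species, locus.family)
                    assert locus.copy == seen.get(key, 0) + 1
                    seen[key] = locus.copy
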