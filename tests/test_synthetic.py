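"""The synthetic-data generators: determinism, contracts, planted truth."""

from __future__ import annotations

import numpy as np
import pytest

import ligperox as lp
from ligperox.genes import introns_from_structure
from ligperox.synthetic import (INTRON_PRESETS, generate_family,
                                generate_gene_structures, generate_genome_layout,
                                generate_sequences, generate_species_table)


class TestGenerateFamily:
    def test_consensus_lengths_match_request(self):
        m = generate_family(n_subclasses=2, length=350, seed=1)
        assert all(len(sc.consensus) == 350 for sc in m.subclasses)

    def test_same_seed_reproduces_identical_model(self):
        a = generate_family(n_subclasses=9, length=350, seed=1)
        b = generate_family(n_subclasses=9, length=350, seed=1)
        assert a.reference_sequence == b.reference_sequence
        assert [s.consensus for s in a.subclasses] == [s.consensus for s in b.subclasses]
        assert a.family_columns == b.family_columns
        assert [s.intron_pattern for s in a.subclasses] == [
            s.intron_pattern for s in b.subclasses]

    def test_vp_consensus_carries_triad_and_trp(self):
        m = generate_family(n_subclasses=9, length=350, seed=7)
        vp = m.subclass("VP").consensus
        p1, p2, p3 = m.anchors.mn_site
        assert (vp[p1 - 1], vp[p2 - 1], vp[p3 - 1]) == ("E", "E", "D")
        assert vp[m.anchors.catalytic_trp - 1] == "W"
        lip = m.subclass("LiP").consensus
        assert lip[m.anchors.catalytic_trp - 1] == "W"
        assert lip[p1 - 1] not in "ED"

    def test_length_below_anchor_span_names_offending_anchor(self):
        with pytest.raises(ValueError, match="cys_sites position 317"):
            generate_family(n_subclasses=2, length=300, seed=1)

    def test_family_columns_identical_across_subclasses(self):
        m = generate_family(n_subclasses=5, seed=2)
        for col in m.family_columns:
            chars = {sc.consensus[col - 1] for sc in m.subclasses}
            assert chars == {m.reference_sequence[col - 1]}


class TestGenerateSequences:
    def test_zero_substitution_rate_returns_consensus(self, family_model):
        recs, truth = generate_sequences(family_model, n_per_class=2, sub_rate=0.0, seed=1)
        for rid, seq in recs.items():
            label = truth.sequence_labels[rid]["subclass"]
            assert seq == family_model.subclass(label).consensus

    def test_record_count_and_truth_completeness(self, sequence_batch):
        records, truth = sequence_batch
        assert len(records) == 9 * 20
        assert set(truth.sequence_labels) == set(records)

    def test_mutated_site_count_is_binomial(self, family_model):
        """Observed substitutions ~ Binomial(non-anchor sites, sub_rate)."""
        rate = 0.15
        recs, truth = generate_sequences(family_model, n_per_class=20, sub_rate=rate, seed=33)
        n_free = 350 - len(set(family_model.anchors.all_positions()))
        diffs = 0
        for rid, seq in recs.items():
            cons = family_model.subclass(truth.sequence_labels[rid]["subclass"]).consensus
            diffs += sum(a != b for a, b in zip(seq, cons))
        n_trials = len(recs) * n_free
        mean = n_trials * rate
        sd = np.sqrt(n_trials * rate * (1 - rate))
        assert abs(diffs - mean) <= 3 * sd

    def test_anchor_states_always_preserved(self, family_model, sequence_batch):
        records, truth = sequence_batch
        for rid, seq in records.items():
            cons = family_model.subclass(truth.sequence_labels[rid]["subclass"]).consensus
            for p in family_model.anchors.all_positions():
                assert seq[p - 1] == cons[p - 1]

    def test_indel_mode_changes_lengths_but_respects_neighborhoods(self, family_model):
        recs, truth = generate_sequences(
            family_model, n_per_class=20, sub_rate=0.1, seed=4, indels=True)
        lengths = {len(s) for s in recs.values()}
        assert len(lengths) > 1  # some records gained or lost residues
        assert set(truth.sequence_labels) == set(recs)

    def test_byte_identical_under_same_seed(self, family_model):
        a, _ = generate_sequences(family_model, n_per_class=3, sub_rate=0.2, seed=9, indels=True)
        b, _ = generate_sequences(family_model, n_per_class=3, sub_rate=0.2, seed=9, indels=True)
        assert a == b


class TestGenerateGeneStructures:
    def test_no_introns_gives_single_exon_genes(self, family_model):
        recs, truth = generate_sequences(family_model, n_per_class=2, sub_rate=0.0, seed=1)
        labels = {k: v["subclass"] for k, v in truth.sequence_labels.items()}
        structs, _ = generate_gene_structures(
            recs, family_model, labels, preset=None, mean_introns=0.0, carriage=0.0, seed=2)
        assert all(len(g.exons) == 1 for g in structs)
        assert all(g.cds_length == 3 * len(recs[g.protein_id]) + 3 for g in structs)

    def test_basidiomycete_preset_statistics(self, family_model):
        """~8 introns of ~54 nt on average across 200 genes, within 10%."""
        recs, truth = generate_sequences(family_model, n_per_class=23, sub_rate=0.0, seed=3)
        labels = {k: v["subclass"] for k, v in truth.sequence_labels.items()}
        structs, _ = generate_gene_structures(
            recs, family_model, labels, preset="basidiomycete", seed=4)
        counts, sizes = [], []
        for g in structs:
            ips = introns_from_structure(g)
            counts.append(len(ips))
            sizes.extend(ip.length for ip in ips)
        mean_n, mean_size = INTRON_PRESETS["basidiomycete"]
        assert len(structs) >= 200
        assert abs(np.mean(counts) - mean_n) <= 0.1 * mean_n
        assert abs(np.mean(sizes) - mean_size) <= 0.1 * mean_size

    def test_ascomycete_preset_statistics(self, family_model):
        recs, truth = generate_sequences(family_model, n_per_class=23, sub_rate=0.0, seed=5)
        labels = {k: v["subclass"] for k, v in truth.sequence_labels.items()}
        structs, _ = generate_gene_structures(
            recs, family_model, labels, preset="ascomycete", seed=6)
        counts, sizes = [], []
        for g in structs:
            ips = introns_from_structure(g)
            counts.append(len(ips))
            sizes.extend(ip.length for ip in ips)
        assert abs(np.mean(counts) - 2.0) <= 0.2
        assert abs(np.mean(sizes) - 74.0) <= 7.4

    def test_planted_cintron_carriage_read_back(self, family_model):
        """A pattern position at carriage 0.6 appears in ~60% of class genes."""
        recs, truth = generate_sequences(family_model, n_per_class=100, sub_rate=0.0, seed=7)
        labels = {k: v["subclass"] for k, v in truth.sequence_labels.items()}
        structs, gtruth = generate_gene_structures(
            recs, family_model, labels, preset=None, mean_introns=0.0,
            carriage=0.6, seed=8)
        target = family_model.subclass("MnP").intron_pattern[0]
        mnp_genes = [g for g in structs if labels[g.protein_id] == "MnP"]
        carried = sum(
            1 for g in mnp_genes
            if any((ip.codon, ip.phase) == target for ip in introns_from_structure(g))
        )
        sd = np.sqrt(100 * 0.6 * 0.4)
        assert abs(carried - 60) <= 3 * sd

    def test_truth_lists_every_gene_exactly_once(self, family_model):
        recs, truth = generate_sequences(family_model, n_per_class=3, sub_rate=0.0, seed=1)
        labels = {k: v["subclass"] for k, v in truth.sequence_labels.items()}
        structs, gtruth = generate_gene_structures(recs, family_model, labels, seed=2)
        assert set(gtruth.gene_introns) == {g.gene_id for g in structs}
        for g in structs:
            got = [(ip.codon, ip.phase, ip.length) for ip in introns_from_structure(g)]
            assert got == gtruth.gene_introns[g.gene_id]


class TestGenomeLayout:
    @pytest.fixture()
    def layout(self, family_model):
        recs, truth = generate_sequences(family_model, n_per_class=2, sub_rate=0.05, seed=1)
        labels = {k: v["subclass"] for k, v in truth.sequence_labels.items()}
        structs, _ = generate_gene_structures(recs, family_model, labels, seed=2)
        scenario = [("TD", "MnP_000"), ("TD", "LiP_000"), ("TD", "VP_000"),
                    ("SD", "CIIBA_000"), ("SD", "CIIBB_000"), ("WGD", "CIIBC_000")]
        return generate_genome_layout(recs, structs, family_model, scenario, seed=3)

    def test_tandem_copies_are_consecutive(self, layout):
        _, loci, _, truth = layout
        for ev in truth.duplication_events:
            if ev.type == "TD":
                la, lb = loci[ev.gene_a], loci[ev.gene_b]
                assert la.scaffold == lb.scaffold
                assert abs(la.rank - lb.rank) == 1

    def test_segmental_copies_have_intervening_genes(self, layout):
        _, loci, _, truth = layout
        for ev in truth.duplication_events:
            if ev.type == "SD":
                la, lb = loci[ev.gene_a], loci[ev.gene_b]
                assert la.scaffold == lb.scaffold
                assert abs(la.rank - lb.rank) > 1

    def test_wgd_copies_on_distinct_scaffolds(self, layout):
        _, loci, _, truth = layout
        for ev in truth.duplication_events:
            if ev.type == "WGD":
                assert loci[ev.gene_a].scaffold != loci[ev.gene_b].scaffold

    def test_truth_lists_exactly_six_events(self, layout):
        _, _, _, truth = layout
        types = sorted(ev.type for ev in truth.duplication_events)
        assert types == ["SD", "SD", "TD", "TD", "TD", "WGD"]

    def test_unknown_gene_directive_rejected(self, family_model):
        recs, truth = generate_sequences(family_model, n_per_class=1, sub_rate=0.0, seed=1)
        labels = {k: v["subclass"] for k, v in truth.sequence_labels.items()}
        structs, _ = generate_gene_structures(recs, family_model, labels, seed=2)
        with pytest.raises(ValueError, match="nonexistent"):
            generate_genome_layout(recs, structs, family_model,
                                   [("TD", "nonexistent")], seed=3)


class TestSpeciesTable:
    def test_zero_violation_rate_satisfies_rule_everywhere(self):
        df, _ = generate_species_table(100, violation_rate=0.0, seed=1)
        flags, frac = lp.ccp_rule_check(df)
        assert frac == 1.0

    def test_violation_fraction_within_binomial_noise(self):
        df, truth = generate_species_table(200, violation_rate=0.1, seed=2)
        _, frac = lp.ccp_rule_check(df)
        sd = np.sqrt(0.1 * 0.9 / 200)
        assert abs((1 - frac) - 0.1) <= 3 * sd
        assert set(truth.species_consistency) == set(df["species"])

    def test_full_association_sends_cii_species_to_lignin_codes(self):
        df, _ = generate_species_table(150, violation_rate=0.0, seed=3, association=1.0)
        lignin = {"NPP", "HPP", "WR"}
        assert set(df.loc[df.total_cii > 0, "trophism"]) <= lignin
        assert set(df.loc[df.total_cii == 0, "trophism"]).isdisjoint(lignin)

    def test_deterministic_under_seed(self):
        a, _ = generate_species_table(50, seed=4)
        b, _ = generate_species_table(50, seed=4)
        assert a.equals(b)
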