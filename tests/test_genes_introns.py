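"""Gene structures, intron coordinates, cintron grouping and conservation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ligperox.cintrons import (Cintron, class_specificity_report, conservation_rates,
                               find_cintrons, map_intron_to_alignment)
from ligperox.genes import (GeneStructure, IntronPosition, exons_from_introns,
                            introns_from_structure, read_gff3, write_gff3)
from ligperox.msa import MultipleAlignment


class TestIntronExtraction:
    def test_single_exon_gene_has_no_introns(self):
        g = GeneStructure("g", "s", "+", [(1, 303)], "p")
        assert introns_from_structure(g) == []

    def test_phase0_junction(self):
        g = GeneStructure("g", "s", "+", [(1, 300), (361, 510)], "p")
        (ip,) = introns_from_structure(g)
        assert (ip.codon, ip.phase, ip.length) == (100, 0, 60)

    def test_phase1_junction(self):
        g = GeneStructure("g", "s", "+", [(1, 301), (361, 509)], "p")
        (ip,) = introns_from_structure(g)
        assert (ip.codon, ip.phase) == (101, 1)

    def test_cds_not_divisible_by_three_names_gene(self):
        with pytest.raises(ValueError, match="gene broken"):
            GeneStructure("broken", "s", "+", [(1, 100)], "p")

    @pytest.mark.parametrize("strand", ["+", "-"])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_round_trip_recovers_planted_introns(self, strand, seed):
        """Writer -> extractor round trip is exact, on both strands."""
        rng = np.random.default_rng(seed)
        L = int(rng.integers(80, 200))
        n_introns = int(rng.integers(0, 6))
        codons = rng.choice(np.arange(2, L), size=n_introns, replace=False)
        triples = sorted(
            (int(c), int(rng.integers(0, 3)), int(rng.integers(25, 90)))
            for c in codons
        )
        exons = exons_from_introns(L, triples, scaffold_start=501, strand=strand)
        g = GeneStructure("g", "s", strand, exons, "p")
        got = [(ip.codon, ip.phase, ip.length) for ip in introns_from_structure(g)]
        assert got == triples

    @settings(max_examples=60, derandomize=True)
    @given(
        L=st.integers(40, 250),
        strand=st.sampled_from("+-"),
        start=st.integers(1, 10_000),
        introns=st.lists(
            st.tuples(st.integers(2, 39), st.integers(0, 2), st.integers(20, 120)),
            max_size=5, unique_by=lambda t: t[0]),
    )
    def test_round_trip_property(self, L, strand, start, introns):
        """Any valid intron layout survives the writer -> extractor round trip."""
        triples = sorted(introns)
        exons = exons_from_introns(L, triples, start, strand)
        g = GeneStructure("g", "s", strand, exons, "p")
        assert [(ip.codon, ip.phase, ip.length) for ip in introns_from_structure(g)] == triples
        assert g.protein_length == L

    def test_strand_symmetry(self):
        """Mirrored reverse-strand coordinates give identical intron positions."""
        triples = [(30, 2, 50), (77, 0, 61)]
        plus = GeneStructure("g+", "s", "+", exons_from_introns(100, triples, 1, "+"), "p")
        minus = GeneStructure("g-", "s", "-", exons_from_introns(100, triples, 1, "-"), "p")
        key = lambda g: [(ip.codon, ip.phase, ip.length) for ip in introns_from_structure(g)]
        assert key(plus) == key(minus)

    def test_gff3_round_trip(self, tmp_path):
        triples = [(10, 1, 45), (50, 0, 52)]
        genes = [
            GeneStructure("gA", "scaf1", "+", exons_from_introns(90, triples, 11, "+"), "pA"),
            GeneStructure("gB", "scaf2", "-", exons_from_introns(70, [(33, 2, 61)], 5, "-"), "pB"),
        ]
        path = tmp_path / "x.gff3"
        write_gff3(genes, path)
        back = read_gff3(path)
        assert [(g.gene_id, g.scaffold, g.strand, g.exons, g.protein_id) for g in back] == [
            (g.gene_id, g.scaffold, g.strand, g.exons, g.protein_id) for g in genes
        ]


class TestMapIntronToAlignment:
    def test_ungapped_row_is_identity(self):
        ip = IntronPosition("g", 100, 0)
        assert map_intron_to_alignment(ip, "A" * 150) == 100

    def test_gaps_before_position_shift_column(self):
        row = "A" * 50 + "-" * 7 + "A" * 100
        assert map_intron_to_alignment(IntronPosition("g", 100, 1), row) == 107

    def test_codon_beyond_ungapped_length_rejected(self):
        with pytest.raises(ValueError, match="beyond ungapped row length"):
            map_intron_to_alignment(IntronPosition("g", 500, 0), "A" * 400)


def _gene_with_introns(gid: str, L: int, triples) -> GeneStructure:
    exons = exons_from_introns(L, triples, 1, "+")
    return GeneStructure(gid, "s", "+", exons, gid)


class TestFindCintrons:
    def test_shared_position_groups_into_one_cintron(self):
        genes = [_gene_with_introns(g, 200, [(150, 0, 50)]) for g in ("g1", "g2")]
        aln = MultipleAlignment({g.gene_id: "A" * 200 for g in genes})
        (ci,) = find_cintrons(genes, aln)
        assert (ci.column, ci.phase, ci.members) == (150, 0, ["g1", "g2"])

    def test_phase_is_part_of_cintron_identity(self):
        genes = [
            _gene_with_introns("g1", 200, [(150, 0, 50)]),
            _gene_with_introns("g2", 200, [(150, 1, 50)]),
        ]
        aln = MultipleAlignment({"g1": "A" * 200, "g2": "A" * 200})
        cints = find_cintrons(genes, aln)
        assert [(c.column, c.phase) for c in cints] == [(150, 0), (150, 1)]

    def test_gene_without_alignment_row_rejected(self):
        genes = [_gene_with_introns("g1", 200, [])]
        aln = MultipleAlignment({"x": "A" * 200, "y": "A" * 200})
        with pytest.raises(ValueError, match="no alignment row"):
            find_cintrons(genes, aln)

    def test_matches_brute_force_grouping(self):
        """Grouping equals an independent all-pairs comparison of (column, phase)."""
        rng = np.random.default_rng(8)
        genes, rows = [], {}
        for i in range(50):
            L = 150
            n = int(rng.integers(0, 5))
            codons = rng.choice(np.arange(2, 120), size=n, replace=False)
            triples = sorted((int(c), int(rng.integers(0, 3)), 40) for c in codons)
            genes.append(_gene_with_introns(f"g{i}", L, triples))
            rows[f"g{i}"] = "A" * L
        aln = MultipleAlignment(rows)
        cints = find_cintrons(genes, aln)
        # brute force: collect every (gene, column, phase), group by dict
        expected: dict[tuple[int, int], list[str]] = {}
        for g in genes:
            for ip in introns_from_structure(g):
                col = map_intron_to_alignment(ip, rows[g.gene_id])
                expected.setdefault((col, ip.phase), []).append(g.gene_id)
        assert {(c.column, c.phase): c.members for c in cints} == {
            k: sorted(v) for k, v in expected.items()
        }


class TestConservationRates:
    def _make(self, n_with: int, n_class: int = 10):
        genes = []
        for i in range(n_class):
            triples = [(50, 0, 40)] if i < n_with else []
            genes.append(_gene_with_introns(f"g{i}", 100, triples))
        aln = MultipleAlignment({g.gene_id: "A" * 100 for g in genes})
        cints = find_cintrons(genes, aln)
        labels = {f"g{i}": "X" for i in range(n_class)}
        return conservation_rates(cints, labels)

    def test_rate_above_half_is_conserved(self):
        (ci,) = self._make(6)
        assert ci.rates["X"] == pytest.approx(0.6) and ci.conserved

    def test_rate_exactly_half_is_not_conserved(self):
        (ci,) = self._make(5)
        assert ci.rates["X"] == pytest.approx(0.5) and not ci.conserved

    def test_rate_below_half_is_not_conserved(self):
        (ci,) = self._make(3)
        assert not ci.conserved

    def test_universal_cintron_flagged(self):
        genes = [_gene_with_introns(f"a{i}", 100, [(50, 0, 40)]) for i in range(4)]
        genes += [_gene_with_introns(f"b{i}", 100, [(50, 0, 40)]) for i in range(4)]
        aln = MultipleAlignment({g.gene_id: "A" * 100 for g in genes})
        labels = {f"a{i}": "A" for i in range(4)} | {f"b{i}": "B" for i in range(4)}
        (ci,) = conservation_rates(find_cintrons(genes, aln), labels)
        assert ci.conserved and ci.universal

    def test_rates_invariant_to_gene_order(self):
        genes = [_gene_with_introns(f"g{i}", 100, [(50, 0, 40)] if i % 2 else [])
                 for i in range(10)]
        aln = MultipleAlignment({g.gene_id: "A" * 100 for g in genes})
        labels = {g.gene_id: "X" for g in genes}
        a = conservation_rates(find_cintrons(genes, aln), labels)
        b = conservation_rates(find_cintrons(list(reversed(genes)), aln), labels)
        assert [(c.column, c.phase, c.rates) for c in a] == [
            (c.column, c.phase, c.rates) for c in b]


class TestSpecificityReport:
    def _annotated(self):
        # class A: intron at 30 (specific); both classes: intron at 60 (universal)
        genes = [_gene_with_introns(f"a{i}", 100, [(30, 0, 40), (60, 1, 40)])
                 for i in range(5)]
        genes += [_gene_with_introns(f"b{i}", 100, [(60, 1, 40)]) for i in range(5)]
        aln = MultipleAlignment({g.gene_id: "A" * 100 for g in genes})
        labels = {f"a{i}": "A" for i in range(5)} | {f"b{i}": "B" for i in range(5)}
        return conservation_rates(find_cintrons(genes, aln), labels)

    def test_planted_class_specific_and_universal_introns(self):
        rep = class_specificity_report(self._annotated())
        assert rep["specific"] == {"A": [(30, 0)]}
        assert rep["universal"] == [(60, 1)]
        assert rep["shared"] == []

    def test_matrix_rows_follow_tree_order(self):
        order = [f"b{i}" for i in range(5)] + [f"a{i}" for i in range(5)]
        rep = class_specificity_report(self._annotated(), tree_order=order)
        assert list(rep["matrix"].index) == order
        assert rep["matrix"]["c60.1"].sum() == 10

    def test_empty_cintron_set_gives_empty_lists(self):
        rep = class_specificity_report([])
        assert rep["specific"] == {} and rep["shared"] == [] and rep["universal"] == []
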