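"""Gene structures, intron coordinates, and GFF3 interchange.

Coordinates follow GFF3 conventions: genomic positions are 1-based and
inclusive, strand is ``+``/``-``.  Exons are stored 5'->3' in *transcript*
orientation, so a reverse-strand gene lists its exons by decreasing genomic
coordinate.  Genes here are protein-coding with CDS == exons (no UTRs), and
the CDS includes the stop codon: protein length = CDS/3 - 1.

An intron position is expressed in protein coordinates as (codon index,
phase): phase is the number of nucleotides of the interrupted codon lying 5'
of the intron; an intron "after codon i, phase 0" sits between codons i and
i+1.  Equivalently, with u = upstream CDS nucleotides, phase = u mod 3 and
codon = ceil(u / 3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable


@dataclass
class IntronPosition:
    """One intron in protein coordinates, plus its genomic length."""

    gene_id: str
    codon: int  # 1-based codon index after/in which the intron falls
    phase: int  # 0, 1 or 2
    length: int | None = None  # nt
    column: int | None = None  # alignment column, once mapped

    def __post_init__(self) -> None:
        if self.phase not in (0, 1, 2):
            raise ValueError(f"phase must be 0, 1 or 2 (gene {self.gene_id})")
        if self.codon < 1:
            raise ValueError(f"codon index must be >= 1 (gene {self.gene_id})")

    def upstream_nt(self) -> int:
        """CDS nucleotides 5' of the intron."""
        return 3 * self.codon if self.phase == 0 else 3 * (self.codon - 1) + self.phase


@dataclass
class GeneStructure:
    """A protein-coding gene as ordered exon intervals on a scaffold."""

    gene_id: str
    scaffold: str
    strand: str
    exons: list[tuple[int, int]]  # transcript order, genomic 1-based inclusive
    protein_id: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or - (gene {self.gene_id})")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"exon start > end in gene {self.gene_id}")
        ordered = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping exons in gene {self.gene_id}")
        if self.strand == "+" and self.exons != ordered:
            raise ValueError(f"+ strand exons must ascend (gene {self.gene_id})")
        if self.strand == "-" and self.exons != ordered[::-1]:
            raise ValueError(f"- strand exons must descend (gene {self.gene_id})")
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"CDS length {self.cds_length} of gene {self.gene_id} is not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def protein_length(self) -> int:
        return self.cds_length // 3 - 1  # stop codon excluded

    @property
    def span(self) -> tuple[int, int]:
        starts = [s for s, _ in self.exons]
        ends = [e for _, e in self.exons]
        return min(starts), max(ends)


def introns_from_structure(g: GeneStructure) -> list[IntronPosition]:
    """Intron positions (codon, phase, genomic length) from exon junctions.

    Strand-aware: a reverse-strand gene with mirrored coordinates yields the
    same protein-coordinate introns as its forward twin.
    """
    introns: list[IntronPosition] = []
    upstream = 0
    for (s1, e1), (s2, e2) in zip(g.exons, g.exons[1:]):
        upstream += e1 - s1 + 1
        codon = upstream // 3 if upstream % 3 == 0 else upstream // 3 + 1
        phase = upstream % 3
        gap = (s2 - e1 - 1) if g.strand == "+" else (s1 - e2 - 1)
        introns.append(IntronPosition(g.gene_id, codon, phase, length=gap))
    return introns


def exons_from_introns(
    protein_length: int,
    introns: Iterable[tuple[int, int, int]],
    scaffold_start: int,
    strand: str,
) -> list[tuple[int, int]]:
    """Lay out exon intervals for a CDS of 3*(protein_length)+3 nt.

    ``introns`` are (codon, phase, length) triples; the gene occupies
    genomic positions starting at ``scaffold_start`` (the 5'-most position
    for either strand being the leftmost genomic coordinate).
    """
    cds = 3 * protein_length + 3
    cuts = []
    for codon, phase, length in introns:
        ip = IntronPosition("tmp", codon, phase, length)
        u = ip.upstream_nt()
        if not 0 < u < cds:
            raise ValueError(f"intron at codon {codon} phase {phase} outside CDS")
        cuts.append((u, length))
    cuts.sort()
    if len({u for u, _ in cuts}) != len(cuts):
        raise ValueError("introns collide at the same CDS offset")

    # transcript-order exon lengths and 5'-offsets within the spliced gene
    pieces: list[tuple[int, int]] = []  # (offset within gene span, exon nt)
    prev_u = 0
    offset = 0
    for u, ilen in cuts:
        pieces.append((offset, u - prev_u))
        offset += (u - prev_u) + ilen
        prev_u = u
    pieces.append((offset, cds - prev_u))
    span = offset + (cds - prev_u)

    exons: list[tuple[int, int]] = []
    for off, n in pieces:
        if strand == "+":
            s = scaffold_start + off
            exons.append((s, s + n - 1))
        else:
            e = scaffold_start + span - 1 - off
            exons.append((e - n + 1, e))
    return exons


# --- GFF3 interchange -------------------------------------------------------

_GFF_HEADER = "##gff-version 3"


def write_gff3(genes: Iterable[GeneStructure], path: str | Path) -> None:
    lines = [_GFF_HEADER]
    for g in genes:
        start, end = g.span
        gid, tid = g.gene_id, f"{g.gene_id}.t1"
        lines.append(
            f"{g.scaffold}\tligperox\tgene\t{start}\t{end}\t.\t{g.strand}\t.\tID={gid}"
        )
        lines.append(
            f"{g.scaffold}\tligperox\tmRNA\t{start}\t{end}\t.\t{g.strand}\t.\t"
            f"ID={tid};Parent={gid};protein_id={g.protein_id}"
        )
        upstream = 0
        for s, e in g.exons:
            frame = (3 - upstream % 3) % 3
            lines.append(
                f"{g.scaffold}\tligperox\texon\t{s}\t{e}\t.\t{g.strand}\t.\tParent={tid}"
            )
            lines.append(
                f"{g.scaffold}\tligperox\tCDS\t{s}\t{e}\t.\t{g.strand}\t{frame}\tParent={tid}"
            )
            upstream += e - s + 1
    Path(path).write_text("\n".join(lines) + "\n")


def _attributes(s: str) -> dict[str, str]:
    out = {}
    for part in s.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_gff3(path: str | Path) -> list[GeneStructure]:
    """Read gene structures from a flat gene/mRNA/exon/CDS GFF3 file."""
    mrna_meta: dict[str, tuple[str, str, str, str]] = {}  # tid -> (gene, scaffold, strand, protein)
    cds: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) != 9:
            raise ValueError(f"malformed GFF3 line: {line!r}")
        scaffold, _, ftype, start, end, _, strand, _, attrs = f
        a = _attributes(attrs)
        if ftype == "mRNA":
            tid = a["ID"]
            mrna_meta[tid] = (a.get("Parent", tid), scaffold, strand, a.get("protein_id", tid))
            order.append(tid)
        elif ftype == "CDS":
            cds.setdefault(a["Parent"], []).append((int(start), int(end)))
    genes = []
    for tid in order:
        gene_id, scaffold, strand, protein_id = mrna_meta[tid]
        exons = sorted(cds.get(tid, []), reverse=(strand == "-"))
        genes.append(GeneStructure(gene_id, scaffold, strand, exons, protein_id))
    return genes
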