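"""Common-intron (cintron) detection and per-class conservation rates.

Intron positions are lifted from protein coordinates into alignment columns
through each gene's row of a protein multiple alignment; introns sharing an
exact (column, phase) identity form a *cintron*.  Per sub-class, a cintron's
conservation rate is the fraction of the class's genes carrying it; a
cintron is *conserved* when that rate strictly exceeds 50% in at least one
class.  A configurable column tolerance (default 0, i.e. exact identity) is
available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genes import GeneStructure, IntronPosition, introns_from_structure
from .msa import GAP, MultipleAlignment

CONSERVATION_CUTOFF = 0.5  # strict: rate must exceed this


def map_intron_to_alignment(ip: IntronPosition, row: str) -> int:
    """Alignment column (1-based) of the codon carrying the intron.

    ``row`` is the gene's gapped protein row; the intron's codon index must
    not exceed the row's ungapped length.
    """
    target = ip.codon
    seen = 0
    for col, c in enumerate(row, start=1):
        if c != GAP:
            seen += 1
            if seen == target:
                return col
    raise ValueError(
        f"intron codon {ip.codon} of gene {ip.gene_id} beyond ungapped row length {seen}"
    )


@dataclass
class Cintron:
    """An intron position shared (or not) across genes of the family."""

    column: int
    phase: int
    members: list[str]  # gene ids, sorted
    rates: dict[str, float] = field(default_factory=dict)  # per-class conservation
    conserved: bool = False
    majority_class: str | None = None
    universal: bool = False  # conserved in every class

    @property
    def key(self) -> tuple[int, int]:
        return (self.column, self.phase)


def find_cintrons(
    genes: Iterable[GeneStructure],
    aln: MultipleAlignment,
    tolerance: int = 0,
) -> list[Cintron]:
    """Group intron positions by exact (alignment column, phase).

    Every gene's protein must be a row of ``aln``.  All groups are reported,
    singletons included, ordered by (column, phase).  With ``tolerance`` > 0,
    same-phase groups whose columns lie within that many columns of the
    group seeded at the smallest column are merged (greedy left-to-right);
    the merged cintron keeps the seed column.
    """
    placed: dict[tuple[int, int], list[str]] = {}
    for g in genes:
        if g.protein_id not in aln:
            raise ValueError(f"gene {g.gene_id}: protein {g.protein_id} has no alignment row")
        row = aln.rows[g.protein_id]
        for ip in introns_from_structure(g):
            col = map_intron_to_alignment(ip, row)
            placed.setdefault((col, ip.phase), []).append(g.gene_id)

    keys = sorted(placed)
    if tolerance > 0:
        merged: dict[tuple[int, int], list[str]] = {}
        seed_for_phase: dict[int, tuple[int, int]] = {}
        for col, phase in keys:
            seed = seed_for_phase.get(phase)
            if seed is not None and col - seed[0] <= tolerance:
                merged[seed].extend(placed[(col, phase)])
            else:
                seed = (col, phase)
                seed_for_phase[phase] = seed
                merged[seed] = list(placed[(col, phase)])
        placed = merged
        keys = sorted(placed)
    return [Cintron(col, phase, sorted(placed[(col, phase)])) for col, phase in keys]


def conservation_rates(
    cintrons: Sequence[Cintron], class_labels: Mapping[str, str]
) -> list[Cintron]:
    """Annotate cintrons with per-class conservation rates in place.

    ``class_labels`` maps every analyzed gene (not only cintron members) to
    its sub-class; the denominator for a class is all its genes, so a class
    missing from a cintron scores rate 0.  Conserved = rate > 0.5 in at
    least one class (strict).  Majority-class ties break alphabetically.
    """
    class_sizes: dict[str, int] = {}
    for cls in class_labels.values():
        class_sizes[cls] = class_sizes.get(cls, 0) + 1
    classes = sorted(class_sizes)
    for ci in cintrons:
        for gid in ci.members:
            if gid not in class_labels:
                raise ValueError(f"cintron member gene {gid} has no class label")
        in_class: dict[str, int] = {c: 0 for c in classes}
        for gid in ci.members:
            in_class[class_labels[gid]] += 1
        ci.rates = {c: in_class[c] / class_sizes[c] for c in classes}
        ci.conserved = any(r > CONSERVATION_CUTOFF for r in ci.rates.values())
        ci.universal = all(r > CONSERVATION_CUTOFF for r in ci.rates.values())
        best = max(ci.rates.values())
        ci.majority_class = min(c for c, r in ci.rates.items() if r == best)
    return list(cintrons)


def class_specificity_report(
    cintrons: Sequence[Cintron],
    specificity_ceiling: float = 0.1,
    tree_order: Sequence[str] | None = None,
    gene_introns: Mapping[str, set[tuple[int, int]]] | None = None,
) -> dict:
    """Specific / shared / universal cintron lists plus a presence matrix.

    A cintron is *specific* to a class when it is conserved in exactly that
    class and its rate stays below ``specificity_ceiling`` everywhere else;
    *universal* when conserved in every class; *shared* otherwise (conserved
    in more than one but not all).  The presence/absence matrix rows follow
    ``tree_order`` (e.g. leaves in order of appearance in a phylogenetic
    tree) when given, else sorted gene ids.
    """
    specific: dict[str, list[tuple[int, int]]] = {}
    shared: list[tuple[int, int]] = []
    universal: list[tuple[int, int]] = []
    for ci in cintrons:
        if not ci.conserved:
            continue
        hot = [c for c, r in ci.rates.items() if r > CONSERVATION_CUTOFF]
        if ci.universal:
            universal.append(ci.key)
        elif len(hot) == 1 and all(
            r < specificity_ceiling for c, r in ci.rates.items() if c != hot[0]
        ):
            specific.setdefault(hot[0], []).append(ci.key)
        else:
            shared.append(ci.key)

    member_sets = {ci.key: set(ci.members) for ci in cintrons}
    gene_ids: list[str] = sorted({g for m in member_sets.values() for g in m})
    if tree_order is not None:
        known = set(gene_ids)
        gene_ids = [g for g in tree_order if g in known] + [
            g for g in gene_ids if g not in set(tree_order)
        ]
    cols = [f"c{col}.{phase}" for col, phase in sorted(member_sets)]
    matrix = pd.DataFrame(0, index=gene_ids, columns=cols, dtype=int)
    for (col, phase), members in member_sets.items():
        label = f"c{col}.{phase}"
        for g in members:
            matrix.loc[g, label] = 1
    matrix.index.name = "gene_id"
    return {
        "specific": specific,
        "shared": shared,
        "universal": universal,
        "matrix": matrix,
    }


def cintron_table(cintrons: Sequence[Cintron]) -> pd.DataFrame:
    rows = []
    for ci in cintrons:
        row = {
            "column": ci.column,
            "phase": ci.phase,
            "n_members": len(ci.members),
            "conserved": ci.conserved,
            "universal": ci.universal,
            "majority_class": ci.majority_class,
        }
        for c, r in ci.rates.items():
            row[f"rate_{c}"] = r
        rows.append(row)
    return pd.DataFrame(rows)
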