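"""Within-species paralog pairing and duplication typing.

Recent duplications leave paralog pairs that are each other's closest
relatives.  Pairs are read off a tree (or a distance matrix plus cluster
assignment) as mutual nearest neighbors within a cluster, same species
required; each event is then typed from scaffold coordinates:

* TD (tandem): same scaffold, successive genes (at most ``max_intervening``
  unrelated genes between the copies; default 0),
* SD (segmental): same scaffold, different locus,
* WGD (cross-scaffold): copies on different scaffolds.

The WGD category is purely coordinate-based — cross-scaffold pairs may in
reality be dispersed duplicates, hence the label "WGD (cross-scaffold)" in
reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .trees import tip_distances

logger = logging.getLogger(__name__)

DUPLICATION_TYPES = ("TD", "SD", "WGD", "unknown")


@dataclass(frozen=True)
class GeneLocus:
    """Genomic placement of one gene, with its ordinal rank on the scaffold."""

    gene_id: str
    species: str
    scaffold: str
    start: int
    end: int
    strand: str
    rank: int  # ordinal position among all annotated genes on the scaffold

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"locus start > end for {self.gene_id}")
        if self.rank < 1:
            raise ValueError(f"rank must be >= 1 for {self.gene_id}")


@dataclass
class DuplicationEvent:
    gene_a: str
    gene_b: str
    type: str  # TD | SD | WGD | unknown
    same_scaffold: bool | None = None
    intervening: int | None = None

    def __post_init__(self) -> None:
        if self.type not in DUPLICATION_TYPES:
            raise ValueError(f"unknown duplication type {self.type!r}")

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.gene_a, self.gene_b))


def paralog_pairs(
    ids: Sequence[str],
    dist: np.ndarray,
    species: Mapping[str, str],
    clusters: Mapping[str, str] | None = None,
) -> list[tuple[str, str]]:
    """Same-species mutual-nearest-neighbor pairs within each cluster.

    Rounds of pairing: in every round, all mutual nearest neighbors among
    the still-unpaired leaves of each cluster are identified together (so
    two sequential duplications yielding the clade ((a,b),(c,d)) give both
    pairs in the first round); MNN pairs of the same species become paralog
    pairs, cross-species MNN pairs retire unpaired.  Each gene joins at
    most one pair.
    """
    for leaf in ids:
        if leaf not in species:
            raise ValueError(f"leaf {leaf} has no species assignment")
    idx = {g: i for i, g in enumerate(ids)}
    if clusters is None:
        clusters = {g: "all" for g in ids}
    pairs: list[tuple[str, str]] = []
    by_cluster: dict[str, list[str]] = {}
    for g in ids:
        by_cluster.setdefault(clusters.get(g, "all"), []).append(g)

    for members in by_cluster.values():
        active = list(members)
        while len(active) >= 2:
            sub = np.array([[dist[idx[a], idx[b]] for b in active] for a in active])
            np.fill_diagonal(sub, np.inf)
            nn = sub.argmin(axis=1)
            round_pairs = []
            for i, j in enumerate(nn):
                if j > i and nn[j] == i:
                    round_pairs.append((active[i], active[j]))
            if not round_pairs:
                break
            for a, b in round_pairs:
                if species[a] == species[b]:
                    pairs.append(tuple(sorted((a, b))))
            taken = {g for p in round_pairs for g in p}
            active = [g for g in active if g not in taken]
    return sorted(pairs)


def pairs_from_tree(
    tree: TreeNode,
    species: Mapping[str, str],
    clusters: Mapping[str, str] | None = None,
) -> list[tuple[str, str]]:
    """Paralog pairs from patristic distances on a tree."""
    ids, d = tip_distances(tree)
    return paralog_pairs(ids, d, species, clusters)


def classify_duplication(
    pair: tuple[str, str],
    loci: Mapping[str, GeneLocus],
    max_intervening: int = 0,
) -> DuplicationEvent:
    """Type one paralog pair from scaffold coordinates.

    Symmetric in the pair; a missing locus yields type "unknown" with a
    logged warning instead of an error.
    """
    a, b = sorted(pair)
    la, lb = loci.get(a), loci.get(b)
    if la is None or lb is None:
        missing = a if la is None else b
        logger.warning("no locus for gene %s; duplication typed unknown", missing)
        return DuplicationEvent(a, b, "unknown")
    if la.scaffold != lb.scaffold:
        return DuplicationEvent(a, b, "WGD", same_scaffold=False)
    intervening = abs(la.rank - lb.rank) - 1
    dtype = "TD" if intervening <= max_intervening else "SD"
    return DuplicationEvent(a, b, dtype, same_scaffold=True, intervening=intervening)


def duplication_summary(
    events: Sequence[DuplicationEvent],
    loci: Mapping[str, GeneLocus],
    region_window: int = 10,
) -> dict:
    """Per-species event counts and genomic-region grouping of family genes.

    Regions are maximal runs of family genes on one scaffold whose
    successive rank gaps are <= ``region_window``.
    """
    counts: dict[str, dict[str, int]] = {}
    for ev in events:
        locus = loci.get(ev.gene_a) or loci.get(ev.gene_b)
        sp = locus.species if locus else "unknown"
        row = counts.setdefault(sp, {t: 0 for t in DUPLICATION_TYPES})
        row[ev.type] += 1
    counts_df = (
        pd.DataFrame.from_dict(counts, orient="index")
        .reindex(columns=list(DUPLICATION_TYPES))
        .fillna(0)
        .astype(int)
        .sort_index()
    )
    counts_df.index.name = "species"

    regions: list[dict] = []
    by_scaffold: dict[tuple[str, str], list[GeneLocus]] = {}
    for locus in loci.values():
        by_scaffold.setdefault((locus.species, locus.scaffold), []).append(locus)
    for (sp, scaffold), genes in sorted(by_scaffold.items()):
        genes = sorted(genes, key=lambda l: l.rank)
        run = [genes[0]]
        for locus in genes[1:]:
            if locus.rank - run[-1].rank <= region_window:
                run.append(locus)
            else:
                regions.append(_region(sp, scaffold, run))
                run = [locus]
        regions.append(_region(sp, scaffold, run))
    return {"counts": counts_df, "regions": regions}


def _region(species: str, scaffold: str, run: list[GeneLocus]) -> dict:
    return {
        "species": species,
        "scaffold": scaffold,
        "genes": [l.gene_id for l in run],
        "rank_range": (run[0].rank, run[-1].rank),
    }


def loci_table(loci: Mapping[str, GeneLocus]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": l.gene_id,
            "species": l.species,
            "scaffold": l.scaffold,
            "start": l.start,
            "end": l.end,
            "strand": l.strand,
            "rank": l.rank,
        }
        for l in loci.values()
    ]
    return pd.DataFrame(rows).sort_values("gene_id").reset_index(drop=True)


def read_loci_tsv(path) -> dict[str, GeneLocus]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for _, r in df.iterrows():
        out[r.gene_id] = GeneLocus(
            r.gene_id, r.species, r.scaffold, int(r.start), int(r.end), r.strand, int(r["rank"])
        )
    return out
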