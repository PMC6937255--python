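"""Synthetic class II peroxidase families with known ground truth.

Every input the analysis pipeline consumes can be generated here with the
truth attached: a family model (reference + per-sub-class consensus
sequences carrying residue signatures at anchored positions), protein
records mutated from the consensus, gene structures with planted
class-specific intron patterns, genome layouts containing tandem, segmental
and cross-scaffold duplicates, and species tables obeying the CcP/CII
co-occurrence rule at a controllable violation rate.

The generative model is deliberately simple: i.i.d. substitution from a
background composition at non-anchor sites, no evolution along a tree.
Anchor neighborhoods (+/- 2 residues) are protected from indels so mature
numbering stays recoverable by alignment.  Intron presets encode the two
lineage regimes: "ascomycete" genes average 2 introns of ~74 nt,
"basidiomycete" genes 8 introns of ~54 nt.

All randomness in a call flows from one integer seed through a single
``numpy.random.Generator``; identical parameters and seed reproduce
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import AMINO_ACIDS
from .anchors import ResidueAnchors
from .duplications import DuplicationEvent, GeneLocus
from .genes import GeneStructure, exons_from_introns, introns_from_structure
from .profiles import DEFAULT_BACKGROUND

#: canonical sub-class order; the first three carry the catalytic signatures
SUBCLASS_ORDER = ("MnP", "LiP", "VP", "CIIBA", "CIIBB", "CIIBC", "CIIAA", "CIIAB", "CIIAC")

#: (mn_triad, catalytic_trp) per sub-class; His/Cys/Ca anchors are present in all
SUBCLASS_SIGNATURES: dict[str, dict[str, bool]] = {
    label: {
        "mn_site": label in ("MnP", "VP"),
        "catalytic_trp": label in ("LiP", "VP"),
        "active_his": True,
        "cys_sites": True,
        "ca_ligands": True,
    }
    for label in SUBCLASS_ORDER
}

#: (mean introns per gene, mean intron size in nt) per lineage preset
INTRON_PRESETS = {"ascomycete": (2.0, 74.0), "basidiomycete": (8.0, 54.0)}


def _signature_functional_type(sig: Mapping[str, bool]) -> str:
    triad, trp = sig["mn_site"], sig["catalytic_trp"]
    if triad and trp:
        return "VP-signature"
    if triad:
        return "MnP-signature"
    if trp:
        return "LiP-signature"
    return "none"


@dataclass
class SubclassModel:
    label: str
    consensus: str
    signature: dict[str, bool]
    intron_pattern: tuple[tuple[int, int], ...]  # (codon, phase), shared in class


@dataclass
class FamilyModel:
    """Generative truth for one synthetic peroxidase family."""

    reference_id: str
    reference_sequence: str
    anchors: ResidueAnchors
    subclasses: list[SubclassModel]
    family_columns: tuple[int, ...]  # 1-based columns identical across sub-classes
    background: np.ndarray

    def __post_init__(self) -> None:
        L = len(self.reference_sequence)
        self.anchors.check_against_length(L)
        for sc in self.subclasses:
            if len(sc.consensus) != L:
                raise ValueError(f"consensus of {sc.label} does not match reference length")
            missing = set(sc.signature) - set(self.anchors.groups())
            if set(self.anchors.groups()) - set(sc.signature):
                raise ValueError(f"signature of {sc.label} does not cover all anchor groups")
            if missing:
                raise ValueError(f"signature of {sc.label} names unknown groups {missing}")
        if abs(float(np.sum(self.background)) - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")

    @property
    def labels(self) -> list[str]:
        return [sc.label for sc in self.subclasses]

    def subclass(self, label: str) -> SubclassModel:
        for sc in self.subclasses:
            if sc.label == label:
                return sc
        raise KeyError(label)

    def anchor_positions(self) -> set[int]:
        return set(self.anchors.all_positions())


@dataclass
class SyntheticTruth:
    """Ground-truth labels for everything a generator emitted."""

    seed: int
    sequence_labels: dict[str, dict[str, str]] = field(default_factory=dict)
    gene_introns: dict[str, list[tuple[int, int, int]]] = field(default_factory=dict)
    duplication_events: list[DuplicationEvent] = field(default_factory=list)
    species_consistency: dict[str, bool] = field(default_factory=dict)

    def merge(self, other: "SyntheticTruth") -> None:
        self.sequence_labels.update(other.sequence_labels)
        self.gene_introns.update(other.gene_introns)
        self.duplication_events.extend(other.duplication_events)
        self.species_consistency.update(other.species_consistency)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "sequence_labels": self.sequence_labels,
            "gene_introns": {k: [list(t) for t in v] for k, v in self.gene_introns.items()},
            "duplication_events": [asdict(ev) for ev in self.duplication_events],
            "species_consistency": self.species_consistency,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _draw(rng: np.random.Generator, background: np.ndarray, exclude: set[str]) -> str:
    """One residue from the background, excluding the given letters."""
    letters = [a for a in AMINO_ACIDS if a not in exclude]
    probs = np.array([background[AMINO_ACIDS.index(a)] for a in letters])
    return str(rng.choice(letters, p=probs / probs.sum()))


def generate_family(
    n_subclasses: int = 9,
    length: int = 350,
    seed: int = 0,
    divergence: float = 0.5,
    family_conserved_fraction: float = 0.3,
    n_pattern_introns: int = 4,
    anchors: ResidueAnchors | None = None,
    background: np.ndarray | None = None,
) -> FamilyModel:
    """Generate a family model with planted sub-class signatures.

    Each sub-class consensus equals the reference at anchor columns whose
    signature state is "present" (a non-matching residue is planted where
    the state is "absent") and at the family-conserved columns; the
    remaining columns diverge from the reference independently with
    probability ``divergence``.
    """
    if n_subclasses < 2:
        raise ValueError("need at least 2 sub-classes")
    anchors = anchors or ResidueAnchors()
    anchors.check_against_length(length)
    bg = DEFAULT_BACKGROUND if background is None else np.asarray(background, float)
    rng = np.random.default_rng(seed)

    ref = [str(c) for c in rng.choice(list(AMINO_ACIDS), size=length, p=bg / bg.sum())]
    e1, e2, e3 = anchors.mn_site
    ref[e1 - 1], ref[e2 - 1], ref[e3 - 1] = "E", "E", "D"
    ref[anchors.catalytic_trp - 1] = "W"
    for p in anchors.active_his:
        ref[p - 1] = "H"
    for p in anchors.cys_sites:
        ref[p - 1] = "C"
    for p in anchors.ca_ligands:
        ref[p - 1] = _draw(rng, bg, exclude=set(AMINO_ACIDS) - anchors.ca_allowed)
    reference = "".join(ref)

    anchor_pos = set(anchors.all_positions())
    free = [p for p in range(1, length + 1) if p not in anchor_pos]
    n_fam = int(round(family_conserved_fraction * len(free)))
    family_cols = tuple(sorted(rng.choice(free, size=n_fam, replace=False).tolist()))
    family_set = set(family_cols)

    labels = list(SUBCLASS_ORDER[:n_subclasses])
    labels += [f"SC{i}" for i in range(len(labels) + 1, n_subclasses + 1)]

    subclasses = []
    for label in labels:
        sig = SUBCLASS_SIGNATURES.get(
            label,
            {"mn_site": False, "catalytic_trp": False, "active_his": True,
             "cys_sites": True, "ca_ligands": True},
        )
        cons = list(reference)
        for group, (positions, allowed) in anchors.groups().items():
            if sig[group]:
                continue
            for p in positions:
                cons[p - 1] = _draw(rng, bg, exclude=set(allowed) | {cons[p - 1]})
        for p in free:
            if p not in family_set and rng.random() < divergence:
                cons[p - 1] = _draw(rng, bg, exclude={cons[p - 1]})

        codons = rng.choice(np.arange(5, length - 5), size=n_pattern_introns, replace=False)
        phases = rng.integers(0, 3, size=n_pattern_introns)
        pattern = tuple(sorted((int(c), int(ph)) for c, ph in zip(codons, phases)))
        subclasses.append(SubclassModel(label, "".join(cons), dict(sig), pattern))

    return FamilyModel("synthetic_ref", reference, anchors, subclasses, family_cols, bg)


def _mutate(
    seq: str,
    rate: float,
    rng: np.random.Generator,
    background: np.ndarray,
    protected: set[int],
) -> str:
    """I.i.d. substitution outside protected 1-based positions.

    Replacements are drawn from the background excluding the current
    residue, so every mutation event changes the site.
    """
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        if (i + 1) in protected:
            continue
        out[i] = _draw(rng, background, exclude={out[i]})
    return "".join(out)


def generate_sequences(
    model: FamilyModel,
    n_per_class: int = 20,
    sub_rate: float = 0.15,
    seed: int = 0,
    indels: bool = False,
    mean_indels: float = 1.0,
    max_indel: int = 3,
) -> tuple[dict[str, str], SyntheticTruth]:
    """Protein records mutated from each sub-class consensus.

    Non-anchor sites substitute independently with probability ``sub_rate``;
    anchor-site states are always preserved.  With ``indels=True`` each
    record additionally receives a Poisson(``mean_indels``) number of short
    insertions/deletions (1..``max_indel`` residues) outside anchor
    neighborhoods (anchor position +/- 2).
    """
    if not (0.0 <= sub_rate < 1.0):
        raise ValueError("sub_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    records: dict[str, str] = {}
    truth = SyntheticTruth(seed=seed)
    anchor_pos = sorted(model.anchor_positions())

    for sc in model.subclasses:
        ftype = _signature_functional_type(sc.signature)
        for i in range(n_per_class):
            rid = f"{sc.label}_{i:03d}"
            seq = _mutate(sc.consensus, sub_rate, rng, model.background, set(anchor_pos))
            if indels:
                seq = _apply_indels(seq, anchor_pos, rng, model.background,
                                    mean_indels, max_indel)
            records[rid] = seq
            truth.sequence_labels[rid] = {"subclass": sc.label, "functional_type": ftype}
    return records, truth


def _apply_indels(
    seq: str,
    anchor_pos: Sequence[int],
    rng: np.random.Generator,
    background: np.ndarray,
    mean_indels: float,
    max_indel: int,
) -> str:
    current = np.array(anchor_pos)  # anchor coordinates in the evolving sequence
    s = list(seq)
    for _ in range(int(rng.poisson(mean_indels))):
        protected = {p + d for p in current for d in range(-2, 3)}
        k = int(rng.integers(1, max_indel + 1))
        if rng.random() < 0.5:  # insertion between positions j and j+1
            spots = [j for j in range(len(s) + 1)
                     if j not in protected and (j + 1) not in protected]
            if not spots:
                continue
            j = int(rng.choice(spots))
            ins = [_draw(rng, background, set()) for _ in range(k)]
            s[j:j] = ins
            current = np.where(current > j, current + k, current)
        else:  # deletion of segment [j+1, j+k] (1-based)
            spots = [
                j for j in range(len(s) - k + 1)
                if not any((j + d + 1) in protected for d in range(k))
            ]
            if not spots:
                continue
            j = int(rng.choice(spots))
            del s[j:j + k]
            current = np.where(current > j + k, current - k, current)
    return "".join(s)


def generate_gene_structures(
    records: Mapping[str, str],
    model: FamilyModel,
    labels: Mapping[str, str],
    preset: str | None = "basidiomycete",
    mean_introns: float | None = None,
    mean_intron_size: float | None = None,
    carriage: float = 0.9,
    seed: int = 0,
    scaffold: str = "scaffold_1",
    intergenic: int = 500,
) -> tuple[list[GeneStructure], SyntheticTruth]:
    """Gene structures with class-shared intron patterns plus private introns.

    Each gene carries its class's planted (codon, phase) pattern with
    probability ``carriage`` per position, topped up with random private
    introns so the expected intron count matches ``mean_introns``.  When the
    planted pattern alone would exceed the target mean it is truncated to
    its leading positions; with ``mean_introns = 0`` the full pattern is
    planted (at its carriage) and no private introns are added, so the
    caller controls intron content entirely through the pattern.  Intron
    sizes are normal around ``mean_intron_size`` (sd 15%, floor 20 nt).
    Genes are laid end to end on one synthetic scaffold with random strand.
    """
    if preset is not None and preset not in INTRON_PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(INTRON_PRESETS)}")
    preset_mean, preset_size = INTRON_PRESETS.get(preset, (0.0, 60.0)) if preset else (0.0, 60.0)
    mean_introns = preset_mean if mean_introns is None else mean_introns
    mean_intron_size = preset_size if mean_intron_size is None else mean_intron_size
    if mean_introns < 0:
        raise ValueError("mean_introns must be >= 0")

    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(seed=seed)
    structures: list[GeneStructure] = []
    offset = 1
    for rid, seq in records.items():
        L = len(seq)
        pattern = [
            (c, p) for c, p in model.subclass(labels[rid]).intron_pattern if c <= L - 1
        ]
        if mean_introns > 0:
            k = len(pattern) if carriage == 0 else int(mean_introns // carriage)
            pattern = pattern[: min(len(pattern), k)]
        carried = [cp for cp in pattern if rng.random() < carriage]
        used_codons = {c for c, _ in carried}
        n_private = int(rng.poisson(max(0.0, mean_introns - carriage * len(pattern))))
        for _ in range(n_private):
            while True:  # resample on collision with an existing junction
                c = int(rng.integers(2, L))
                if c not in used_codons:
                    break
            used_codons.add(c)
            carried.append((c, int(rng.integers(0, 3))))
        sizes = np.maximum(
            20, np.rint(rng.normal(mean_intron_size, 0.15 * mean_intron_size,
                                   size=len(carried)))
        ).astype(int)
        triples = sorted(
            (c, p, int(s)) for (c, p), s in zip(carried, sizes)
        )
        strand = "+" if rng.random() < 0.5 else "-"
        exons = exons_from_introns(L, triples, offset, strand)
        g = GeneStructure(rid, scaffold, strand, exons, protein_id=rid)
        structures.append(g)
        truth.gene_introns[rid] = triples
        offset = g.span[1] + 1 + intergenic
    return structures, truth


def generate_genome_layout(
    records: Mapping[str, str],
    structures: Sequence[GeneStructure],
    model: FamilyModel,
    scenario: Sequence[tuple[str, str]],
    seed: int = 0,
    species: str = "Fungus_syntheticus",
    n_scaffolds: int = 3,
    spacer_between: int = 5,
    sd_spacers: int = 6,
    copy_sub_rate: float = 0.02,
) -> tuple[dict[str, str], dict[str, GeneLocus], list[GeneStructure], SyntheticTruth]:
    """Place genes on scaffolds and execute duplication directives.

    ``scenario`` is a list of (type, gene_id) with type in TD/SD/WGD.  The
    copy of gene *g* is named ``g_d`` and placed: TD immediately after *g*
    (no intervening gene), SD on the same scaffold behind ``sd_spacers``
    unrelated spacer genes, WGD on the next scaffold.  Copies are lightly
    re-mutated (``copy_sub_rate`` at non-anchor sites) so each pair remains
    mutually nearest neighbors.  Returns the augmented records, loci for
    all family genes (ranks count spacer genes), augmented structures and
    the planted event list.
    """
    struct_by_id = {g.gene_id: g for g in structures}
    for dtype, gid in scenario:
        if dtype not in ("TD", "SD", "WGD"):
            raise ValueError(f"unknown duplication directive {dtype!r}")
        if gid not in struct_by_id:
            raise ValueError(f"directive names unknown gene {gid!r}")

    rng = np.random.default_rng(seed)
    # occupant lists per scaffold: family gene ids or None (spacer gene)
    lanes: list[list[str | None]] = [[] for _ in range(n_scaffolds)]
    lane_of: dict[str, int] = {}
    for i, g in enumerate(structures):
        lane = i % n_scaffolds
        if lanes[lane]:
            lanes[lane].extend([None] * spacer_between)
        lanes[lane].append(g.gene_id)
        lane_of[g.gene_id] = lane

    out_records = dict(records)
    truth = SyntheticTruth(seed=seed)
    anchor_pos = model.anchor_positions()
    for dtype, gid in scenario:
        copy_id = f"{gid}_d"
        base_seq = records[gid]
        protected = anchor_pos if len(base_seq) >= max(anchor_pos) else set()
        out_records[copy_id] = _mutate(base_seq, copy_sub_rate, rng,
                                       model.background, protected)
        src = struct_by_id[gid]
        if dtype == "TD":
            lane = lane_of[gid]
            pos = lanes[lane].index(gid) + 1
            lanes[lane].insert(pos, copy_id)
        elif dtype == "SD":
            lane = lane_of[gid]
            pos = lanes[lane].index(gid) + 1
            lanes[lane][pos:pos] = [None] * sd_spacers + [copy_id]
        else:  # WGD: a different scaffold
            lane = (lane_of[gid] + 1) % n_scaffolds
            if lanes[lane]:
                lanes[lane].extend([None] * spacer_between)
            lanes[lane].append(copy_id)
        lane_of[copy_id] = lane
        truth.duplication_events.append(DuplicationEvent(gid, copy_id, dtype))

    # lay every family gene (originals relocated, copies new) onto its lane
    loci: dict[str, GeneLocus] = {}
    out_structs: list[GeneStructure] = []
    spacer_span, gap = 1500, 200
    for lane_idx, occupants in enumerate(lanes):
        scaffold = f"scaffold_{lane_idx + 1}"
        pos = 1
        for rank, occ in enumerate(occupants, start=1):
            if occ is None:
                pos += spacer_span + gap
                continue
            src = struct_by_id.get(occ) or struct_by_id[occ[:-2]]
            span = src.span[1] - src.span[0] + 1
            strand = src.strand
            loci[occ] = GeneLocus(occ, species, scaffold, pos, pos + span - 1, strand, rank)
            triples = [(ip.codon, ip.phase, ip.length) for ip in introns_from_structure(src)]
            exons = exons_from_introns(src.protein_length, triples, pos, strand)
            out_structs.append(GeneStructure(occ, scaffold, strand, exons, occ))
            if occ not in struct_by_id:
                truth.gene_introns[occ] = triples
            pos += span + gap
    out_structs.sort(key=lambda g: g.gene_id)
    return out_records, loci, out_structs, truth


def generate_species_table(
    n_species: int = 200,
    violation_rate: float = 0.1,
    seed: int = 0,
    association: float = 0.9,
    p_cii: float = 0.5,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Species table obeying the CcP/CII rule at 1 - ``violation_rate``.

    Rule-consistent species carry 2 CcP copies when they have no CII
    sequence and exactly 1 when they have at least one; violators break it.
    Trophism codes associate with CII presence at strength ``association``
    (1.0: every CII-positive species gets a lignin-associated code, every
    CII-negative species a non-lignin code).
    """
    if not (0.0 <= violation_rate <= 1.0):
        raise ValueError("violation_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    lignin_codes = ("NPP", "HPP", "WR")
    other_codes = ("S", "BR", "DND", "BPP", "OP", "APM", "APE",
                   "Sy", "ECM", "ERM", "OMF", "Li", "END")
    orders = {
        "Ascomycota": ("Pleosporales", "Hypocreales", "Eurotiales"),
        "Basidiomycota": ("Polyporales", "Agaricales", "Boletales"),
    }
    asco_classes = ("CIIAA", "CIIAB", "CIIAC")
    basidio_classes = ("MnP", "LiP", "VP", "CIIBA", "CIIBB", "CIIBC")

    rows = []
    truth = SyntheticTruth(seed=seed)
    for i in range(n_species):
        name = f"Fungus_sp_{i:03d}"
        phylum = "Basidiomycota" if rng.random() < 0.5 else "Ascomycota"
        order = str(rng.choice(orders[phylum]))
        counts = {c: 0 for c in
                  ("MnP", "LiP", "VP", "CIIBA", "CIIBB", "CIIBC", "CIIAA", "CIIAB", "CIIAC")}
        if rng.random() < p_cii:
            active = basidio_classes if phylum == "Basidiomycota" else asco_classes
            for c in active:
                counts[c] = int(rng.poisson(0.8))
            if sum(counts.values()) == 0:
                counts[str(rng.choice(active))] = 1
        total = sum(counts.values())
        # CII-positive species draw a lignin-associated code with probability
        # `association`; CII-negative species with probability 1 - association
        if (total > 0) == (rng.random() < association):
            trophism = str(rng.choice(lignin_codes))
        else:
            trophism = str(rng.choice(other_codes))
        ccp = 2 if total == 0 else 1
        consistent = rng.random() >= violation_rate
        if not consistent:
            ccp = 1 if total == 0 else 2
        truth.species_consistency[name] = bool(consistent)
        rows.append({"species": name, "phylum": phylum, "order": order,
                     "trophism": trophism, "ccp": ccp, **counts,
                     "total_cii": total})
    return pd.DataFrame(rows), truth


# --- on-disk fixture --------------------------------------------------------

def write_fasta(records: Mapping[str, str], path: str | Path) -> None:
    recs = [SeqRecord(Seq(s), id=k, description="") for k, s in records.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
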