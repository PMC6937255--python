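"""Residue-signature detection and catalytic functional typing.

A query is aligned to the mature reference, anchor positions are transferred,
and the observed residues are checked against each group's allowed class.
The functional type is called from the Mn2+ oxidation triad and the catalytic
tryptophan alone:

==============  ==============  ================
Mn triad        catalytic Trp   functional type
==============  ==============  ================
present         present         VP-signature
present         absent          MnP-signature
absent          present         LiP-signature
absent          absent          none
==============  ==============  ================

Cysteine, histidine and Ca2+-ligand counts are reported as supporting
evidence but never gate the call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .align import AlignParams, map_reference_positions, pairwise_align
from .anchors import ResidueAnchors

FUNCTIONAL_TYPES = ("VP-signature", "MnP-signature", "LiP-signature", "none")


@dataclass(frozen=True)
class SiteDetail:
    """Observation at one anchor: where it mapped and what was found."""

    group: str
    anchor_position: int
    query_position: int | None
    observed: str | None
    matched: bool


@dataclass
class ResidueSignature:
    """Presence/absence summary of the diagnostic residue groups."""

    sequence_id: str
    mn_triad_present: bool
    catalytic_trp_present: bool
    n_cys_found: int
    n_his_found: int
    n_ca_ligands_found: int
    details: list[SiteDetail] = field(default_factory=list)


def detect_signature(
    query: str,
    reference: str,
    anchors: ResidueAnchors,
    sequence_id: str = "query",
    params: AlignParams | None = None,
) -> ResidueSignature:
    """Align ``query`` to ``reference`` and read off the anchor residues."""
    anchors.check_against_length(len(reference))
    aln = pairwise_align(query, reference, params)
    mapping = map_reference_positions(aln, list(anchors.all_positions()))
    details: list[SiteDetail] = []
    counts: dict[str, int] = {}
    for group, (positions, allowed) in anchors.groups().items():
        n = 0
        for p in positions:
            qp = mapping[p]
            obs = query[qp - 1] if qp is not None else None
            ok = obs is not None and obs in allowed
            n += ok
            details.append(SiteDetail(group, p, qp, obs, ok))
        counts[group] = n
    return ResidueSignature(
        sequence_id=sequence_id,
        mn_triad_present=counts["mn_site"] == 3,
        catalytic_trp_present=counts["catalytic_trp"] == 1,
        n_cys_found=counts["cys_sites"],
        n_his_found=counts["active_his"],
        n_ca_ligands_found=counts["ca_ligands"],
        details=details,
    )


def functional_type(sig: ResidueSignature) -> str:
    """Catalytic type from the (triad, Trp) truth table; total on all 4 cells."""
    if sig.mn_triad_present and sig.catalytic_trp_present:
        return "VP-signature"
    if sig.mn_triad_present:
        return "MnP-signature"
    if sig.catalytic_trp_present:
        return "LiP-signature"
    return "none"


def signature_table(
    records: Mapping[str, str] | Iterable[tuple[str, str]],
    reference: str,
    anchors: ResidueAnchors,
    params: AlignParams | None = None,
) -> pd.DataFrame:
    """Per-sequence signature summary for a batch of proteins."""
    items = records.items() if isinstance(records, Mapping) else records
    rows = []
    for seq_id, seq in items:
        sig = detect_signature(seq, reference, anchors, seq_id, params)
        rows.append(
            {
                "sequence_id": seq_id,
                "mn_triad_present": sig.mn_triad_present,
                "catalytic_trp_present": sig.catalytic_trp_present,
                "n_cys_found": sig.n_cys_found,
                "n_his_found": sig.n_his_found,
                "n_ca_ligands_found": sig.n_ca_ligands_found,
                "functional_type": functional_type(sig),
            }
        )
    return pd.DataFrame(rows)


def write_signature_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
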