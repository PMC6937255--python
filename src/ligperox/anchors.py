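"""Diagnostic residue anchors for class II peroxidases.

Class II ligninolytic peroxidases carry a small set of diagnostic residues
whose presence or absence separates the catalytic types: the three acidic
residues of the Mn2+ oxidation site (Glu35, Glu39, Asp179 in mature PcMnP01
numbering), the exposed catalytic tryptophan of LiP/VP, two active-site
histidines, eight cysteines forming four disulfide bridges, and nine ligands
of the two structural Ca2+ ions.

Positions are given in *mature numbering*: residue 1 is the first residue of
the processed protein, signal peptide already removed.  Only the Mn-site
coordinates are canonical; the remaining coordinates ship as configuration
tied to the reference sequence in use (here, the synthetic reference of
:mod:`ligperox.synthetic`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator


@dataclass(frozen=True)
class ResidueAnchors:
    """Mature-numbering coordinates of the diagnostic residue groups.

    Parameters
    ----------
    reference_id :
        Identifier of the mature reference protein the coordinates refer to.
    mn_site :
        Three positions of the Mn2+ oxidation triad (default 35, 39, 179).
    catalytic_trp :
        Position of the exposed catalytic tryptophan (LiP/VP).
    active_his :
        Two active-site histidines (distal and proximal).
    cys_sites :
        Eight cysteines of the four disulfide bridges.
    ca_ligands :
        Nine ligands of the two structural Ca2+ ions.
    """

    reference_id: str = "synthetic_ref"
    mn_site: tuple[int, int, int] = (35, 39, 179)
    catalytic_trp: int = 171
    active_his: tuple[int, int] = (46, 173)
    cys_sites: tuple[int, ...] = (3, 15, 34, 120, 195, 242, 249, 317)
    ca_ligands: tuple[int, ...] = (48, 63, 66, 68, 70, 177, 192, 196, 199)
    # allowed residue classes per group; the Mn triad accepts any acidic
    # residue (E or D) at each of its three sites
    mn_allowed: frozenset[str] = frozenset({"E", "D"})
    trp_allowed: frozenset[str] = frozenset({"W"})
    his_allowed: frozenset[str] = frozenset({"H"})
    cys_allowed: frozenset[str] = frozenset({"C"})
    ca_allowed: frozenset[str] = frozenset({"D", "G", "S", "T", "E", "N", "V", "I"})

    def __post_init__(self) -> None:
        if len(self.mn_site) != 3:
            raise ValueError("mn_site must hold exactly 3 positions")
        if len(self.active_his) != 2:
            raise ValueError("active_his must hold exactly 2 positions")
        if len(self.cys_sites) != 8:
            raise ValueError("cys_sites must hold exactly 8 positions")
        if len(self.ca_ligands) != 9:
            raise ValueError("ca_ligands must hold exactly 9 positions")
        positions = list(self.all_positions())
        if len(set(positions)) != len(positions):
            raise ValueError("anchor positions must be pairwise distinct")
        if min(positions) < 1:
            raise ValueError("anchor positions are 1-based and must be >= 1")

    def all_positions(self) -> Iterator[int]:
        yield from self.mn_site
        yield self.catalytic_trp
        yield from self.active_his
        yield from self.cys_sites
        yield from self.ca_ligands

    def groups(self) -> dict[str, tuple[tuple[int, ...], frozenset[str]]]:
        """Anchor groups as ``name -> (positions, allowed residues)``."""
        return {
            "mn_site": (tuple(self.mn_site), self.mn_allowed),
            "catalytic_trp": ((self.catalytic_trp,), self.trp_allowed),
            "active_his": (tuple(self.active_his), self.his_allowed),
            "cys_sites": (tuple(self.cys_sites), self.cys_allowed),
            "ca_ligands": (tuple(self.ca_ligands), self.ca_allowed),
        }

    @property
    def max_position(self) -> int:
        return max(self.all_positions())

    def check_against_length(self, length: int) -> None:
        """Raise if any anchor lies beyond a reference of ``length`` residues."""
        for name, (positions, _) in self.groups().items():
            for p in positions:
                if p > length:
                    raise ValueError(
                        f"anchor {name} position {p} exceeds reference length {length}"
                    )

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        for k in ("mn_allowed", "trp_allowed", "his_allowed", "cys_allowed", "ca_allowed"):
            d[k] = sorted(d[k])
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ResidueAnchors":
        d = json.loads(Path(path).read_text())
        for k in ("mn_allowed", "trp_allowed", "his_allowed", "cys_allowed", "ca_allowed"):
            if k in d:
                d[k] = frozenset(d[k])
        for k in ("mn_site", "active_his", "cys_sites", "ca_ligands"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


DEFAULT_ANCHORS = ResidueAnchors()
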