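"""Multiple-alignment container and identity distances.

Profiles, cintron mapping and tree building all consume protein multiple
alignments.  Alignment construction itself is an input to this package
(an external aligner, or synthetic same-length sequences which are trivially
aligned); here we only hold and interrogate it.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"


class MultipleAlignment:
    """An ordered mapping of row identifiers to equal-length gapped strings."""

    def __init__(self, rows: Mapping[str, str] | Iterable[tuple[str, str]]):
        items = list(rows.items() if isinstance(rows, Mapping) else rows)
        if len(items) < 2:
            raise ValueError("an alignment needs at least 2 rows")
        lengths = {len(s) for _, s in items}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        self.rows: dict[str, str] = dict(items)
        if len(self.rows) != len(items):
            raise ValueError("duplicate row identifiers")
        self.n_columns: int = lengths.pop()

    def __len__(self) -> int:
        return len(self.rows)

    def __contains__(self, key: str) -> bool:
        return key in self.rows

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    def column(self, j: int) -> str:
        """Column ``j`` (0-based) as a string over rows, in row order."""
        return "".join(s[j] for s in self.rows.values())

    def ungapped(self, key: str) -> str:
        return self.rows[key].replace(GAP, "")

    def subalignment(self, keys: Iterable[str]) -> "MultipleAlignment":
        return MultipleAlignment({k: self.rows[k] for k in keys})

    @classmethod
    def from_fasta(cls, path: str | Path) -> "MultipleAlignment":
        recs = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
        return cls(recs)

    def to_fasta(self, path: str | Path) -> None:
        recs = [SeqRecord(Seq(s), id=k, description="") for k, s in self.rows.items()]
        SeqIO.write(recs, str(path), "fasta")


def identity_distance_matrix(aln: MultipleAlignment) -> tuple[list[str], np.ndarray]:
    """Pairwise distance 1 - identical / aligned non-gap positions.

    Positions where either row carries a gap are excluded from both numerator
    and denominator; a pair sharing no non-gap positions gets distance 1.
    """
    ids = aln.ids
    mat = np.array([list(aln.rows[k]) for k in ids])
    nongap = mat != GAP
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            tot = int(both.sum())
            if tot == 0:
                dij = 1.0
            else:
                ident = int((mat[i][both] == mat[j][both]).sum())
                dij = 1.0 - ident / tot
            d[i, j] = d[j, i] = dij
    return ids, d
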