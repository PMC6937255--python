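"""Global pairwise protein alignment and reference-position mapping.

The aligner is a thin, validated wrapper around :class:`Bio.Align.PairwiseAligner`
configured for global alignment with BLOSUM62 and affine gaps (a gap of
length *k* costs ``gap_open + k * gap_extend``; defaults 11 + k).  ``X`` is
tolerated in queries and scores 0 against every residue.

Mapping mature-numbering anchor positions from a reference onto a query runs
through the alignment columns, so a query with extra N-terminal residues or
internal indels still yields correct coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: accepted query alphabet; X is an unknown residue scoring 0 everywhere
ALPHABET = AMINO_ACIDS + "X"


@dataclass(frozen=True)
class AlignParams:
    """Scoring parameters for global pairwise alignment."""

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0


@dataclass
class PairwiseAlignment:
    """A global alignment of a query against a reference.

    ``query_gapped`` and ``reference_gapped`` are equal-length gapped strings;
    removing the gaps restores the input sequences.
    """

    query_gapped: str
    reference_gapped: str
    score: float
    params: AlignParams = field(default_factory=AlignParams)

    def __post_init__(self) -> None:
        if len(self.query_gapped) != len(self.reference_gapped):
            raise ValueError("gapped rows must have equal length")

    @property
    def query(self) -> str:
        return self.query_gapped.replace("-", "")

    @property
    def reference(self) -> str:
        return self.reference_gapped.replace("-", "")


def validate_protein(seq: str, name: str) -> None:
    """Reject empty sequences and non-amino-acid characters."""
    if not seq:
        raise ValueError(f"{name} sequence is empty")
    for i, c in enumerate(seq):
        if c not in ALPHABET:
            raise ValueError(
                f"{name} sequence contains non-amino-acid character {c!r} at position {i + 1}"
            )


@lru_cache(maxsize=8)
def _scoring_matrix(name: str):
    m = substitution_matrices.load(name).copy()
    # X scores 0 against everything, including itself
    if "X" in m.alphabet:
        xi = m.alphabet.index("X")
        for j in range(len(m.alphabet)):
            m[xi, j] = 0.0
            m[j, xi] = 0.0
    return m


@lru_cache(maxsize=8)
def _aligner(params: AlignParams) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.substitution_matrix = _scoring_matrix(params.matrix)
    # biopython charges open on the first gap position and extend thereafter;
    # open + (k-1)*extend == gap_open + k*gap_extend requires this shift
    a.open_gap_score = -(params.gap_open + params.gap_extend)
    a.extend_gap_score = -params.gap_extend
    return a


def pairwise_align(
    query: str, reference: str, params: AlignParams | None = None
) -> PairwiseAlignment:
    """Optimal global alignment of ``query`` against ``reference``.

    Deterministic: among co-optimal alignments the aligner's first traceback
    is returned, which is a fixed function of the inputs.
    """
    params = params or AlignParams()
    validate_protein(query, "query")
    validate_protein(reference, "reference")
    aln = _aligner(params).align(query, reference)[0]
    return PairwiseAlignment(
        query_gapped=str(aln[0]),
        reference_gapped=str(aln[1]),
        score=float(aln.score),
        params=params,
    )


def map_reference_positions(
    aln: PairwiseAlignment, positions: list[int] | tuple[int, ...]
) -> dict[int, int | None]:
    """Map 1-based reference positions to 1-based query positions.

    A position maps to ``None`` when the query carries a gap at that
    alignment column.  Present mappings are strictly increasing.
    """
    ref_len = len(aln.reference)
    for p in positions:
        if p < 1 or p > ref_len:
            raise ValueError(f"anchor position {p} outside reference (length {ref_len})")
    wanted = set(positions)
    out: dict[int, int | None] = {}
    qpos = rpos = 0
    for qc, rc in zip(aln.query_gapped, aln.reference_gapped):
        if qc != "-":
            qpos += 1
        if rc != "-":
            rpos += 1
            if rpos in wanted:
                out[rpos] = qpos if qc != "-" else None
    return {p: out[p] for p in positions}
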