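"""Affine-gap global DP between a query and a position-specific profile.

Numba-compiled inner loop; scores are position-specific match scores
``S[j, a]`` for profile column j against residue index a.  A gap of length k
costs ``gap_open + k * gap_extend`` on either side, end gaps included
(true global alignment).  Unknown residues (index -1) score 0 at every
column.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1e30


@njit(cache=True)
def profile_align_score(S, qidx, gap_open, gap_extend):  # pragma: no cover - numba
    n_cols = S.shape[0]
    m = qidx.shape[0]
    first = gap_open + gap_extend  # cost of opening a length-1 gap
    ext = gap_extend

    M = np.full((m + 1, n_cols + 1), NEG)
    Ix = np.full((m + 1, n_cols + 1), NEG)  # gap in query (profile column deleted)
    Iy = np.full((m + 1, n_cols + 1), NEG)  # gap in profile (query residue inserted)
    M[0, 0] = 0.0
    for j in range(1, n_cols + 1):
        Ix[0, j] = -(gap_open + gap_extend * j)
    for i in range(1, m + 1):
        Iy[i, 0] = -(gap_open + gap_extend * i)

    for i in range(1, m + 1):
        a = qidx[i - 1]
        for j in range(1, n_cols + 1):
            s = 0.0 if a < 0 else S[j - 1, a]
            best_prev = M[i - 1, j - 1]
            if Ix[i - 1, j - 1] > best_prev:
                best_prev = Ix[i - 1, j - 1]
            if Iy[i - 1, j - 1] > best_prev:
                best_prev = Iy[i - 1, j - 1]
            M[i, j] = best_prev + s

            # gap-to-gap transitions open a fresh gap on the other side
            o = M[i, j - 1] - first
            oy = Iy[i, j - 1] - first
            if oy > o:
                o = oy
            e = Ix[i, j - 1] - ext
            Ix[i, j] = o if o > e else e

            o = M[i - 1, j] - first
            ox = Ix[i - 1, j] - first
            if ox > o:
                o = ox
            e = Iy[i - 1, j] - ext
            Iy[i, j] = o if o > e else e

    best = M[m, n_cols]
    if Ix[m, n_cols] > best:
        best = Ix[m, n_cols]
    if Iy[m, n_cols] > best:
        best = Iy[m, n_cols]
    return best
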