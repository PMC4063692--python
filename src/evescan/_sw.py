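"""Self-contained affine-gap Smith-Waterman scorer (numba DP).

This is an independent, quadratic-time code path used to verify the
translated-search alignments produced via Biopython.  It deliberately shares
no code with the search implementation.  Gap of length g costs
``open + (g-1)*extend`` (both passed as negative scores).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from Bio.Align import substitution_matrices

_NEG = -10 ** 9


@njit(cache=True)
def _sw_kernel(a, b, sub, gap_open, gap_extend):
    n, m = a.size, b.size
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), float(_NEG))  # gap in a (left move)
    F = np.full((n + 1, m + 1), float(_NEG))  # gap in b (up move)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] + gap_open, E[i, j - 1] + gap_extend)
            F[i, j] = max(H[i - 1, j] + gap_open, F[i - 1, j] + gap_extend)
            diag = H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]
            h = max(0.0, diag, E[i, j], F[i, j])
            H[i, j] = h
            if h > best:
                best = h
    return best


class LocalScorer:
    """Best local alignment score between two protein strings."""

    def __init__(self, matrix_name: str = "BLOSUM62",
                 gap_open: float = -11.0, gap_extend: float = -1.0):
        mat = substitution_matrices.load(matrix_name)
        self.alphabet = str(mat.alphabet)
        self._index = {c: i for i, c in enumerate(self.alphabet)}
        self._sub = np.asarray(mat, dtype=float)
        self.gap_open = float(gap_open)
        self.gap_extend = float(gap_extend)

    def _encode(self, s: str) -> np.ndarray:
        idx = self._index
        x = idx.get("X", 0)
        return np.array([idx.get(c, x) for c in s], dtype=np.int64)

    def score(self, a: str, b: str) -> float:
        if not a or not b:
            return 0.0
        return _sw_kernel(self._encode(a), self._encode(b), self._sub,
                          self.gap_open, self.gap_extend)
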