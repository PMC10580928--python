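"""Semi-global pairwise nucleotide alignment with affine gap costs.

This is the identity primitive used for OTU clustering and best-hit novelty
screening.  The alignment model is:

* global alignment with *free end gaps* (terminal gaps in either sequence
  cost nothing and are excluded from the identity denominator);
* scoring: match +5 / mismatch -4 / gap open -10 / gap extend -1 (a gap of
  length L costs 10 + (L - 1));
* only unambiguous identical residues (A, C, G, T) count as matches — an
  IUPAC ambiguity code never matches, not even itself — and they score as
  mismatches during alignment;
* identity = identical columns / alignment columns, where the column count
  excludes terminal-gap columns but counts internal gap columns.

The dynamic program is written as a numba kernel: full-length 16S genes are
~1,400 nt and greedy clustering performs thousands of pairwise comparisons,
which is far outside what a pure-Python DP can sustain.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MATCH_SCORE = 5
MISMATCH_SCORE = -4
GAP_OPEN = -10  # cost of a gap of length 1
GAP_EXTEND = -1  # additional cost per extra gapped column

IUPAC_DNA = "ACGTRYSWKMBDHVN"

_NEG = np.int64(-(10**15))

# A,C,G,T -> 0..3; every other IUPAC code gets a distinct value >= 4 so that
# equality of ambiguity codes is representable but never scored as a match.
_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate(IUPAC_DNA):
    _ENCODE[ord(_c)] = _i


class AlignmentError(ValueError):
    """Raised for sequences the aligner cannot handle."""


def encode(seq: str) -> np.ndarray:
    """Encode an uppercase IUPAC nucleotide string to int8 codes."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE[arr]
    if (codes < 0).any():
        bad = sorted({seq[i] for i in np.nonzero(codes < 0)[0]})
        raise AlignmentError(f"non-IUPAC characters in sequence: {bad}")
    return codes


@njit(cache=True, nogil=True)
def _semiglobal_kernel(a, b):  # pragma: no cover - exercised via wrapper
    """Return (matches, columns, score) of the optimal semi-global alignment.

    States: M (residue vs residue), X (gap in b, consumes a), Y (gap in a,
    consumes b).  Leading/trailing gaps are free: an alignment core may start
    at any cell of the first row/column and the final score is maximised over
    the last row/column of the M matrix (a core never starts or ends with an
    internal gap — extending the free terminal gap always scores better).
    Traceback tie-break preference is M > X > Y > start, which makes the
    reported identity a deterministic function of the inputs.
    """
    n = a.shape[0]
    m = b.shape[0]
    M = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    X = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    Y = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    # pointers: 0 = fresh start, 1 = from M, 2 = from X, 3 = from Y
    PM = np.zeros((n + 1, m + 1), dtype=np.int8)
    PX = np.zeros((n + 1, m + 1), dtype=np.int8)
    PY = np.zeros((n + 1, m + 1), dtype=np.int8)

    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            if ai == b[j - 1] and ai < 4:
                s = MATCH_SCORE
            else:
                s = MISMATCH_SCORE
            # M state
            best = M[i - 1, j - 1]
            ptr = 1
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                ptr = 2
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                ptr = 3
            if (i == 1 or j == 1) and best < 0:
                best = 0
                ptr = 0
            M[i, j] = best + s
            PM[i, j] = ptr
            # X state: gap column in b (consume a_i)
            bx = M[i - 1, j] + GAP_OPEN
            px = 1
            if X[i - 1, j] + GAP_EXTEND > bx:
                bx = X[i - 1, j] + GAP_EXTEND
                px = 2
            if Y[i - 1, j] + GAP_OPEN > bx:
                bx = Y[i - 1, j] + GAP_OPEN
                px = 3
            X[i, j] = bx
            PX[i, j] = px
            # Y state: gap column in a (consume b_j)
            by = M[i, j - 1] + GAP_OPEN
            py = 1
            if X[i, j - 1] + GAP_OPEN > by:
                by = X[i, j - 1] + GAP_OPEN
                py = 2
            if Y[i, j - 1] + GAP_EXTEND > by:
                by = Y[i, j - 1] + GAP_EXTEND
                py = 3
            Y[i, j] = by
            PY[i, j] = py

    # best end on the last row or last column (trailing gaps free)
    bi, bj = n, m
    best = M[n, m]
    for j in range(1, m):
        if M[n, j] > best:
            best = M[n, j]
            bi, bj = n, j
    for i in range(1, n):
        if M[i, m] > best:
            best = M[i, m]
            bi, bj = i, m

    matches = 0
    columns = 0
    i, j = bi, bj
    state = 1  # in M
    while True:
        if state == 1:
            columns += 1
            if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                matches += 1
            ptr = PM[i, j]
            i -= 1
            j -= 1
        elif state == 2:
            columns += 1
            ptr = PX[i, j]
            i -= 1
        else:
            columns += 1
            ptr = PY[i, j]
            j -= 1
        if ptr == 0:
            break
        state = ptr
    return matches, columns, best


def semiglobal_identity(a: str, b: str) -> tuple[int, int, int]:
    """Align two encoded-or-raw sequences; return (matches, columns, score).

    Inputs are uppercase IUPAC strings.  Raises :class:`AlignmentError` on
    empty or non-IUPAC input.
    """
    if not a or not b:
        raise AlignmentError("cannot align an empty sequence")
    ea = encode(a)
    eb = encode(b)
    matches, columns, score = _semiglobal_kernel(ea, eb)
    return int(matches), int(columns), int(score)
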