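"""Independent oracles used by the test suite.

``dp_identity_oracle`` is a pure-Python dynamic program over the identity
contract (semi-global, free end gaps, match +5 / mismatch -4 / gap open -10 /
gap extend -1, ambiguity codes never match, deterministic M > X > Y > start
traceback preference, boundary scanned (n,m) then last row then last column).
It shares no code with the package's numba kernel.

``enumerate_identity_oracle`` exhaustively enumerates every alignment of two
very short sequences, returning the optimal score and the set of identities
achieved by score-optimal alignments — a ground truth that is independent of
any dynamic-programming formulation.
"""

from __future__ import annotations

MATCH, MISMATCH, OPEN, EXT = 5, -4, -10, -1
NEG = float("-inf")
ACGT = set("ACGT")


def _s(x: str, y: str) -> int:
    return MATCH if (x == y and x in ACGT) else MISMATCH


def dp_identity_oracle(a: str, b: str) -> tuple[int, int, int]:
    """Return (matches, columns, score) under the identity contract."""
    # canonical ordering mirrors the symmetric public function
    if (len(a), a) < (len(b), b):
        a, b = b, a
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    PM = [[0] * (m + 1) for _ in range(n + 1)]
    PX = [[0] * (m + 1) for _ in range(n + 1)]
    PY = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _s(a[i - 1], b[j - 1])
            best, ptr = M[i - 1][j - 1], 1
            if X[i - 1][j - 1] > best:
                best, ptr = X[i - 1][j - 1], 2
            if Y[i - 1][j - 1] > best:
                best, ptr = Y[i - 1][j - 1], 3
            if (i == 1 or j == 1) and best < 0:
                best, ptr = 0, 0
            M[i][j], PM[i][j] = best + s, ptr
            bx, px = M[i - 1][j] + OPEN, 1
            if X[i - 1][j] + EXT > bx:
                bx, px = X[i - 1][j] + EXT, 2
            if Y[i - 1][j] + OPEN > bx:
                bx, px = Y[i - 1][j] + OPEN, 3
            X[i][j], PX[i][j] = bx, px
            by, py = M[i][j - 1] + OPEN, 1
            if X[i][j - 1] + OPEN > by:
                by, py = X[i][j - 1] + OPEN, 2
            if Y[i][j - 1] + EXT > by:
                by, py = Y[i][j - 1] + EXT, 3
            Y[i][j], PY[i][j] = by, py

    bi, bj, best = n, m, M[n][m]
    for j in range(1, m):
        if M[n][j] > best:
            bi, bj, best = n, j, M[n][j]
    for i in range(1, n):
        if M[i][m] > best:
            bi, bj, best = i, m, M[i][m]

    matches = columns = 0
    i, j, state = bi, bj, 1
    while True:
        if state == 1:
            columns += 1
            if a[i - 1] == b[j - 1] and a[i - 1] in ACGT:
                matches += 1
            ptr = PM[i][j]
            i, j = i - 1, j - 1
        elif state == 2:
            columns += 1
            ptr = PX[i][j]
            i -= 1
        else:
            columns += 1
            ptr = PY[i][j]
            j -= 1
        if ptr == 0:
            break
        state = ptr
    return matches, columns, int(best)


def enumerate_identity_oracle(a: str, b: str) -> tuple[int, set[float]]:
    """Exhaustive alignment enumeration for very short sequences.

    Returns (optimal score, {identity of every score-optimal alignment}).
    An alignment is a monotone path of diagonal / up / left moves; leading
    and trailing gap runs are free and excluded from the column count;
    internal gaps carry affine costs; an alignment must contain at least one
    residue-residue column.
    """
    n, m = len(a), len(b)
    results: list[tuple[int, int, int]] = []  # (score, matches, columns)

    def walk(i, j, cols, started):
        # cols: list of ("D", i, j) / ("U",) / ("L",) moves so far
        if i == n and j == m:
            if started:
                scored = _score_path(a, b, cols)
                if scored is not None:
                    results.append(scored)
            return
        if i < n and j < m:
            walk(i + 1, j + 1, cols + [("D", i, j)], True)
        if i < n:
            walk(i + 1, j, cols + [("U",)], started)
        if j < m:
            walk(i, j + 1, cols + [("L",)], started)

    walk(0, 0, [], False)
    best = max(r[0] for r in results)
    idents = {r[1] / r[2] for r in results if r[0] == best}
    return best, idents


def _score_path(a: str, b: str, cols) -> tuple[int, int, int] | None:
    # strip free terminal gap runs; a valid free-end-gap alignment starts on
    # the first row OR first column, so a terminal run mixing gaps in both
    # sequences is not a legal alignment and the path is discarded
    lo = 0
    while lo < len(cols) and cols[lo][0] != "D":
        lo += 1
    hi = len(cols)
    while hi > lo and cols[hi - 1][0] != "D":
        hi -= 1
    if len({mv[0] for mv in cols[:lo]}) > 1 or len({mv[0] for mv in cols[hi:]}) > 1:
        return None
    core = cols[lo:hi]
    score = matches = 0
    prev_gap = None  # "U"/"L"/None, for affine accounting
    for move in core:
        if move[0] == "D":
            _, i, j = move
            sc = _s(a[i], b[j])
            score += sc
            if sc == MATCH:
                matches += 1
            prev_gap = None
        else:
            score += EXT if prev_gap == move[0] else OPEN
            prev_gap = move[0]
    return score, matches, len(core)
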