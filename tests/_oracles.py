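"""Independent brute-force oracles for the test suite.

The Smith-Waterman implementation here is written against the textbook
recurrences (full dynamic-programming matrices, antidiagonal fill, explicit
traceback) and shares no code with the package's alignment engine; it exists
so the package can be checked against an exhaustive search on small inputs.
"""
from __future__ import annotations

import numpy as np

MATCH = 1
MISMATCH = -1
GAP_OPEN = -5     # score of the first gap column
GAP_EXTEND = -2   # score of each further gap column

NEG = -10 ** 9


def _score_matrices(a: str, b: str):
    """Fill full H (best), E (gap in a / consuming b) and F (gap in b /
    consuming a) matrices, 1-based with a zero border."""
    m, n = len(a), len(b)
    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    for d in range(2, m + n + 1):
        ilo = max(1, d - n)
        ihi = min(m, d - 1)
        if ilo > ihi:
            continue
        ii = np.arange(ilo, ihi + 1)
        jj = d - ii
        sub = np.where(av[ii - 1] == bv[jj - 1], MATCH, MISMATCH)
        E[ii, jj] = np.maximum(H[ii, jj - 1] + GAP_OPEN,
                               E[ii, jj - 1] + GAP_EXTEND)
        F[ii, jj] = np.maximum(H[ii - 1, jj] + GAP_OPEN,
                               F[ii - 1, jj] + GAP_EXTEND)
        H[ii, jj] = np.maximum.reduce([
            np.zeros(len(ii), dtype=np.int64),
            H[ii - 1, jj - 1] + sub,
            E[ii, jj], F[ii, jj]])
    return H, E, F


def sw_score(a: str, b: str) -> int:
    """Optimal local alignment score (exhaustive DP)."""
    H, _, _ = _score_matrices(a, b)
    return int(H.max())


def sw_align(a: str, b: str):
    """Best local alignment with statistics.

    Returns (score, matches, columns, (a_start, a_end), (b_start, b_end));
    score 0 means no positive-scoring local alignment exists and the other
    fields are zeroed.
    """
    H, E, F = _score_matrices(a, b)
    score = int(H.max())
    if score <= 0:
        return 0, 0, 0, (0, 0), (0, 0)
    i, j = np.unravel_index(np.argmax(H), H.shape)
    i, j = int(i), int(j)
    a_end, b_end = i, j
    matches = columns = 0
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] == 0:
                break
            sub = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            if H[i, j] == H[i - 1, j - 1] + sub:
                matches += int(a[i - 1] == b[j - 1])
                columns += 1
                i, j = i - 1, j - 1
            elif H[i, j] == E[i, j]:
                state = "E"
            elif H[i, j] == F[i, j]:
                state = "F"
            else:  # pragma: no cover - would indicate a fill bug
                raise AssertionError("inconsistent traceback")
        elif state == "E":
            columns += 1
            if E[i, j] == E[i, j - 1] + GAP_EXTEND:
                j -= 1
            else:
                j -= 1
                state = "H"
        else:  # state == "F"
            columns += 1
            if F[i, j] == F[i - 1, j] + GAP_EXTEND:
                i -= 1
            else:
                i -= 1
                state = "H"
    return score, matches, columns, (i, a_end), (j, b_end)


def sw_similar(a: str, b: str, min_identity: float, min_coverage: float,
               revcomp_fn=None) -> bool:
    """Dissimilarity audit oracle: does the best local alignment of the pair
    (either orientation) reach both thresholds?  Coverage is relative to the
    shorter sequence."""
    if revcomp_fn is None:
        comp = str.maketrans("ACGTN", "TGCAN")

        def revcomp_fn(s):
            return s.translate(comp)[::-1]
    short = min(len(a), len(b))
    for bb in (b, revcomp_fn(b)):
        score, matches, columns, (a0, a1), (b0, b1) = sw_align(a, bb)
        if score <= 0 or columns == 0:
            continue
        span = max(a1 - a0, b1 - b0)
        if matches / columns >= min_identity and span / short >= min_coverage:
            return True
    return False


def merge_intervals_oracle(intervals, max_gap):
    """Fixpoint pairwise merge (union-find flavour), independent of the
    sweep implementation: repeatedly merge any two intervals whose gap is
    < max_gap or which overlap, until stable."""
    items = [list(iv) for iv in intervals]
    changed = True
    while changed:
        changed = False
        for x in range(len(items)):
            for y in range(x + 1, len(items)):
                a, b = items[x], items[y]
                lo, hi = (a, b) if a[0] <= b[0] else (b, a)
                gap = hi[0] - lo[1]
                if gap < max_gap or gap <= 0:
                    items[x] = [min(a[0], b[0]), max(a[1], b[1])]
                    del items[y]
                    changed = True
                    break
            if changed:
                break
    return sorted(tuple(iv) for iv in items)
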