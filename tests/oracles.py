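"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately re-derive results by exhaustive enumeration or naive
dynamic programming, sharing no code with the package implementations.
"""

from __future__ import annotations

NEG = float("-inf")

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def naive_affine_score(a: str, b: str, match=1.0, mismatch=-1.0,
                       gap_open=-5.0, gap_extend=-1.0) -> float:
    """Optimal global alignment score, Gotoh three-matrix DP.

    A gap of length k costs gap_open + (k-1) * gap_extend.
    """
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


def enumerate_tandem_arrays(s: str, min_unit=2, max_unit=10, min_copies=3):
    """All maximal tandem arrays by direct checking of every (start, unit).

    Returns a set of (start, end, unit_len, copies, partial) tuples for
    arrays whose unit's fundamental period equals unit_len.
    """
    out = set()
    n = len(s)
    for u in range(min_unit, max_unit + 1):
        for start in range(n - 2 * u + 1):
            unit = s[start : start + u]
            if len(unit) < u:
                continue
            # canonical unit length: the fundamental period, or its
            # smallest admissible multiple when the period < min_unit
            p = next(
                (k for k in range(1, u) if u % k == 0 and unit == unit[:k] * (u // k)),
                u,
            )
            canonical = p if p >= min_unit else p * -(-min_unit // p)
            if canonical != u:
                continue
            # count full copies
            k = 1
            while s[start + k * u : start + (k + 1) * u] == unit:
                k += 1
            if k < min_copies:
                continue
            # partial extension
            partial = 0
            base = start + k * u
            while base + partial < n and s[base + partial] == unit[partial % u]:
                partial += 1
            if partial >= u:  # should have been a full copy
                continue
            end = base + partial
            # left-maximality: the periodic region must not extend left
            if start > 0 and s[start - 1] == s[start - 1 + u]:
                continue
            out.add((start, end, u, k, partial))
    return out


def enumerate_hairpins(s: str, min_stem=6, max_loop=30, min_loop=3):
    """All maximal perfect inverted repeats by checking every (i, j, k).

    Returns a set of (stem_start_5p, stem_len, loop_len, stem_start_3p,
    score) tuples for maximal stems.
    """
    score_of = {("G", "C"): 3, ("C", "G"): 3, ("A", "T"): 2, ("T", "A"): 2}
    n = len(s)
    out = set()
    for i in range(n):          # last base of 5' arm
        for loop in range(min_loop, max_loop + 1):
            j = i + loop + 1    # first base of 3' arm
            if j >= n:
                break
            k = 0
            while i - k >= 0 and j + k < n and _COMP.get(s[i - k]) == s[j + k]:
                k += 1
            if k >= min_stem:
                score = sum(score_of.get((s[i - t], s[j + t]), 0) for t in range(k))
                out.add((i - k + 1, k, loop, j, score))
    return out
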