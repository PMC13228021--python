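"""Independent brute-force oracles used by the test suite.

These deliberately avoid the vectorized/incremental code paths of the
package: plain nested-loop dynamic programming and exhaustive window
checking, so agreement is a real cross-check.
"""

from __future__ import annotations

import math

MATCH, MISMATCH, GAP = 1, -1, -2


def nw_align_brute(a: str, b: str) -> tuple[int, int, int]:
    """Nested-loop Needleman-Wunsch (linear gaps, end gaps penalized).

    Returns (score, matches, columns) with the same tie-break order the
    package documents: diagonal, then gap in ``b``, then gap in ``a``.
    """
    n, m = len(a), len(b)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        H[i][0] = GAP * i
    for j in range(1, m + 1):
        H[0][j] = GAP * j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            H[i][j] = max(H[i - 1][j - 1] + s, H[i - 1][j] + GAP, H[i][j - 1] + GAP)
    i, j = n, m
    matches = columns = 0
    while i > 0 or j > 0:
        columns += 1
        if i > 0 and j > 0:
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            if H[i][j] == H[i - 1][j - 1] + s:
                matches += a[i - 1] == b[j - 1]
                i, j = i - 1, j - 1
                continue
        if i > 0 and H[i][j] == H[i - 1][j] + GAP:
            i -= 1
            continue
        j -= 1
    return H[n][m], matches, columns


def tolerant_runs_brute(hom: list[bool], rate: float) -> list[tuple[int, int]]:
    """Exhaustive greedy leftmost maximal tolerant runs.

    A window [i, j] is valid when it starts and ends homozygous, has no
    two adjacent heterozygous entries, and its heterozygous count is at
    most floor(rate * window size).  For each leftmost homozygous start
    the largest valid endpoint is taken (checked by full recount for
    every candidate), and the scan resumes after it.
    """

    def valid(i: int, j: int) -> bool:
        if not (hom[i] and hom[j]):
            return False
        window = hom[i:j + 1]
        for a, b in zip(window, window[1:]):
            if not a and not b:
                return False
        n_het = sum(1 for h in window if not h)
        return n_het <= math.floor(rate * len(window))

    runs: list[tuple[int, int]] = []
    i, n = 0, len(hom)
    while i < n:
        if not hom[i]:
            i += 1
            continue
        best = i
        for j in range(i, n):
            if valid(i, j):
                best = j
        runs.append((i, best))
        i = best + 1
    return runs
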