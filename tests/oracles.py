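"""Independent brute-force oracles used to validate the implementations."""

from __future__ import annotations

from itertools import permutations

import numpy as np
from scipy.stats import spearmanr

NEG = float("-inf")


def gotoh_local_score(a: str, b: str, match, mismatch, gap_open, gap_extend):
    """Exhaustive affine-gap local alignment DP (Gotoh), score and end cell.

    Convention: a gap of length L scores gap_open + (L-1)*gap_extend.
    Returns (best_score, (i, j)) with i, j the 1-based end indices on a, b.
    """
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (consumes b)
    F = np.full((n + 1, m + 1), NEG)  # gap in b (consumes a)
    best = 0.0
    best_cell = (0, 0)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
                best_cell = (i, j)
    return best, best_cell


def brute_tsd(genome_seq: str, start: int, end: int, window: int, lo: int, hi: int):
    """Longest word duplicated immediately left of start and right of end."""
    best = None
    for L in range(lo, hi + 1):
        if start - L < 0 or end + L > len(genome_seq):
            continue
        left = genome_seq[start - L : start]
        right = genome_seq[end : end + L]
        if left == right and (best is None or L > best[1]):
            best = (right, L)
    return best


def brute_microhomology(line_seq: str, s: int, e: int, k_lo: int, k_hi: int, window: int):
    """All words shared by the upstream and downstream breakpoint flanks."""
    up = line_seq[max(0, s - window) : s]
    down = line_seq[e : e + window]
    out = set()
    for k in range(k_lo, k_hi + 1):
        for i in range(len(up) - k + 1):
            for j in range(len(down) - k + 1):
                if up[i : i + k] == down[j : j + k]:
                    out.add(up[i : i + k])
    return out


def brute_spearman_permutation(x, y):
    """Exact two-sided permutation test of the Spearman statistic."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho = spearmanr(x, y).statistic
    n = len(x)
    hits = 0
    total = 0
    for perm in permutations(range(n)):
        total += 1
        if abs(spearmanr(x[list(perm)], y).statistic) >= abs(rho) - 1e-12:
            hits += 1
    return rho, hits / total
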