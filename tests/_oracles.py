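"""Independent oracles: deliberately naive implementations used only to
verify the package's optimized code paths.  Nothing here imports the
aligner, the exact test, or the enrichment code under test."""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


def hamming_scan(
    tag: str, sequences: dict[str, str], max_mismatches: int
) -> list[tuple[str, int, str, int]]:
    """Exhaustive all-position, both-strand Hamming scan.

    Returns (ref_id, position, strand, mismatches) sorted the same way the
    aligner sorts.  Vectorized with numpy so full-universe scans of a few
    hundred tags stay inside seconds.
    """
    hits: list[tuple[str, int, str, int]] = []
    L = len(tag)
    for strand, q in (("+", tag), ("-", revcomp(tag))):
        q_arr = np.frombuffer(q.encode(), dtype=np.uint8)
        for rid, seq in sequences.items():
            if len(seq) < L:
                continue
            s_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            windows = np.lib.stride_tricks.sliding_window_view(s_arr, L)
            mism = (windows != q_arr).sum(axis=1)
            for pos in np.nonzero(mism <= max_mismatches)[0]:
                hits.append((rid, int(pos), strand, int(mism[pos])))
    hits.sort(key=lambda h: (h[3], h[0], h[1], h[2]))
    return hits


class OracleScanner:
    """hamming_scan with reference arrays encoded once, for scans of many
    tags against a large universe."""

    def __init__(self, sequences: dict[str, str]):
        self.arrays = {
            rid: np.frombuffer(seq.encode(), dtype=np.uint8)
            for rid, seq in sequences.items()
        }

    def scan(self, tag: str, max_mismatches: int) -> list[tuple[str, int, str, int]]:
        hits: list[tuple[str, int, str, int]] = []
        L = len(tag)
        for strand, q in (("+", tag), ("-", revcomp(tag))):
            q_arr = np.frombuffer(q.encode(), dtype=np.uint8)
            for rid, s_arr in self.arrays.items():
                if s_arr.size < L:
                    continue
                windows = np.lib.stride_tricks.sliding_window_view(s_arr, L)
                mism = (windows != q_arr).sum(axis=1)
                for pos in np.nonzero(mism <= max_mismatches)[0]:
                    hits.append((rid, int(pos), strand, int(mism[pos])))
        hits.sort(key=lambda h: (h[3], h[0], h[1], h[2]))
        return hits


def _midranks(values: list[float]) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def mann_whitney_exact(x: list[float], y: list[float]) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by enumerating group assignments.

    Counts arrangements whose U is at least as far from n1*n2/2 as the
    observed U (midranks for ties).  Pure-Python, no scipy."""
    n1, n2 = len(x), len(y)
    pooled = list(x) + list(y)
    ranks = _midranks(pooled)
    offset = n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    u_obs = sum(ranks[:n1]) - offset
    d_obs = abs(u_obs - mu)
    extreme = total = 0
    for idx in combinations(range(n1 + n2), n1):
        u = sum(ranks[i] for i in idx) - offset
        total += 1
        if abs(u - mu) >= d_obs - 1e-9:
            extreme += 1
    return u_obs, extreme / total


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] for X ~ Hypergeom(N, K, n), by direct summation of
    binomial coefficients."""
    denom = math.comb(N, n)
    total = 0
    for j in range(k, min(K, n) + 1):
        total += math.comb(K, j) * math.comb(N - K, n - j)
    return total / denom


def expected_pairwise_diff(divergence: float) -> float:
    """Per-site probability that two descendants of one ancestor differ,
    after independent substitution at the given per-base rate (substituted
    bases drawn uniformly from the 3 alternatives)."""
    d = divergence
    return 2 * d * (1 - d) + d * d * (2.0 / 3.0)
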