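"""Independent brute-force oracles for cross-checking the implementation.

Everything here is deliberately naive: position-by-position genome scans,
all-pairs enumeration, exhaustive label permutations. None of it shares code
with the package.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from numba import njit

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def encode(seq: str) -> np.ndarray:
    return np.array([_CODE[b] for b in seq], dtype=np.int8)


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


@njit(cache=True)
def _scan(genome: np.ndarray, read: np.ndarray, max_mismatch: int) -> np.ndarray:
    n, m = len(genome), len(read)
    hits = np.empty(n, dtype=np.int64)
    mism = np.empty(n, dtype=np.int64)
    count = 0
    for start in range(n - m + 1):
        d = 0
        for j in range(m):
            if genome[start + j] != read[j]:
                d += 1
                if d > max_mismatch:
                    break
        if d <= max_mismatch:
            hits[count] = start
            mism[count] = d
            count += 1
    return np.column_stack((hits[:count], mism[:count]))


def brute_force_align(
    read_seq: str,
    genome: dict[str, str],
    max_mismatch: int = 1,
    encoded: dict[str, np.ndarray] | None = None,
) -> list[tuple[str, int, str, int]]:
    """Every placement of the read with <= max_mismatch substitutions.

    Scans every offset of every chromosome on both strands (reverse
    complement against the plus strand). Returns (chrom, start, strand,
    mismatches) sorted. Pass a pre-encoded genome when scanning many reads.
    """
    if encoded is None:
        encoded = encode_genome(genome)
    out = []
    for strand, query in (("+", read_seq), ("-", revcomp(read_seq))):
        q = encode(query)
        for chrom, enc in encoded.items():
            for start, d in _scan(enc, q, max_mismatch):
                out.append((chrom, int(start), strand, int(d)))
    return sorted(out)


def encode_genome(genome: dict[str, str]) -> dict[str, np.ndarray]:
    return {chrom: encode(seq) for chrom, seq in genome.items()}


def all_pairs_spectrum(
    plus: list[tuple[str, int, float]],
    minus: list[tuple[str, int, float]],
    max_overlap: int = 20,
) -> np.ndarray:
    """Ping-pong overlap spectrum by explicit all-pairs enumeration.

    Inputs are (chrom, five_prime_position, weight) per placement. Overlap
    k = 5'(minus) - 5'(plus) + 1 in plus coordinates, 1 <= k <= max_overlap.
    """
    spectrum = np.zeros(max_overlap)
    for chrom_p, pos_p, w_p in plus:
        for chrom_m, pos_m, w_m in minus:
            if chrom_p != chrom_m:
                continue
            k = pos_m - pos_p + 1
            if 1 <= k <= max_overlap:
                spectrum[k - 1] += w_p * w_m
    return spectrum


def exact_ranksum_p(a: list[float], b: list[float]) -> float:
    """Two-sided exact rank-sum p by exhaustive enumeration of labelings.

    Enumerates every way of assigning |a| of the pooled ranks to group A and
    counts labelings whose rank-sum is at least as extreme (two-sided via
    2 * min(lower tail, upper tail), capped at 1). Requires no ties.
    """
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n1 = len(a)
    w_obs = sum(ranks[v] for v in a)
    sums = [sum(combo) for combo in combinations(range(1, len(pooled) + 1), n1)]
    total = len(sums)
    lower = sum(s <= w_obs for s in sums) / total
    upper = sum(s >= w_obs for s in sums) / total
    return min(1.0, 2 * min(lower, upper))


def exact_hypergeom_p(k: int, big_n: int, big_k: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n) by direct summation of counts."""
    total = comb(big_n, n)
    favorable = 0
    for i in range(k, min(big_k, n) + 1):
        favorable += comb(big_k, i) * comb(big_n - big_k, n - i)
    return favorable / total


def brute_force_present(counts_row: np.ndarray, min_all: int, min_half: int) -> bool:
    """Presence rule evaluated literally, one piRNA at a time."""
    n = len(counts_row)
    branch_all = all(c > min_all for c in counts_row)
    n_over = sum(c > min_half for c in counts_row)
    branch_half = n_over >= -(-n // 2)  # ceil(n/2)
    return branch_all or branch_half
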