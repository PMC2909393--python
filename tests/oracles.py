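"""Independent reference implementations used only as test oracles.

These deliberately share no code with the package: alignment scores come
from exhaustive enumeration (tiny inputs) or Biopython's PairwiseAligner;
clustering comes from a naive O(n^3) agglomerative loop on a dense
matrix; k-mer distance from Counter arithmetic.
"""

from __future__ import annotations

import math
from collections import Counter
from functools import lru_cache


def brute_force_nw_score(a: str, b: str, match: float, mismatch: float,
                         gap_open: float, gap_extend: float,
                         end_free: bool) -> float:
    """Best global alignment score by exhaustive recursion.

    State: (i, j, prev) where prev is 0 none/diag, 1 gap-in-b, 2 gap-in-a.
    A gap column costs gap_open when opening and gap_extend when extending;
    terminal gap columns are free when end_free.
    """

    @lru_cache(maxsize=None)
    def go(i: int, j: int, prev: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = -math.inf
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + go(i + 1, j + 1, 0))
        if i < len(a):
            free = end_free and (j == 0 or j == len(b))
            cost = 0.0 if free else (gap_extend if prev == 1 else gap_open)
            best = max(best, -cost + go(i + 1, j, 1))
        if j < len(b):
            free = end_free and (i == 0 or i == len(a))
            cost = 0.0 if free else (gap_extend if prev == 2 else gap_open)
            best = max(best, -cost + go(i, j + 1, 2))
        return best

    return go(0, 0, 0)


def biopython_nw_score(a: str, b: str, match: float, mismatch: float,
                       gap_open: float, gap_extend: float,
                       end_free: bool) -> float:
    """Affine global alignment score from Biopython's C implementation."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    if end_free:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    return float(aligner.score(a, b))


def naive_hcluster(n: int, get_dist, linkage: str, threshold: float,
                   rounding: bool = False) -> list[frozenset]:
    """Naive O(n^3) agglomerative clustering cut at a threshold.

    ``get_dist(i, j)`` must return the pairwise distance (1.0 for missing
    pairs).  Merging repeats while the minimum linkage value (rounded to
    whole percent when ``rounding``) is at or below the threshold; ties
    break on the smallest pair of cluster indices.
    """
    clusters: list[list[int]] = [[i] for i in range(n)]

    def linkval(ca: list[int], cb: list[int]) -> float:
        ds = [get_dist(i, j) for i in ca for j in cb]
        if linkage == "single":
            return min(ds)
        if linkage == "complete":
            return max(ds)
        return sum(ds) / len(ds)

    while len(clusters) > 1:
        best = None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                v = linkval(clusters[x], clusters[y])
                if rounding:
                    v = math.floor(v * 100.0 + 0.5) / 100.0
                if best is None or v < best[0] - 1e-12:
                    best = (v, x, y)
        if best is None or best[0] > threshold + 1e-9:
            break
        _, x, y = best
        clusters[x] = clusters[x] + clusters[y]
        del clusters[y]
    return sorted(
        (frozenset(c) for c in clusters),
        key=lambda c: min(c),
    )


def kmer_multiset_distance(a: str, b: str, k: int) -> float:
    """1 - shared/min over k-mer multisets, via Counter intersection."""
    ca = Counter(a[i:i + k] for i in range(len(a) - k + 1))
    cb = Counter(b[i:i + k] for i in range(len(b) - k + 1))
    shared = sum((ca & cb).values())
    return 1.0 - shared / min(sum(ca.values()), sum(cb.values()))


def partition_of_labels(labels) -> list[frozenset]:
    groups: dict[int, set[int]] = {}
    for idx, lab in enumerate(labels):
        groups.setdefault(int(lab), set()).add(idx)
    return sorted((frozenset(g) for g in groups.values()), key=lambda c: min(c))
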