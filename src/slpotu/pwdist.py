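"""Pairwise alignment distances and per-read error rates.

The distance between two reads is *quickdist*: the number of substitutions
plus indel differences divided by the alignment length, computed on an
affine-gap Needleman-Wunsch global alignment.  A maximal run of gap
columns counts as ONE indel difference by default, mirroring the error
definition used for pyrosequencing reads (an insertion or deletion of any
length is a single event); ``gap_per_column=True`` restores per-column
counting.  Terminal gap runs are excluded from both numerator and
denominator when ``end_gaps_free`` is set, so amplicons of unequal natural
length do not accrue spurious distance.

Because an all-pairs alignment is quadratic, ``sparse_distances`` applies
a conservative k-mer multiset prescreen first and stores only distances at
or below a cutoff, in the spirit of ESPRIT's kmer/needle pipeline.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from . import _align
from .seqio import UniqueSeq

__all__ = [
    "AlignScoring",
    "PairwiseAlignment",
    "SparseDistanceSet",
    "ErrorObservation",
    "nw_align",
    "quickdist",
    "pair_distance",
    "kmer_distance",
    "sparse_distances",
    "error_rate",
    "error_distribution",
]


@dataclass(frozen=True)
class AlignScoring:
    """Affine-gap alignment scoring.

    Gap penalties default to the ESPRIT needledist settings (open 5.75,
    extend 2.75); substitution scores default to match +5 / mismatch -4.
    Penalties are stored as positive magnitudes.  A gap run of length L
    costs ``gap_open + (L - 1) * gap_extend``.
    """

    match_reward: float = 5.0
    mismatch_penalty: float = 4.0
    gap_open: float = 5.75
    gap_extend: float = 2.75
    end_gaps_free: bool = True

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValueError("require gap_open >= gap_extend >= 0")


@dataclass
class PairwiseAlignment:
    """A global alignment of two sequences with column statistics.

    ``substitutions``, ``gap_events`` and ``gap_columns`` refer to the full
    alignment; the ``internal_*`` fields exclude terminal gap runs (the
    quantities used when end gaps are free).
    """

    aligned_a: str
    aligned_b: str
    score: float
    columns: int
    substitutions: int
    gap_events: int
    gap_columns: int
    internal_columns: int
    internal_gap_events: int
    internal_gap_columns: int
    end_gaps_free: bool


def _scratch(n: int, m: int):
    shape = (n + 1, m + 1)
    return (
        np.empty(shape, dtype=np.float64),
        np.empty(shape, dtype=np.float64),
        np.empty(shape, dtype=np.float64),
        np.empty(shape, dtype=np.int8),
        np.empty(shape, dtype=np.int8),
        np.empty(shape, dtype=np.int8),
        np.empty(n + m + 2, dtype=np.int8),
    )


def nw_align(a: str, b: str, scoring: AlignScoring = AlignScoring()) -> PairwiseAlignment:
    """Optimal global affine-gap alignment of two DNA strings.

    Traceback tie-breaking is deterministic: prefer a diagonal step, then
    a gap in ``b`` (up), then a gap in ``a`` (left).
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    ea = _align.encode(a)
    eb = _align.encode(b)
    M, X, Y, PM, PX, PY, ops = _scratch(len(a), len(b))
    score, k = _align._nw_fill_traceback(
        ea, eb, scoring.match_reward, -scoring.mismatch_penalty,
        scoring.gap_open, scoring.gap_extend, scoring.end_gaps_free,
        M, X, Y, PM, PX, PY, ops,
    )
    cols, subs, ge, gc, ic, ige, igc = _align._ops_stats(ea, eb, ops, k)
    ra = []
    rb = []
    ai = bi = 0
    for t in range(k):
        op = ops[t]
        if op == 0:
            ra.append(a[ai])
            rb.append(b[bi])
            ai += 1
            bi += 1
        elif op == 1:
            ra.append(a[ai])
            rb.append("-")
            ai += 1
        else:
            ra.append("-")
            rb.append(b[bi])
            bi += 1
    return PairwiseAlignment(
        aligned_a="".join(ra),
        aligned_b="".join(rb),
        score=float(score),
        columns=int(cols),
        substitutions=int(subs),
        gap_events=int(ge),
        gap_columns=int(gc),
        internal_columns=int(ic),
        internal_gap_events=int(ige),
        internal_gap_columns=int(igc),
        end_gaps_free=scoring.end_gaps_free,
    )


def quickdist(alignment: PairwiseAlignment, gap_per_column: bool = False) -> float:
    """Normalized distance of an alignment, in [0, 1].

    ``(substitutions + indel differences) / alignment length``; terminal
    gap runs are excluded when the alignment was built with free end gaps.
    A fully-overhanging alignment (no aligned columns left after trimming)
    is reported as distance 1.0.
    """
    if alignment.columns == 0:
        raise ValueError("zero-length alignment has no distance")
    if alignment.end_gaps_free:
        cols = alignment.internal_columns
        gaps = (alignment.internal_gap_columns if gap_per_column
                else alignment.internal_gap_events)
    else:
        cols = alignment.columns
        gaps = alignment.gap_columns if gap_per_column else alignment.gap_events
    if cols == 0:
        return 1.0
    return (alignment.substitutions + gaps) / cols


def pair_distance(a: str, b: str, scoring: AlignScoring = AlignScoring(),
                  gap_per_column: bool = False) -> float:
    """Symmetric quickdist between two sequences.

    The pair is put in canonical (lexicographic) order before alignment so
    traceback tie-breaking cannot make the distance asymmetric.
    """
    if a == b:
        return 0.0
    if b < a:
        a, b = b, a
    return quickdist(nw_align(a, b, scoring), gap_per_column=gap_per_column)


def kmer_distance(a: str, b: str, k: int = 6) -> float:
    """1 - (shared k-mers / min k-mer count), with multiset counts."""
    if k <= 0:
        raise ValueError("k must be positive")
    if len(a) < k or len(b) < k:
        raise ValueError(f"sequences must be at least {k} nt for k={k}")
    ea = _align.encode(a)
    eb = _align.encode(b)
    ka = np.empty(len(a), dtype=np.int64)
    kb = np.empty(len(b), dtype=np.int64)
    na = _align._kmer_codes(ea, k, ka)
    nb = _align._kmer_codes(eb, k, kb)
    shared = _align._shared_kmers(ka, na, kb, nb)
    return 1.0 - shared / min(na, nb)


@dataclass
class SparseDistanceSet:
    """All pairwise distances at or below a cutoff, stored sparsely.

    Entries are ``(i, j, d)`` with ``i < j`` indexing the input sequence
    list; the set is symmetric by construction and pairs that are absent
    are known (or presumed, if a prescreen was used) to exceed the cutoff.
    """

    cutoff: float
    n_items: int
    ids: list[str] = field(default_factory=list)
    _map: dict[tuple[int, int], float] = field(default_factory=dict)

    def add(self, i: int, j: int, d: float) -> None:
        if i == j:
            raise ValueError("self-pairs are not stored")
        if d > self.cutoff:
            raise ValueError(f"distance {d} exceeds cutoff {self.cutoff}")
        if i > j:
            i, j = j, i
        self._map[(i, j)] = d

    def get(self, i: int, j: int, default: float = math.inf) -> float:
        if i == j:
            return 0.0
        if i > j:
            i, j = j, i
        return self._map.get((i, j), default)

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, pair: tuple[int, int]) -> bool:
        i, j = pair
        return (min(i, j), max(i, j)) in self._map

    @property
    def entries(self) -> list[tuple[int, int, float]]:
        return [(i, j, d) for (i, j), d in sorted(self._map.items())]

    def neighbors(self, max_dist: Optional[float] = None) -> list[list[tuple[int, float]]]:
        """Adjacency lists: for each item, (partner, distance) pairs."""
        adj: list[list[tuple[int, float]]] = [[] for _ in range(self.n_items)]
        for (i, j), d in self._map.items():
            if max_dist is not None and d > max_dist:
                continue
            adj[i].append((j, d))
            adj[j].append((i, d))
        return adj

    def subset(self, indices: Sequence[int]) -> "SparseDistanceSet":
        """Restrict to a subset of items, reindexed to 0..len(indices)-1."""
        pos = {orig: new for new, orig in enumerate(indices)}
        out = SparseDistanceSet(
            cutoff=self.cutoff,
            n_items=len(indices),
            ids=[self.ids[i] for i in indices] if self.ids else [],
        )
        for (i, j), d in self._map.items():
            if i in pos and j in pos:
                out.add(pos[i], pos[j], d)
        return out

    def write_column(self, path: str | os.PathLike) -> None:
        """Write mothur column format: id_i, id_j, distance (6 decimals)."""
        with open(path, "w") as fh:
            for i, j, d in self.entries:
                fh.write(f"{self.ids[i]}\t{self.ids[j]}\t{d:.6f}\n")

    @classmethod
    def read_column(cls, path: str | os.PathLike, ids: Sequence[str],
                    cutoff: float) -> "SparseDistanceSet":
        index = {rid: i for i, rid in enumerate(ids)}
        out = cls(cutoff=cutoff, n_items=len(ids), ids=list(ids))
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                out.add(index[parts[0]], index[parts[1]], float(parts[2]))
        return out


def _pack(seqs: Sequence[str]):
    lengths = np.array([len(s) for s in seqs], dtype=np.int64)
    lmax = int(lengths.max())
    mat = np.zeros((len(seqs), lmax), dtype=np.uint8)
    for i, s in enumerate(seqs):
        mat[i, : len(s)] = _align.encode(s)
    return mat, lengths


def sparse_distances(
    uniques: Sequence[UniqueSeq],
    cutoff: float = 0.03,
    kmer_cutoff: float = 0.5,
    scoring: AlignScoring = AlignScoring(),
    k: int = 6,
    use_prescreen: bool = True,
    gap_per_column: bool = False,
) -> SparseDistanceSet:
    """Quickdist for every candidate pair of unique sequences.

    Pairs are skipped without alignment only when their k-mer distance
    exceeds ``kmer_cutoff`` (a deliberately conservative prescreen for a
    3% target cutoff); every surviving pair is aligned and kept if its
    quickdist is at or below ``cutoff``.
    """
    seqs = [u.sequence for u in uniques]
    if len(set(seqs)) != len(seqs):
        raise ValueError("unique sequences must be pairwise distinct")
    out = SparseDistanceSet(cutoff=cutoff, n_items=len(seqs),
                            ids=[u.id for u in uniques])
    if len(seqs) < 2:
        return out
    mat, lengths = _pack(seqs)
    nk = int(lengths.min()) - k + 1
    if use_prescreen and nk < 1:
        raise ValueError(f"sequences shorter than k={k}; disable the prescreen")
    kcounts = np.zeros(len(seqs), dtype=np.int64)
    kcodes = np.zeros((len(seqs), max(1, int(lengths.max()) - k + 1)), dtype=np.int64)
    if use_prescreen:
        for i in range(len(seqs)):
            kcounts[i] = _align._kmer_codes(mat[i, : lengths[i]], k, kcodes[i])
    ii, jj, dd = _align._sparse_kernel(
        mat, lengths, kcodes, kcounts, cutoff, kmer_cutoff, use_prescreen,
        scoring.match_reward, -scoring.mismatch_penalty,
        scoring.gap_open, scoring.gap_extend, scoring.end_gaps_free,
        gap_per_column,
    )
    for i, j, d in zip(ii, jj, dd):
        out.add(int(i), int(j), float(d))
    return out


@dataclass
class ErrorObservation:
    """Error count of one read against its nearest template."""

    read_id: str
    template_id: str
    n_errors: int
    template_length: int

    @property
    def error_rate(self) -> float:
        return self.n_errors / self.template_length


def error_rate(
    read_seq: str,
    template_set: Sequence[tuple[str, str]],
    scoring: AlignScoring = AlignScoring(),
    read_id: str = "read",
) -> ErrorObservation:
    """Errors of a read relative to its best-matching template.

    Each maximal gap run counts as one error regardless of length —
    insertions and deletions of any length are single events — plus one
    per substituted column; the rate is normalized by the length of the
    template, not of the alignment.  The template minimizing the error
    count wins (ties keep the earliest in ``template_set``).
    """
    if not template_set:
        raise ValueError("template set is empty")
    tseqs = [t[1] for t in template_set]
    tmat, tlens = _pack(tseqs)
    lmax = max(len(read_seq), int(tlens.max()))
    M, X, Y, PM, PX, PY, ops = _scratch(lmax, lmax)
    best_t, best_e = _align._error_count_vs_templates(
        _align.encode(read_seq), tlens, tmat,
        scoring.match_reward, -scoring.mismatch_penalty,
        scoring.gap_open, scoring.gap_extend, scoring.end_gaps_free,
        M, X, Y, PM, PX, PY, ops,
    )
    tid, tseq = template_set[int(best_t)]
    return ErrorObservation(
        read_id=read_id,
        template_id=tid,
        n_errors=int(best_e),
        template_length=len(tseq),
    )


def error_distribution(
    observations: Iterable[ErrorObservation] | Iterable[int],
    template_length: int,
    per_base_rate: float,
):
    """Observed vs binomial-expected counts of reads with n errors.

    If errors were independent across positions, the number of reads with
    exactly n errors out of N reads of length L would be
    ``N * C(L, n) * p**n * (1-p)**(L-n)``.  Rows cover every observed n
    (and all smaller n); expected counts over the full support sum to N.
    Returns a pandas DataFrame with columns n_errors, observed_count,
    expected_binomial_count.
    """
    import pandas as pd

    if not (0.0 <= per_base_rate <= 1.0):
        raise ValueError("per-base rate must be within [0, 1]")
    counts: list[int] = []
    for obs in observations:
        counts.append(obs.n_errors if isinstance(obs, ErrorObservation) else int(obs))
    if not counts:
        raise ValueError("no observations")
    n_reads = len(counts)
    max_n = max(counts)
    ns = np.arange(max_n + 1)
    observed = np.bincount(counts, minlength=max_n + 1)
    expected = n_reads * stats.binom.pmf(ns, template_length, per_base_rate)
    return pd.DataFrame(
        {
            "n_errors": ns,
            "observed_count": observed,
            "expected_binomial_count": expected,
        }
    )
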