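"""Single-linkage preclustering (SLP) and the SLP/PW-AL pipeline.

Deep amplicon sequencing inflates OTU richness: a read with a couple of
errors can sit within 3% of its template yet more than 3% from other
errant reads, so complete- and even average-linkage clustering splinters
one template into many OTUs.  SLP exploits the fact that templates are
sequenced far more often than any particular error variant: unique
sequences are sorted by abundance and greedily absorbed into 2%
single-linkage preclusters seeded by the most abundant sequences, so
error variants chain onto their presumed template without low-frequency
reads ever chaining two genuine templates together.

Pass 1 never merges two clusters: a sequence within 2% of several
clusters joins the first-created (i.e. most abundant) one only.  Pass 2
rescues small clusters (< 10 reads) by absorbing them into any large
cluster holding a member within 2%.  Each precluster is then represented
by its most abundant sequence, carrying the precluster's total read
count, in a final 3% clustering (average linkage by default).

Two templates genuinely closer than the precluster width are merged by
pass 1 — at a 3% final threshold they would cluster together under any
linkage rule, so no information is lost at the OTU level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .cluster import LINKAGES, OTUSet, ThresholdClustering
from .pwdist import AlignScoring, SparseDistanceSet, sparse_distances
from .seqio import UniqueSeq, is_abundance_sorted

__all__ = [
    "Precluster",
    "SLPConfig",
    "SLPPreclusterer",
    "SLPClustering",
    "slp_precluster",
    "slp_pipeline",
]


@dataclass
class Precluster:
    """A 2% single-linkage precluster.

    The representative is the highest-count member (ties broken by the
    lexicographically smallest sequence) and stands in for the whole
    precluster, with its aggregated count, in downstream clustering.
    """

    representative: UniqueSeq
    members: list[UniqueSeq]
    total_count: int
    created_rank: int

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class SLPConfig:
    """SLP parameters.

    precluster_width 0.02 is the narrowest width usable on ~60-nt tags
    (one nucleotide difference); small clusters hold fewer than 10 reads;
    the final cut is the conventional 3% OTU threshold.
    """

    precluster_width: float = 0.02
    small_cluster_max: int = 9
    final_width: float = 0.03
    final_linkage: str = "average"

    def __post_init__(self) -> None:
        if not (0 < self.precluster_width < self.final_width):
            raise ValueError(
                "require 0 < precluster_width < final_width "
                f"(got {self.precluster_width} vs {self.final_width})"
            )
        if self.final_linkage not in LINKAGES:
            raise ValueError(f"unknown linkage {self.final_linkage!r}")
        if self.small_cluster_max < 0:
            raise ValueError("small_cluster_max must be non-negative")


@dataclass
class _RepItem:
    """Precluster representative carrying the precluster's total count."""

    sequence: str
    count: int
    rep_id: str
    precluster: Precluster

    @property
    def id(self) -> str:
        return self.rep_id


def _elect(members: list[UniqueSeq]) -> UniqueSeq:
    return min(members, key=lambda m: (-m.count, m.sequence))


class SLPPreclusterer(BaseEstimator):
    """Abundance-ordered single-linkage preclustering.

    Parameters
    ----------
    width : float
        Preclustering width; a sequence joins a cluster when strictly
        closer than ``width`` to any member (boundary distances do not
        join).
    small_cluster_max : int
        Pass-2 rescue: clusters with at most this many reads are tested
        against the larger clusters once, in descending count order.
    kmer_cutoff, k, use_prescreen, scoring, gap_per_column
        Distance-computation options when no distances are supplied.

    Attributes
    ----------
    preclusters_ : list of Precluster, in creation order.
    labels_ : ndarray mapping each input sequence to its precluster index.
    representatives_ : list of UniqueSeq (one per precluster).
    """

    def __init__(
        self,
        width: float = 0.02,
        small_cluster_max: int = 9,
        kmer_cutoff: float = 0.5,
        k: int = 6,
        use_prescreen: bool = True,
        scoring: Optional[AlignScoring] = None,
        gap_per_column: bool = False,
    ):
        self.width = width
        self.small_cluster_max = small_cluster_max
        self.kmer_cutoff = kmer_cutoff
        self.k = k
        self.use_prescreen = use_prescreen
        self.scoring = scoring
        self.gap_per_column = gap_per_column

    def fit(self, X: Sequence[UniqueSeq], y=None,
            distances: Optional[SparseDistanceSet] = None,
            distance_fn: Optional[Callable[[str, str], float]] = None):
        """Precluster abundance-sorted unique sequences.

        ``X`` must already be sorted by count descending (ties broken
        lexicographically); sortedness is part of the algorithm and
        unsorted input raises.  Distances come from ``distances`` (a
        sparse set over ``X``), from ``distance_fn`` (called on sequence
        pairs on demand), or are computed internally.
        """
        uniques = list(X)
        if not uniques:
            raise ValueError("no sequences to precluster")
        if not is_abundance_sorted(uniques):
            raise ValueError(
                "input must be sorted by count descending (ties by sequence); "
                "abundance order is part of the SLP algorithm"
            )
        n = len(uniques)
        if distances is not None:
            if distances.n_items != n:
                raise ValueError("distance set does not match input size")
            if distances.cutoff < self.width:
                raise ValueError(
                    f"distance cutoff {distances.cutoff} below width {self.width}"
                )
            adj = distances.neighbors()
        elif distance_fn is not None:
            adj = self._adjacency_from_fn(uniques, distance_fn)
        else:
            distances = sparse_distances(
                uniques, cutoff=self.width, kmer_cutoff=self.kmer_cutoff,
                scoring=self.scoring or AlignScoring(), k=self.k,
                use_prescreen=self.use_prescreen,
                gap_per_column=self.gap_per_column,
            )
            adj = distances.neighbors()
        width = self.width

        # Pass 1: greedy assignment in abundance order.  The most abundant
        # sequence seeds cluster 0; each later sequence joins the
        # first-created cluster holding any member strictly within the
        # width, otherwise it seeds a new cluster.  Clusters never merge.
        cluster_of = np.full(n, -1, dtype=int)
        clusters: list[list[int]] = []
        for idx in range(n):
            target = -1
            for nb, d in adj[idx]:
                if d < width and nb < idx:
                    c = cluster_of[nb]
                    if target < 0 or c < target:
                        target = c
            if target < 0:
                target = len(clusters)
                clusters.append([])
            clusters[target].append(idx)
            cluster_of[idx] = target

        # Pass 2: single rescue sweep.  Small clusters, in descending
        # total-count order, are absorbed into the first large cluster
        # (same ordering) holding any member within the width.  Totals and
        # orderings are frozen at the start of the pass; no cascading.
        totals = [sum(uniques[i].count for i in c) for c in clusters]
        order = sorted(range(len(clusters)), key=lambda c: (-totals[c], c))
        big = [c for c in order if totals[c] > self.small_cluster_max]
        small = [c for c in order if totals[c] <= self.small_cluster_max]
        big_pos = {c: r for r, c in enumerate(big)}
        absorbed: dict[int, int] = {}
        for s in small:
            target = -1
            for idx in clusters[s]:
                for nb, d in adj[idx]:
                    if d < width:
                        c = cluster_of[nb]
                        if c in big_pos and (target < 0 or big_pos[c] < target):
                            target = big_pos[c]
            if target >= 0:
                absorbed[s] = big[target]
        for s, t in absorbed.items():
            clusters[t].extend(clusters[s])
            for idx in clusters[s]:
                cluster_of[idx] = t
            clusters[s] = []

        preclusters = []
        final_index = np.full(len(clusters), -1, dtype=int)
        for rank, members_idx in enumerate(clusters):
            if not members_idx:
                continue
            members = [uniques[i] for i in members_idx]
            final_index[rank] = len(preclusters)
            preclusters.append(
                Precluster(
                    representative=_elect(members),
                    members=members,
                    total_count=sum(m.count for m in members),
                    created_rank=rank,
                )
            )
        self.preclusters_ = preclusters
        self.labels_ = final_index[cluster_of]
        self.representatives_ = [p.representative for p in preclusters]
        self.distances_ = distances
        return self

    def _adjacency_from_fn(self, uniques, fn):
        n = len(uniques)
        adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
        for i in range(n):
            for j in range(i + 1, n):
                d = fn(uniques[i].sequence, uniques[j].sequence)
                if d < self.width:
                    adj[i].append((j, d))
                    adj[j].append((i, d))
        return adj


def slp_precluster(
    uniques_sorted: Sequence[UniqueSeq],
    distance_fn: Optional[Callable[[str, str], float]] = None,
    config: SLPConfig = SLPConfig(),
    distances: Optional[SparseDistanceSet] = None,
    scoring: Optional[AlignScoring] = None,
) -> list[Precluster]:
    """Run SLP preclustering on abundance-sorted unique sequences."""
    est = SLPPreclusterer(width=config.precluster_width,
                          small_cluster_max=config.small_cluster_max,
                          scoring=scoring)
    est.fit(uniques_sorted, distances=distances, distance_fn=distance_fn)
    return est.preclusters_


class SLPClustering(ClusterMixin, BaseEstimator):
    """SLP followed by threshold clustering of precluster representatives.

    The default configuration is the SLP/PW-AL method: 2% preclustering,
    then 3% average-linkage clustering of representatives based on
    pairwise alignments.  Each representative enters the final clustering
    with weight one but carries its precluster's total read count into the
    OTU totals.

    Attributes
    ----------
    labels_ : ndarray, OTU index per input unique sequence.
    otus_ : OTUSet over precluster representatives.
    preclusters_ : list of Precluster.
    """

    def __init__(
        self,
        precluster_width: float = 0.02,
        small_cluster_max: int = 9,
        final_width: float = 0.03,
        final_linkage: str = "average",
        mothur_rounding: bool = False,
        kmer_cutoff: float = 0.5,
        k: int = 6,
        use_prescreen: bool = True,
        scoring: Optional[AlignScoring] = None,
        gap_per_column: bool = False,
    ):
        self.precluster_width = precluster_width
        self.small_cluster_max = small_cluster_max
        self.final_width = final_width
        self.final_linkage = final_linkage
        self.mothur_rounding = mothur_rounding
        self.kmer_cutoff = kmer_cutoff
        self.k = k
        self.use_prescreen = use_prescreen
        self.scoring = scoring
        self.gap_per_column = gap_per_column

    @property
    def config(self) -> SLPConfig:
        return SLPConfig(
            precluster_width=self.precluster_width,
            small_cluster_max=self.small_cluster_max,
            final_width=self.final_width,
            final_linkage=self.final_linkage,
        )

    def fit(self, X: Sequence[UniqueSeq], y=None,
            distances: Optional[SparseDistanceSet] = None):
        """Cluster unique sequences into OTUs via SLP.

        Input need not be sorted; it is put into abundance order
        internally and ``labels_`` follows the order of ``X``.
        """
        cfg = self.config  # validates widths
        uniques = list(X)
        if not uniques:
            raise ValueError("no sequences to cluster")
        order = sorted(range(len(uniques)),
                       key=lambda i: (-uniques[i].count, uniques[i].sequence))
        uniques_sorted = [uniques[i] for i in order]
        if distances is None:
            # one sparse computation at the final width serves both stages:
            # pass-1 chains beyond the precluster width stay visible to the
            # final clustering of representatives; with rounding, distances
            # up to final_width + 0.005 still round into range
            cutoff = cfg.final_width + (0.005 if self.mothur_rounding else 0.0)
            distances = sparse_distances(
                uniques_sorted, cutoff=cutoff,
                kmer_cutoff=self.kmer_cutoff,
                scoring=self.scoring or AlignScoring(), k=self.k,
                use_prescreen=self.use_prescreen,
                gap_per_column=self.gap_per_column,
            )
        pre = SLPPreclusterer(width=cfg.precluster_width,
                              small_cluster_max=cfg.small_cluster_max,
                              scoring=self.scoring)
        pre.fit(uniques_sorted, distances=distances)
        self.preclusters_ = pre.preclusters_

        rep_items = [
            _RepItem(sequence=p.representative.sequence, count=p.total_count,
                     rep_id=p.representative.id, precluster=p)
            for p in self.preclusters_
        ]
        index_of = {id(u): i for i, u in enumerate(uniques_sorted)}
        rep_indices = [index_of[id(p.representative)] for p in self.preclusters_]
        rep_distances = distances.subset(rep_indices)
        final = ThresholdClustering(
            linkage=cfg.final_linkage, threshold=cfg.final_width,
            mothur_rounding=self.mothur_rounding,
        )
        final.fit(rep_items, distances=rep_distances)
        self.otus_ = final.otus_
        self.distances_ = distances

        # map OTU labels back through preclusters to the original order
        otu_of_precluster = final.labels_
        labels_sorted = otu_of_precluster[pre.labels_]
        labels = np.empty(len(uniques), dtype=int)
        labels[np.array(order)] = labels_sorted
        self.labels_ = labels
        self.n_clusters_ = len(self.otus_)
        return self


def slp_pipeline(
    uniques: Sequence[UniqueSeq],
    config: SLPConfig = SLPConfig(),
    mothur_rounding: bool = False,
    scoring: Optional[AlignScoring] = None,
    distances: Optional[SparseDistanceSet] = None,
) -> OTUSet:
    """Run the full SLP pipeline (precluster + final clustering)."""
    est = SLPClustering(
        precluster_width=config.precluster_width,
        small_cluster_max=config.small_cluster_max,
        final_width=config.final_width,
        final_linkage=config.final_linkage,
        mothur_rounding=mothur_rounding,
        scoring=scoring,
    )
    est.fit(uniques, distances=distances)
    return est.otus_
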