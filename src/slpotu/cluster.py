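"""Threshold hierarchical clustering of sparse pairwise distances.

OTUs are flat cuts of an agglomerative single-, average- or
complete-linkage clustering: merging proceeds from the smallest linkage
value and stops when no merge is possible at or below the threshold
(closed bound).  Distances absent from the sparse set are treated as 1.0,
which is exact whenever clusters stay within the sparse cutoff radius and
is the convention used for average-linkage means.

``mothur_rounding`` optionally rounds merge heights to the nearest whole
percent before the cut, mimicking clustering tools that round distances
when defining a cluster — with a 3% threshold this lets e.g. two
differences in a 60-nt read (distance 0.0333) still count as 3%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence

import numpy as np
from scipy.cluster import hierarchy
from sklearn.base import BaseEstimator, ClusterMixin

from .pwdist import AlignScoring, SparseDistanceSet, sparse_distances

__all__ = [
    "OTU",
    "OTUSet",
    "OTUStats",
    "ThresholdClustering",
    "hcluster",
    "otu_stats",
]

LINKAGES = ("single", "average", "complete")
MISSING_DISTANCE = 1.0


class CountedSeq(Protocol):
    """Anything clusterable: a unique sequence or a precluster representative."""

    sequence: str
    count: int

    @property
    def id(self) -> str: ...


@dataclass
class OTU:
    """A cluster of sequences with its aggregate read count."""

    members: list
    total_count: int
    representative: object

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class OTUSet:
    """Flat clustering result, OTUs sorted by total count descending."""

    otus: list[OTU]
    linkage: str
    threshold: float
    labels: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __len__(self) -> int:
        return len(self.otus)

    @property
    def total_count(self) -> int:
        return sum(o.total_count for o in self.otus)

    def sizes(self) -> np.ndarray:
        """Rank-abundance vector: OTU counts in descending order."""
        return np.array([o.total_count for o in self.otus], dtype=int)

    def write_list(self, path, label: Optional[str] = None) -> None:
        """Write a mothur-style .list line."""
        if label is None:
            label = f"{self.threshold:.2f}"
        with open(path, "w") as fh:
            cols = [label, str(len(self.otus))]
            for o in self.otus:
                cols.append(",".join(m.id for m in o.members))
            fh.write("\t".join(cols) + "\n")

    def write_table(self, path) -> None:
        """Write a TSV OTU table: otu_id, representative, total_count, members."""
        with open(path, "w") as fh:
            fh.write("otu_id\trepresentative\ttotal_count\tmembers\n")
            for n, o in enumerate(self.otus, 1):
                fh.write(
                    f"otu{n:05d}\t{o.representative.id}\t{o.total_count}\t"
                    + ",".join(m.id for m in o.members)
                    + "\n"
                )


def _rounded(heights: np.ndarray) -> np.ndarray:
    # round half up to the nearest whole percent
    return np.floor(heights * 100.0 + 0.5) / 100.0


def _cut_labels(
    sparse: SparseDistanceSet,
    n: int,
    linkage: str,
    threshold: float,
    mothur_rounding: bool,
) -> np.ndarray:
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; expected one of {LINKAGES}")
    if n == 0:
        return np.empty(0, dtype=int)
    if n == 1:
        return np.zeros(1, dtype=int)
    condensed = np.full(n * (n - 1) // 2, MISSING_DISTANCE)
    for i, j, d in sparse.entries:
        condensed[n * i - i * (i + 1) // 2 + (j - i - 1)] = d
    Z = hierarchy.linkage(condensed, method=linkage)
    heights = _rounded(Z[:, 2]) if mothur_rounding else Z[:, 2]
    Zc = Z.copy()
    Zc[:, 2] = heights
    # closed bound: merges at exactly the threshold are allowed
    labels = hierarchy.fcluster(Zc, t=threshold + 1e-9, criterion="distance")
    return labels - 1


def _build_otuset(
    items: Sequence[CountedSeq],
    labels: np.ndarray,
    linkage: str,
    threshold: float,
) -> OTUSet:
    groups: dict[int, list] = {}
    for item, lab in zip(items, labels):
        groups.setdefault(int(lab), []).append(item)
    otus = []
    for members in groups.values():
        rep = min(members, key=lambda m: (-m.count, m.sequence))
        otus.append(
            OTU(members=members, total_count=sum(m.count for m in members),
                representative=rep)
        )
    otus.sort(key=lambda o: (-o.total_count, o.representative.sequence))
    # relabel in final OTU order for a stable labels vector
    pos = {id(o): n for n, o in enumerate(otus)}
    member_to_otu = {}
    for o in otus:
        for m in o.members:
            member_to_otu[id(m)] = pos[id(o)]
    final = np.array([member_to_otu[id(it)] for it in items], dtype=int)
    return OTUSet(otus=otus, linkage=linkage, threshold=threshold, labels=final)


class ThresholdClustering(ClusterMixin, BaseEstimator):
    """Agglomerative OTU clustering cut at a distance threshold.

    Parameters
    ----------
    linkage : {"single", "average", "complete"}
        Rule for the distance between a sequence and an existing cluster:
        nearest member, unweighted mean over all members, or furthest
        member.
    threshold : float
        Flat-cut distance; merges with linkage value <= threshold happen.
    mothur_rounding : bool
        Round merge heights to the nearest whole percent before the cut.
    cutoff : float, optional
        Sparse-distance cutoff used when distances are computed in
        ``fit``; defaults to ``threshold``.
    kmer_cutoff, k, use_prescreen, scoring, gap_per_column
        Passed through to :func:`slpotu.pwdist.sparse_distances`.

    Attributes
    ----------
    labels_ : ndarray of shape (n_items,)
        OTU index per input item, numbered in abundance order.
    otus_ : OTUSet
        Clusters with counts and representatives.
    n_clusters_ : int
    """

    def __init__(
        self,
        linkage: str = "average",
        threshold: float = 0.03,
        mothur_rounding: bool = False,
        cutoff: Optional[float] = None,
        kmer_cutoff: float = 0.5,
        k: int = 6,
        use_prescreen: bool = True,
        scoring: Optional[AlignScoring] = None,
        gap_per_column: bool = False,
    ):
        self.linkage = linkage
        self.threshold = threshold
        self.mothur_rounding = mothur_rounding
        self.cutoff = cutoff
        self.kmer_cutoff = kmer_cutoff
        self.k = k
        self.use_prescreen = use_prescreen
        self.scoring = scoring
        self.gap_per_column = gap_per_column

    def fit(self, X: Sequence[CountedSeq], y=None,
            distances: Optional[SparseDistanceSet] = None):
        """Cluster unique sequences (optionally with precomputed distances)."""
        if self.linkage not in LINKAGES:
            raise ValueError(
                f"unknown linkage {self.linkage!r}; expected one of {LINKAGES}"
            )
        items = list(X)
        if distances is None:
            if self.cutoff is not None:
                cutoff = self.cutoff
            else:
                # with rounding, distances up to threshold + 0.005 still
                # round into range and must be present in the sparse set
                cutoff = self.threshold + (0.005 if self.mothur_rounding else 0.0)
            distances = sparse_distances(
                items,
                cutoff=cutoff,
                kmer_cutoff=self.kmer_cutoff,
                scoring=self.scoring or AlignScoring(),
                k=self.k,
                use_prescreen=self.use_prescreen,
                gap_per_column=self.gap_per_column,
            )
        elif distances.n_items != len(items):
            raise ValueError(
                f"distance set covers {distances.n_items} items, got {len(items)}"
            )
        raw = _cut_labels(distances, len(items), self.linkage,
                          self.threshold, self.mothur_rounding)
        self.otus_ = _build_otuset(items, raw, self.linkage, self.threshold)
        self.labels_ = self.otus_.labels
        self.n_clusters_ = len(self.otus_)
        self.distances_ = distances
        return self


def hcluster(
    sparse: SparseDistanceSet,
    items: Sequence[CountedSeq],
    linkage: str = "average",
    threshold: float = 0.03,
    mothur_rounding: bool = False,
) -> OTUSet:
    """Cluster items from a precomputed sparse distance set."""
    est = ThresholdClustering(linkage=linkage, threshold=threshold,
                              mothur_rounding=mothur_rounding)
    est.fit(items, distances=sparse)
    return est.otus_


@dataclass
class OTUStats:
    """Abundance summary of an OTU set."""

    n_otus: int
    largest_otu_size: int
    singleton_fraction: float
    singleton_tripleton_fraction: float
    rank_abundance: np.ndarray


def otu_stats(otuset: OTUSet) -> OTUStats:
    """Rank-abundance statistics: totals, singleton and 1-3-read fractions."""
    if len(otuset) == 0:
        raise ValueError("empty OTU set")
    sizes = otuset.sizes()
    return OTUStats(
        n_otus=len(sizes),
        largest_otu_size=int(sizes.max()),
        singleton_fraction=float((sizes == 1).mean()),
        singleton_tripleton_fraction=float((sizes <= 3).mean()),
        rank_abundance=sizes,
    )
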