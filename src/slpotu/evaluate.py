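"""Evaluation against known templates: spurious-OTU counts and depth curves.

On defined template pools the expected number of OTUs is known, so any
extra OTU is attributable to error reads or clustering artifacts.  An OTU
is credited to a template when its representative sequence lies within
the clustering width of that template; each template is claimable once,
with OTUs considered in descending abundance (the most abundant OTU for
a template is the one credited).  The remaining OTUs are spurious.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cluster import OTUSet, otu_stats
from .pwdist import AlignScoring, pair_distance
from .seqio import Read, dereplicate
from .slp import SLPClustering

__all__ = [
    "SpuriousReport",
    "DepthCurve",
    "count_spurious",
    "depth_curve",
    "compare_methods",
    "plot_depth_curve",
]


@dataclass
class SpuriousReport:
    """Template-matched vs spurious OTU bookkeeping."""

    expected_otus: int
    observed_otus: int
    matched: int
    spurious: int
    verdicts: list[tuple[str, str]]  # (otu representative id, verdict)

    @property
    def recovery_fraction(self) -> float:
        """Fraction of templates that claimed an OTU."""
        return self.matched / self.expected_otus if self.expected_otus else 1.0


def count_spurious(
    otuset: OTUSet,
    template_set: Sequence[tuple[str, str]],
    match_width: Optional[float] = None,
    scoring: Optional[AlignScoring] = None,
) -> SpuriousReport:
    """Classify each OTU as template-matched or spurious.

    ``match_width`` defaults to the OTU set's clustering threshold.
    Matching is greedy by OTU abundance: each OTU's representative is
    compared with the unclaimed templates and claims the nearest one
    within the width.
    """
    tseqs = [t[1] for t in template_set]
    if len(set(tseqs)) != len(tseqs):
        raise ValueError("template sequences must be distinct")
    width = match_width if match_width is not None else otuset.threshold
    scoring = scoring or AlignScoring()
    claimed = [False] * len(template_set)
    verdicts = []
    matched = 0
    for otu in otuset.otus:  # already sorted by abundance
        rep = otu.representative.sequence
        best = None
        best_d = None
        for t, (tid, tseq) in enumerate(template_set):
            if claimed[t]:
                continue
            d = pair_distance(rep, tseq, scoring)
            if d <= width and (best_d is None or d < best_d):
                best, best_d = t, d
        if best is not None:
            claimed[best] = True
            matched += 1
            verdicts.append((otu.representative.id, "template_matched"))
        else:
            verdicts.append((otu.representative.id, "spurious"))
    return SpuriousReport(
        expected_otus=len(template_set),
        observed_otus=len(otuset),
        matched=matched,
        spurious=len(otuset) - matched,
        verdicts=verdicts,
    )


@dataclass
class DepthCurve:
    """Spurious-OTU counts as a function of sampling depth."""

    depths: list[int]
    spurious_at_depth: list[float]
    replicates: int
    seed: Optional[int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"depth": self.depths, "mean_spurious_otus": self.spurious_at_depth}
        )


def depth_curve(
    reads: Sequence[Read],
    template_set: Sequence[tuple[str, str]],
    depths: Sequence[int],
    replicates: int = 1,
    seed: Optional[int] = None,
    method: Optional[SLPClustering] = None,
) -> DepthCurve:
    """Spurious OTUs in random subsamples of increasing depth.

    For each depth, reads are subsampled without replacement (a fresh
    generator per depth/replicate, derived from the master seed), the
    clustering method is run end to end, and the spurious count recorded;
    counts are averaged over replicates.
    """
    depths = sorted(int(d) for d in depths)
    if depths and depths[-1] > len(reads):
        raise ValueError(
            f"depth {depths[-1]} exceeds the {len(reads)} available reads"
        )
    if method is None:
        method = SLPClustering(mothur_rounding=True)
    means = []
    root = np.random.SeedSequence(seed)
    streams = root.spawn(len(depths) * replicates)
    s = 0
    for depth in depths:
        counts = []
        for _ in range(replicates):
            rng = np.random.default_rng(streams[s])
            s += 1
            idx = rng.choice(len(reads), size=depth, replace=False)
            sub = [reads[i] for i in idx]
            est = SLPClustering(**method.get_params())
            est.fit(dereplicate(sub))
            counts.append(count_spurious(est.otus_, template_set).spurious)
        means.append(float(np.mean(counts)))
    return DepthCurve(depths=list(depths), spurious_at_depth=means,
                      replicates=replicates, seed=seed)


def plot_depth_curve(curve: DepthCurve, path=None):
    """Plot depth vs mean spurious OTUs; saves to ``path`` when given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve.depths, curve.spurious_at_depth, marker="o")
    ax.set_xlabel("sampling depth (reads)")
    ax.set_ylabel("mean spurious OTUs")
    ax.set_title(f"spurious OTUs vs depth ({curve.replicates} replicates)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def compare_methods(uniques, configs: dict[str, object]) -> pd.DataFrame:
    """One row of OTU statistics per clustering method.

    ``configs`` maps a method name to a fitted-or-unfitted estimator with
    a ``fit``/``otus_`` interface (e.g. :class:`ThresholdClustering` for
    PW-AL/PW-CL, :class:`SLPClustering` for SLP/PW-AL).  Estimators are
    cloned per run via ``get_params`` so repeated configs give identical
    rows.
    """
    if len(configs) < 2:
        raise ValueError("need at least two method configurations to compare")
    rows = []
    for name, est in configs.items():
        run = type(est)(**est.get_params())
        run.fit(uniques)
        stats = otu_stats(run.otus_)
        rows.append(
            {
                "method": name,
                "n_otus": stats.n_otus,
                "largest_otu_size": stats.largest_otu_size,
                "singleton_fraction": stats.singleton_fraction,
                "singleton_tripleton_fraction": stats.singleton_tripleton_fraction,
            }
        )
    return pd.DataFrame(rows)
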