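"""Synthetic template pools and error-bearing amplicon reads.

Emulates defined-template pyrosequencing experiments: a pool of known
template sequences (e.g. 43 plasmid clones, all more than 6% apart) is
"sequenced" with a per-base error process whose defaults match measured
per-base amplicon error rates of roughly 0.002-0.004 (midpoint 0.003).
A small fraction of reads draws all rates multiplied — the heavy tail of
multi-error reads that pyrosequencing produces when beads fall out of
phase — so the number of reads with three or more errors exceeds the
binomial expectation, as observed on real instruments.

Error positions are independent across reads and positions.  Real
pyrosequencing error recurs at specific positions (homopolymer tracts),
so real error variants are shared between reads far more often than
simulated ones; see the methods note for what this means for spurious-OTU
counts.  Ground truth (source template and event count per read) is
recorded for every read.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .pwdist import AlignScoring, pair_distance
from .seqio import Read

__all__ = [
    "ErrorModel",
    "SimTruth",
    "simulate_templates",
    "simulate_reads",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ErrorModel:
    """Per-base error process for simulated reads.

    ``sub_rate`` is the substitution probability per template base;
    ``ins_rate``/``del_rate`` are per-base probabilities of an insertion
    or deletion *event* (event lengths are geometric(0.5), capped at 5).
    A ``heavy_fraction`` of reads multiplies every rate by
    ``heavy_multiplier``.  Defaults sum to a 0.003 per-base event rate
    for ordinary reads.
    """

    sub_rate: float = 0.0025
    ins_rate: float = 0.00025
    del_rate: float = 0.00025
    heavy_fraction: float = 0.01
    heavy_multiplier: float = 10.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate", "heavy_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.heavy_multiplier < 0:
            raise ValueError("heavy_multiplier must be non-negative")


@dataclass
class SimTruth:
    """Ground truth for a simulated read set.

    ``per_read`` has one row per emitted read (read_id, template_id,
    n_errors, heavy); ``template_abundance`` maps template id to its true
    read count.
    """

    per_read: pd.DataFrame
    template_abundance: pd.Series

    def write_tsv(self, path) -> None:
        self.per_read.to_csv(path, sep="\t", index=False)


def simulate_templates(
    k: int,
    length: int = 60,
    min_pairwise_dist: float = 0.06,
    seed: Optional[int] = None,
    scoring: Optional[AlignScoring] = None,
    max_tries_per_template: int = 1000,
) -> list[Read]:
    """Random template pool with a minimum pairwise distance.

    Candidates are drawn uniformly over ACGT and accepted only if their
    quickdist to every already-accepted template is at least
    ``min_pairwise_dist`` (rejection sampling); deterministic under seed.
    """
    if k < 1:
        raise ValueError("need at least one template")
    rng = np.random.default_rng(seed)
    scoring = scoring or AlignScoring()
    templates: list[str] = []
    tries = 0
    budget = max_tries_per_template * k
    while len(templates) < k:
        if tries >= budget:
            raise RuntimeError(
                f"could not place {k} templates at min distance "
                f"{min_pairwise_dist} within {budget} draws"
            )
        tries += 1
        cand = "".join(rng.choice(_BASES, size=length))
        if all(
            pair_distance(cand, t, scoring) >= min_pairwise_dist
            for t in templates
        ):
            templates.append(cand)
    width = len(str(k))
    return [
        Read(id=f"template_{i + 1:0{width}d}", bases=t)
        for i, t in enumerate(templates)
    ]


def _mutate(template: str, rng: np.random.Generator, sub: float,
            ins: float, dele: float) -> tuple[str, int]:
    """Apply per-base substitutions and indel events; returns (seq, events)."""
    out: list[str] = []
    events = 0
    i = 0
    L = len(template)
    while i < L:
        r = rng.random()
        if r < dele:
            # deletion event: remove a run of geometric(0.5) bases, max 5
            run = min(int(rng.geometric(0.5)), 5, L - i)
            events += 1
            i += run
            continue
        base = template[i]
        if rng.random() < sub:
            choices = [b for b in "ACGT" if b != base]
            base = choices[rng.integers(0, 3)]
            events += 1
        out.append(base)
        if rng.random() < ins:
            run = min(int(rng.geometric(0.5)), 5)
            out.extend(rng.choice(_BASES, size=run))
            events += 1
        i += 1
    return "".join(out), events


def simulate_reads(
    templates: Sequence[Read],
    abundances: Optional[Sequence[float]] = None,
    n: int = 10000,
    error_model: ErrorModel = ErrorModel(),
    quality: int = 35,
    seed: Optional[int] = None,
) -> tuple[list[Read], SimTruth]:
    """Draw reads from a template pool under the error model.

    Each read samples a template according to ``abundances`` (uniform by
    default), then substitutions and indel events are applied base by
    base; heavy reads use multiplied rates.  Constant quality scores
    (default 35, above the usual filtering threshold) are attached.  The
    seed argument overrides ``error_model.seed`` when given.
    """
    if n < 1:
        raise ValueError("need at least one read")
    if not templates:
        raise ValueError("template pool is empty")
    k = len(templates)
    if abundances is None:
        p = np.full(k, 1.0 / k)
    else:
        p = np.asarray(abundances, dtype=float)
        if p.shape != (k,):
            raise ValueError("one abundance per template required")
        if abs(p.sum() - 1.0) > 1e-8:
            raise ValueError(f"abundances sum to {p.sum()}, expected 1")
    use_seed = seed if seed is not None else error_model.seed
    rng = np.random.default_rng(use_seed)
    tidx = rng.choice(k, size=n, p=p)
    heavy = rng.random(n) < error_model.heavy_fraction
    reads: list[Read] = []
    rows = []
    width = len(str(n))
    for r in range(n):
        tpl = templates[tidx[r]]
        mult = error_model.heavy_multiplier if heavy[r] else 1.0
        seq, events = _mutate(
            tpl.bases, rng,
            min(1.0, error_model.sub_rate * mult),
            min(1.0, error_model.ins_rate * mult),
            min(1.0, error_model.del_rate * mult),
        )
        if not seq:  # total deletion is possible only at extreme rates
            seq = tpl.bases[:1]
        rid = f"read_{r + 1:0{width}d}"
        reads.append(Read(id=rid, bases=seq, quals=[quality] * len(seq)))
        rows.append((rid, tpl.id, events, bool(heavy[r])))
    per_read = pd.DataFrame(rows, columns=["read_id", "template_id",
                                           "n_errors", "heavy"])
    abundance = per_read["template_id"].value_counts().reindex(
        [t.id for t in templates], fill_value=0
    )
    abundance.name = "true_count"
    return reads, SimTruth(per_read=per_read, template_abundance=abundance)
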