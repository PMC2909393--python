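"""Quality, primer, coverage and contamination filters for amplicon reads.

The read-level filters run in a fixed order so every rejected read gets a
single, deterministic reason code: ambiguous bases, then exact forward
primer/barcode match, then average quality, then a recognizable reverse
primer.  Primer and barcode bases are trimmed from passing reads.

Two further filters operate on dereplicated sequences against reference
sets: a coverage filter removing sequences whose best reference alignment
spans less than a fraction (default 80%) of their length — which catches
non-target amplification products, gross-error reads and most chimeras —
and a contamination filter removing sequences matching a non-target
reference substantially better (default 10 identity points) than the
nearest template.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

from .pwdist import AlignScoring, nw_align, pair_distance
from .seqio import Read, UniqueSeq

__all__ = [
    "FilterConfig",
    "FilterReport",
    "ConfigurationError",
    "filter_reads",
    "coverage_filter",
    "contamination_filter",
]

REASONS = (
    "ambiguous_base",
    "no_forward_primer",
    "low_quality",
    "no_reverse_primer",
    "low_coverage",
    "no_reference_match",
    "contamination",
)


class ConfigurationError(ValueError):
    """Raised when a filter configuration cannot be applied to the input."""


@dataclass(frozen=True)
class FilterConfig:
    """Read-filter settings.

    ``forward_primers`` are full barcoded primer strings that must match
    the read start exactly; the reverse primer may differ by up to
    ``reverse_max_mismatch`` substitutions at the read's 3' end.  Reads
    with mean phred quality below ``min_avg_quality`` (default 30) are
    discarded; set it to None to disable quality checking (e.g. for reads
    without quality scores).  By default the mean is taken over the full
    read, before primer trimming; set ``quality_after_trim`` to compute
    it on the trimmed read instead.
    """

    forward_primers: tuple[str, ...] = ()
    reverse_primer: Optional[str] = None
    reverse_max_mismatch: int = 1
    min_avg_quality: Optional[float] = 30.0
    quality_after_trim: bool = False
    min_coverage_fraction: float = 0.80
    contamination_margin: float = 0.10
    chimera_sequences: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 < self.min_coverage_fraction <= 1.0):
            raise ValueError("min_coverage_fraction must be in (0, 1]")
        if self.contamination_margin < 0:
            raise ValueError("contamination_margin must be non-negative")
        if self.reverse_max_mismatch < 0:
            raise ValueError("reverse_max_mismatch must be non-negative")


@dataclass
class FilterReport:
    """Partition of the input reads into passed and rejected."""

    passed: list[Read]
    rejected: list[tuple[Read, str]]

    @property
    def reason_counts(self) -> Counter:
        return Counter(reason for _, reason in self.rejected)

    @property
    def pass_fraction(self) -> float:
        total = len(self.passed) + len(self.rejected)
        return len(self.passed) / total if total else 0.0

    def summary(self) -> str:
        lines = [
            f"input reads\t{len(self.passed) + len(self.rejected)}",
            f"passed\t{len(self.passed)}",
        ]
        for reason in REASONS:
            n = self.reason_counts.get(reason, 0)
            if n:
                lines.append(f"rejected:{reason}\t{n}")
        lines.append(f"pass_fraction\t{self.pass_fraction:.4f}")
        return "\n".join(lines)

    def write_rejects(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\treason\n")
            for read, reason in self.rejected:
                fh.write(f"{read.id}\t{reason}\n")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _check_read(read: Read, config: FilterConfig) -> tuple[Optional[Read], Optional[str]]:
    if "N" in read.bases:
        return None, "ambiguous_base"
    start = None
    for primer in config.forward_primers:
        if read.bases.startswith(primer):
            start = len(primer)
            break
    if config.forward_primers and start is None:
        return None, "no_forward_primer"
    start = start or 0
    if config.min_avg_quality is not None and not config.quality_after_trim:
        if read.quals is None:
            raise ConfigurationError(
                f"read {read.id!r} has no quality scores but a minimum "
                "average quality is configured; set min_avg_quality=None "
                "to disable quality checking"
            )
        if read.mean_quality < config.min_avg_quality:
            return None, "low_quality"
    end = len(read.bases)
    if config.reverse_primer is not None:
        rp = config.reverse_primer
        if end - start < len(rp) + 1:
            return None, "no_reverse_primer"
        tail = read.bases[end - len(rp):]
        if _hamming(tail, rp) > config.reverse_max_mismatch:
            return None, "no_reverse_primer"
        end -= len(rp)
    trimmed = Read(
        id=read.id,
        bases=read.bases[start:end],
        quals=read.quals[start:end] if read.quals is not None else None,
    )
    if config.min_avg_quality is not None and config.quality_after_trim:
        if trimmed.quals is None:
            raise ConfigurationError(
                f"read {read.id!r} has no quality scores but a minimum "
                "average quality is configured"
            )
        if trimmed.mean_quality < config.min_avg_quality:
            return None, "low_quality"
    return trimmed, None


def filter_reads(reads: Sequence[Read], config: FilterConfig) -> FilterReport:
    """Apply the read-level filters; verdicts are per-read, order-free.

    Checks run in the fixed order ambiguous bases, forward primer,
    average quality, reverse primer; the first failing check supplies the
    rejection reason.  Passing reads are returned with primer and barcode
    bases trimmed.
    """
    passed: list[Read] = []
    rejected: list[tuple[Read, str]] = []
    for read in reads:
        trimmed, reason = _check_read(read, config)
        if reason is None:
            passed.append(trimmed)
        else:
            rejected.append((read, reason))
    return FilterReport(passed=passed, rejected=rejected)


def _shares_kmer(seq: str, ref: str, k: int) -> bool:
    kmers = {seq[i:i + k] for i in range(len(seq) - k + 1)}
    return any(ref[i:i + k] in kmers for i in range(len(ref) - k + 1))


def _alignment_span(seq: str, ref: str, scoring: AlignScoring) -> float:
    """Fraction of ``seq`` inside the best-scoring aligned segment.

    The global alignment's columns are rescored with blastn-like local
    parameters (+1 match, -2 mismatch, gap open 5 / extend 2) and the
    maximum-sum contiguous window located (Kadane), approximating the
    span a local aligner such as BLAST would report: low-identity flanks
    score negative and drop out of the window.
    """
    al = nw_align(seq, ref, scoring)
    a, b = al.aligned_a, al.aligned_b
    col_scores = []
    for t in range(len(a)):
        if a[t] == "-" or b[t] == "-":
            opening = t == 0 or (a[t - 1] != "-" and b[t - 1] != "-") or (
                (a[t] == "-") != (a[t - 1] == "-")
            )
            col_scores.append(-5.0 if opening else -2.0)
        elif a[t] == b[t]:
            col_scores.append(1.0)
        else:
            col_scores.append(-2.0)
    best = run = 0.0
    best_lo = best_hi = lo = 0
    for t, s in enumerate(col_scores):
        if run <= 0:
            run = s
            lo = t
        else:
            run += s
        if run > best:
            best = run
            best_lo, best_hi = lo, t + 1
    covered = sum(1 for t in range(best_lo, best_hi) if a[t] != "-")
    return covered / len(seq)


def coverage_filter(
    uniques: Sequence[UniqueSeq],
    reference_set: Sequence[tuple[str, str]],
    scoring: Optional[AlignScoring] = None,
    min_coverage_fraction: float = 0.80,
    k: int = 6,
) -> tuple[list[UniqueSeq], list[tuple[UniqueSeq, str]]]:
    """Remove sequences without a spanning reference alignment.

    References sharing at least one k-mer with the query are candidates;
    a query with no candidate at all is removed as ``no_reference_match``.
    Otherwise its best-scoring candidate alignment must span at least
    ``min_coverage_fraction`` of the query's length (``low_coverage``
    when it does not).
    """
    if not reference_set:
        raise ValueError("reference set is empty")
    scoring = scoring or AlignScoring()
    kept: list[UniqueSeq] = []
    removed: list[tuple[UniqueSeq, str]] = []
    for u in uniques:
        candidates = [r for r in reference_set if _shares_kmer(u.sequence, r[1], k)]
        if not candidates:
            removed.append((u, "no_reference_match"))
            continue
        best = max(candidates, key=lambda r: nw_align(u.sequence, r[1], scoring).score)
        if _alignment_span(u.sequence, best[1], scoring) < min_coverage_fraction:
            removed.append((u, "low_coverage"))
        else:
            kept.append(u)
    return kept, removed


def contamination_filter(
    uniques: Sequence[UniqueSeq],
    template_set: Sequence[tuple[str, str]],
    nontarget_set: Sequence[tuple[str, str]],
    scoring: Optional[AlignScoring] = None,
    contamination_margin: float = 0.10,
) -> tuple[list[UniqueSeq], list[tuple[UniqueSeq, str]]]:
    """Remove sequences matching non-target references markedly better.

    Identity is 1 - quickdist.  A sequence is contamination when its best
    non-target identity exceeds its best template identity by at least
    the margin (an absolute difference in fractional identity).
    """
    if not template_set or not nontarget_set:
        raise ValueError("template and non-target sets must be non-empty")
    scoring = scoring or AlignScoring()
    kept: list[UniqueSeq] = []
    removed: list[tuple[UniqueSeq, str]] = []
    for u in uniques:
        t_id = max(1.0 - pair_distance(u.sequence, t[1], scoring)
                   for t in template_set)
        n_id = max(1.0 - pair_distance(u.sequence, s[1], scoring)
                   for s in nontarget_set)
        if n_id - t_id >= contamination_margin:
            removed.append((u, "contamination"))
        else:
            kept.append(u)
    return kept, removed
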