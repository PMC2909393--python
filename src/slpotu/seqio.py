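"""Sequence input/output and dereplication.

Reads are parsed from FASTA (optionally with a paired ``.qual`` file) or
FASTQ via Biopython, validated against the DNA alphabet ``{A,C,G,T,N}``,
and collapsed into abundance-sorted unique sequences — the unit all
downstream distance computation and clustering operates on.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Read",
    "UniqueSeq",
    "ParseError",
    "read_sequences",
    "write_fasta",
    "write_qual",
    "write_fastq",
    "dereplicate",
    "write_names",
    "read_names",
    "write_count_table",
]

_ALPHABET = frozenset("ACGTN")


class ParseError(ValueError):
    """Raised when a sequence record violates the expected format."""


@dataclass
class Read:
    """A single sequencing read.

    Parameters
    ----------
    id : str
        Record identifier.
    bases : str
        Uppercase DNA over ``{A,C,G,T,N}``; non-empty.
    quals : list of int, optional
        Per-base phred quality scores, same length as ``bases``.
    """

    id: str
    bases: str
    quals: Optional[list[int]] = None

    def __post_init__(self) -> None:
        self.bases = self.bases.upper()
        if not self.bases:
            raise ParseError(f"read {self.id!r}: empty sequence")
        bad = set(self.bases) - _ALPHABET
        if bad:
            raise ParseError(
                f"read {self.id!r}: invalid characters {sorted(bad)!r} "
                "(alphabet is A,C,G,T,N)"
            )
        if self.quals is not None and len(self.quals) != len(self.bases):
            raise ParseError(
                f"read {self.id!r}: {len(self.quals)} quality values for "
                f"{len(self.bases)} bases"
            )

    @property
    def mean_quality(self) -> float:
        if self.quals is None:
            raise ValueError(f"read {self.id!r} has no quality scores")
        return sum(self.quals) / len(self.quals)


@dataclass
class UniqueSeq:
    """A dereplicated sequence with its read count and member read ids."""

    sequence: str
    count: int
    member_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.member_ids and len(self.member_ids) != self.count:
            raise ValueError(
                f"count {self.count} != number of member ids "
                f"{len(self.member_ids)}"
            )

    @property
    def id(self) -> str:
        """Representative read id (first member)."""
        return self.member_ids[0] if self.member_ids else self.sequence


def read_sequences(
    fasta_path: str | os.PathLike,
    qual_path_or_fastq: Optional[str | os.PathLike] = None,
) -> list[Read]:
    """Read sequences from FASTA (plus optional QUAL) or FASTQ.

    If ``fasta_path`` ends in ``.fastq``/``.fq`` it is parsed as FASTQ and
    the second argument must be omitted.  Otherwise the file is parsed as
    FASTA and ``qual_path_or_fastq``, when given, as a mothur-style QUAL
    file whose record ids must match the FASTA one-to-one, in order.
    """
    fasta_path = os.fspath(fasta_path)
    if fasta_path.endswith((".fastq", ".fq")):
        if qual_path_or_fastq is not None:
            raise ValueError("FASTQ input does not take a separate quality file")
        return _read_fastq(fasta_path)
    reads = []
    for rec in SeqIO.parse(fasta_path, "fasta"):
        reads.append(Read(id=rec.id, bases=str(rec.seq)))
    if qual_path_or_fastq is not None:
        quals = list(SeqIO.parse(os.fspath(qual_path_or_fastq), "qual"))
        if len(quals) != len(reads):
            raise ParseError(
                f"{len(reads)} FASTA records but {len(quals)} QUAL records"
            )
        for read, qrec in zip(reads, quals):
            if read.id != qrec.id:
                raise ParseError(
                    f"FASTA/QUAL id mismatch: {read.id!r} vs {qrec.id!r}"
                )
            read.quals = list(qrec.letter_annotations["phred_quality"])
            if len(read.quals) != len(read.bases):
                raise ParseError(
                    f"read {read.id!r}: quality length {len(read.quals)} "
                    f"!= sequence length {len(read.bases)}"
                )
    return reads


def _read_fastq(path: str) -> list[Read]:
    reads = []
    for rec in SeqIO.parse(path, "fastq"):
        reads.append(
            Read(
                id=rec.id,
                bases=str(rec.seq),
                quals=list(rec.letter_annotations["phred_quality"]),
            )
        )
    return reads


def _as_records(reads: Iterable[Read], with_qual: bool) -> list[SeqRecord]:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.bases), id=r.id, description="")
        if with_qual:
            if r.quals is None:
                raise ValueError(f"read {r.id!r} has no quality scores")
            rec.letter_annotations["phred_quality"] = list(r.quals)
        records.append(rec)
    return records


def write_fasta(reads: Iterable[Read], path: str | os.PathLike, wrap: int = 80) -> None:
    """Write reads as FASTA, line-wrapped at ``wrap`` columns."""
    writer = SeqIO.FastaIO.FastaWriter(os.fspath(path), wrap=wrap)
    writer.write_file(_as_records(reads, with_qual=False))


def write_qual(reads: Iterable[Read], path: str | os.PathLike) -> None:
    SeqIO.write(_as_records(reads, with_qual=True), os.fspath(path), "qual")


def write_fastq(reads: Iterable[Read], path: str | os.PathLike) -> None:
    SeqIO.write(_as_records(reads, with_qual=True), os.fspath(path), "fastq")


def dereplicate(reads: Sequence[Read]) -> list[UniqueSeq]:
    """Collapse identical reads into unique sequences with counts.

    Output is sorted by count descending, ties broken lexicographically by
    sequence, so the ordering is a total order and identical inputs always
    produce identical output.  The sum of counts equals ``len(reads)``.
    """
    if not reads:
        raise ValueError("cannot dereplicate an empty read set")
    by_seq: dict[str, list[str]] = {}
    for r in reads:
        by_seq.setdefault(r.bases, []).append(r.id)
    uniques = [
        UniqueSeq(sequence=seq, count=len(ids), member_ids=ids)
        for seq, ids in by_seq.items()
    ]
    uniques.sort(key=lambda u: (-u.count, u.sequence))
    return uniques


def is_abundance_sorted(uniques: Sequence[UniqueSeq]) -> bool:
    """Check count-descending, ties-lexicographic ordering."""
    keys = [(-u.count, u.sequence) for u in uniques]
    return all(keys[i] <= keys[i + 1] for i in range(len(keys) - 1))


def write_names(uniques: Iterable[UniqueSeq], path: str | os.PathLike) -> None:
    """Write a mothur-dialect names file: representative id TAB member ids."""
    with open(path, "w") as fh:
        for u in uniques:
            ids = u.member_ids or [u.id]
            fh.write(f"{ids[0]}\t{','.join(ids)}\n")


def read_names(path: str | os.PathLike) -> dict[str, list[str]]:
    """Read a names file back into representative -> member-id lists."""
    mapping: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected two tab-separated fields")
            mapping[parts[0]] = parts[1].split(",")
    return mapping


def write_count_table(uniques: Iterable[UniqueSeq], path: str | os.PathLike) -> None:
    """Write a two-column TSV of representative id and read count."""
    with open(path, "w") as fh:
        fh.write("representative\tcount\n")
        for u in uniques:
            fh.write(f"{u.id}\t{u.count}\n")
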