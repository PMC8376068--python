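"""Readers/writers for FASTQ, FASTA and SAM plus the internal record types.

All coordinates are 0-based half-open internally; reports use 1-based
inclusive positions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Optional

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

PHRED_OFFSET = 33
PHRED_MAX = 93

_VALID_ROLES = ("rrna", "virus", "target_db")


class FastqParseError(ValueError):
    """Malformed FASTQ record; message names the failing record index."""


class FastaParseError(ValueError):
    pass


@dataclass
class Read:
    """A single-end sequencing read.

    ``lineage`` records excisions applied to ancestors of this read as
    ``(source_read_id, (cut_start, cut_end))`` tuples, 0-based half-open in
    the coordinates of the source read the cut was applied to.
    """

    read_id: str
    bases: str
    quals: list[int]
    lineage: list[tuple[str, tuple[int, int]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.bases):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.bases)} bases but {len(self.quals)} quality values"
            )
        if any(q < 0 or q > PHRED_MAX for q in self.quals):
            raise ValueError(f"read {self.read_id!r}: Phred score outside [0, {PHRED_MAX}]")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def qual_string(self) -> str:
        return "".join(chr(q + PHRED_OFFSET) for q in self.quals)


@dataclass
class ReferenceSeq:
    """One entry of a reference set (rRNA database, virus genome, target DB)."""

    ref_id: str
    bases: str
    role: str = "target_db"

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"reference {self.ref_id!r}: empty sequence")
        if self.role not in _VALID_ROLES:
            raise ValueError(f"reference {self.ref_id!r}: unknown role {self.role!r}")

    def __len__(self) -> int:
        return len(self.bases)


def read_fastq(path: str | Path) -> Iterator[Read]:
    """Stream Phred+33 single-end FASTQ records in file order.

    Bases are uppercased. Malformed records raise :class:`FastqParseError`
    naming the (0-based) record index.
    """
    with open(path) as handle:
        it = FastqGeneralIterator(handle)
        index = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqParseError(f"malformed FASTQ record at index {index}: {exc}") from exc
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"malformed FASTQ record at index {index}: sequence/quality length mismatch"
                )
            quals = [ord(c) - PHRED_OFFSET for c in qual]
            if any(q < 0 or q > PHRED_MAX for q in quals):
                raise FastqParseError(
                    f"malformed FASTQ record at index {index}: quality outside Phred+33 range"
                )
            yield Read(read_id=title.split()[0] if title else "", bases=seq.upper(), quals=quals)
            index += 1


def write_fastq(reads: Iterable[Read], path: str | Path) -> int:
    """Write reads as Phred+33 FASTQ. Returns the number of records written.

    Cured reads already carry their ``|cut:<start>-<end>/<L|R|M>`` id suffix
    (applied at excision time), so ids are emitted verbatim.
    """
    n = 0
    with open(path, "w") as out:
        for read in reads:
            out.write(f"@{read.read_id}\n{read.bases}\n+\n{read.qual_string}\n")
            n += 1
    return n


def read_fasta(path: str | Path, role: str = "target_db") -> list[ReferenceSeq]:
    """Read a multi-FASTA file; ids must be unique within the file."""
    seqs: list[ReferenceSeq] = []
    seen: set[str] = set()
    with open(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            ref_id = title.split()[0]
            if ref_id in seen:
                raise FastaParseError(f"duplicate FASTA id {ref_id!r} in {path}")
            seen.add(ref_id)
            seqs.append(ReferenceSeq(ref_id=ref_id, bases=seq.upper(), role=role))
    return seqs


def write_fasta(seqs: Iterable[ReferenceSeq], path: str | Path, width: int = 70) -> int:
    n = 0
    with open(path, "w") as out:
        for seq in seqs:
            out.write(f">{seq.ref_id}\n")
            for i in range(0, len(seq.bases), width):
                out.write(seq.bases[i : i + width] + "\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# SAM ingestion
# ---------------------------------------------------------------------------

class SamAlignment(NamedTuple):
    read: Read
    cigar: Optional[str]  # None for unmapped records
    flags: int
    ref_id: Optional[str]
    ref_pos: Optional[int]  # 0-based leftmost reference coordinate


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

# CIGAR ops that consume bases of the read (query)
_READ_OPS = frozenset("MIS=X")


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise ValueError(f"invalid CIGAR string {cigar!r}")
    return ops


def cigar_read_blocks(cigar: str) -> list[tuple[str, int, int]]:
    """Read-coordinate blocks ``(op, start, end)`` for query-consuming ops.

    The returned blocks exactly partition ``[0, read_len)``. Hard clips are
    rejected because the clipped bases are not recoverable from the record.
    """
    blocks: list[tuple[str, int, int]] = []
    pos = 0
    for n, op in parse_cigar(cigar):
        if op == "H":
            raise ValueError("hard-clipped record: clipped bases are unrecoverable")
        if op in _READ_OPS:
            blocks.append((op, pos, pos + n))
            pos += n
    return blocks


def aligned_read_span(cigar: str) -> tuple[int, int]:
    """Smallest span [start, end) on the read covering all aligned (M/=/X/I) blocks."""
    starts = [s for op, s, _ in cigar_read_blocks(cigar) if op != "S"]
    ends = [e for op, _, e in cigar_read_blocks(cigar) if op != "S"]
    if not starts:
        raise ValueError(f"CIGAR {cigar!r} has no aligned block")
    return min(starts), max(ends)


def read_sam_alignments(path: str | Path) -> Iterator[SamAlignment]:
    """Stream SAM/BAM records produced by an external aligner.

    Yields mapped and unmapped records; secondary and supplementary records
    are skipped; hard-clipped records raise (bases unrecoverable). A mapped
    record whose reference has no SQ header line is an error.
    """
    import pysam

    save = pysam.set_verbosity(0)
    try:
        handle = pysam.AlignmentFile(str(path), check_sq=False)
    finally:
        pysam.set_verbosity(save)
    known_refs = set(handle.references)
    with handle:
        for rec in handle:
            if rec.is_secondary or rec.is_supplementary:
                continue
            if rec.cigarstring and "H" in rec.cigarstring:
                raise ValueError(
                    f"record {rec.query_name!r} is hard-clipped; bases unrecoverable"
                )
            seq = rec.query_sequence
            if seq is None:
                raise ValueError(f"record {rec.query_name!r} has no sequence")
            if rec.query_qualities is not None:
                quals = list(rec.query_qualities)
            else:
                quals = [30] * len(seq)  # '*' quality column
            read = Read(read_id=rec.query_name, bases=seq.upper(), quals=quals)
            if rec.is_unmapped:
                yield SamAlignment(read, None, rec.flag, None, None)
            else:
                if rec.reference_name not in known_refs:
                    raise ValueError(
                        f"mapped record {rec.query_name!r} references {rec.reference_name!r} "
                        "with no SQ header line"
                    )
                yield SamAlignment(read, rec.cigarstring, rec.flag, rec.reference_name, rec.reference_start)
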