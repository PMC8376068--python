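"""Local alignment primitive: exact affine-gap Smith-Waterman on both strands.

This is the in-process stand-in for the external boundary-finding aligner:
it always returns the optimal local score (no heuristics), so chimera
boundaries are placed at the exact end of the rRNA-matching stretch.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

import numpy as np

from ._sw import sw_align
from .io_formats import Read, ReferenceSeq

_ENCODE_TABLE = bytes.maketrans(b"ACGTNacgtn", bytes([0, 1, 2, 3, 4, 0, 1, 2, 3, 4]))
_RC_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement; N maps to N. Involution: rc(rc(x)) == x."""
    return seq.translate(_RC_TABLE)[::-1]


def encode(seq: str) -> np.ndarray:
    codes = np.frombuffer(seq.encode().translate(_ENCODE_TABLE), dtype=np.uint8)
    if codes.size and codes.max() > 4:
        bad = chr(seq.encode()[int(np.argmax(codes > 4))])
        raise ValueError(f"non-ACGTN base {bad!r} in sequence")
    return codes


@dataclass(frozen=True)
class ScoringScheme:
    """BLASTN-like defaults; penalties are positive magnitudes."""

    match: int = 2
    mismatch: int = 3
    gap_open: int = 5
    gap_extend: int = 2

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match reward must be > 0")
        if min(self.mismatch, self.gap_open, self.gap_extend) < 0:
            raise ValueError("penalties must be >= 0")


DEFAULT_SCORING = ScoringScheme()
DEFAULT_MIN_SCORE = 30  # ~15 matched bases at +2/match


@dataclass(frozen=True)
class LocalAlignment:
    """Best local alignment of one read against one reference.

    ``read_span`` is always in the read's forward orientation; for strand
    '-' it is the mirror of the span found on the reverse-complemented read.
    """

    read_id: str
    ref_id: str
    read_span: tuple[int, int]
    ref_span: tuple[int, int]
    strand: str  # '+' or '-'
    score: int
    identity: float
    read_len: int
    # one char per alignment column in forward-read order:
    # M match, X mismatch, I gap-in-ref (consumes read), D gap-in-read
    column_ops: str = ""

    @property
    def aligned_read_frac(self) -> float:
        return (self.read_span[1] - self.read_span[0]) / self.read_len

    def __post_init__(self) -> None:
        rs, re_ = self.read_span
        if not (0 <= rs < re_ <= self.read_len):
            raise ValueError(f"read_span {self.read_span} invalid for read length {self.read_len}")
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError(f"identity {self.identity} outside [0, 1]")


QueryLike = Union[Read, ReferenceSeq, str]
RefLike = Union[ReferenceSeq, str]


def _seq_and_id(obj: QueryLike, fallback: str) -> tuple[str, str]:
    if isinstance(obj, Read):
        return obj.bases, obj.read_id
    if isinstance(obj, ReferenceSeq):
        return obj.bases, obj.ref_id
    return obj, fallback


def local_align(
    query: QueryLike,
    ref: RefLike,
    scoring: ScoringScheme = DEFAULT_SCORING,
    min_score: int = DEFAULT_MIN_SCORE,
) -> Optional[LocalAlignment]:
    """Maximum-scoring local alignment over both strands, or None below min_score.

    Co-optimal ties are broken deterministically: smallest read start, then
    smallest reference start, then '+' strand.
    """
    qseq, qid = _seq_and_id(query, "query")
    rseq, rid = _seq_and_id(ref, "ref")
    if not qseq or not rseq:
        raise ValueError("empty query or reference")

    qcodes = encode(qseq)
    rcodes = encode(rseq)
    L = len(qseq)

    candidates = []
    score, qs, qe, rs, re_, matches, cols, path = sw_align(
        qcodes, rcodes, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    )
    if score >= min_score:
        # path is in traceback (end -> start) order; forward-read order reverses it
        ops = _path_to_ops(path[::-1])
        candidates.append((score, qs, rs, 0, (qs, qe), (rs, re_), "+", matches, cols, ops))

    rc_codes = encode(reverse_complement(qseq))
    score, qs, qe, rs, re_, matches, cols, path = sw_align(
        rc_codes, rcodes, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    )
    if score >= min_score:
        # mirror the span found on rc(query) back onto the forward read;
        # traceback order on rc(query) is already forward-read order
        fwd_span = (L - qe, L - qs)
        ops = _path_to_ops(path)
        candidates.append((score, fwd_span[0], rs, 1, fwd_span, (rs, re_), "-", matches, cols, ops))

    if not candidates:
        return None
    # sort key: score desc, read_start asc, ref_start asc, '+' before '-'
    best = min(candidates, key=lambda c: (-c[0], c[1], c[2], c[3]))
    score, _, _, _, read_span, ref_span, strand, matches, cols, ops = best
    return LocalAlignment(
        read_id=qid,
        ref_id=rid,
        read_span=read_span,
        ref_span=ref_span,
        strand=strand,
        score=score,
        identity=matches / cols if cols else 0.0,
        read_len=L,
        column_ops=ops,
    )


_OP_CHARS = "MXID"


def _path_to_ops(path) -> str:
    return "".join(_OP_CHARS[p] for p in path)


_READ_OPS = frozenset("MXI")  # alignment columns that consume read bases
_REF_OPS = frozenset("MXD")


def slice_alignment_columns(aln: LocalAlignment, left: int, right: int) -> LocalAlignment:
    """Restrict an alignment to the column range [left, right) of its
    forward-read-order column_ops, adjusting read/ref spans and identity."""
    ops = aln.column_ops
    if left == 0 and right == len(ops):
        return aln
    if not (0 <= left < right <= len(ops)):
        raise ValueError(f"column range [{left}, {right}) invalid for {len(ops)} columns")

    def consumed(segment: str, opset: frozenset) -> int:
        return sum(1 for c in segment if c in opset)

    read_lo = consumed(ops[:left], _READ_OPS)
    read_hi = consumed(ops[right:], _READ_OPS)
    ref_lo = consumed(ops[:left], _REF_OPS)
    ref_hi = consumed(ops[right:], _REF_OPS)
    rs, re_ = aln.read_span
    fs, fe = aln.ref_span
    kept = ops[left:right]
    if aln.strand == "+":
        new_ref_span = (fs + ref_lo, fe - ref_hi)
    else:
        # forward-read order runs against the reference for '-' alignments
        new_ref_span = (fs + ref_hi, fe - ref_lo)
    return replace(
        aln,
        read_span=(rs + read_lo, re_ - read_hi),
        ref_span=new_ref_span,
        identity=kept.count("M") / len(kept),
        column_ops=kept,
    )


def polish_boundaries(aln: LocalAlignment, window: int = 10) -> Optional[LocalAlignment]:
    """Trim alignment ends until both terminate in ``window`` consecutive
    matching columns.

    A maximum-scoring local alignment can extend a few net-positive columns
    past the true boundary of a shared stretch by chance; requiring a clean
    match run at each end removes those ragged extensions. Returns None when
    no clean run exists (the hit is too noisy to place a boundary).
    """
    ops = aln.column_ops
    if window <= 0 or not ops:
        return aln
    left, right = 0, len(ops)
    while right > left:
        seg = ops[left:right]
        w = min(window, len(seg))
        head = seg[:w]
        if head != "M" * w:
            left += max(i for i, c in enumerate(head) if c != "M") + 1
            continue
        tail = seg[-w:]
        if tail != "M" * w:
            right = right - w + min(i for i, c in enumerate(tail) if c != "M")
            continue
        break
    if right <= left:
        return None
    return slice_alignment_columns(aln, left, right)


def best_hit(
    query: QueryLike,
    refs: Sequence[ReferenceSeq],
    scoring: ScoringScheme = DEFAULT_SCORING,
    min_score: int = DEFAULT_MIN_SCORE,
) -> Optional[LocalAlignment]:
    """Best local_align over a reference set.

    Ties broken by (score desc, reference input order asc, read start asc).
    """
    if not refs:
        raise ValueError("refs must be non-empty")
    best: Optional[LocalAlignment] = None
    best_key: Optional[tuple] = None
    for idx, ref in enumerate(refs):
        hit = local_align(query, ref, scoring, min_score)
        if hit is None:
            continue
        key = (-hit.score, idx, hit.read_span[0])
        if best_key is None or key < best_key:
            best = hit
            best_key = key
    return best
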