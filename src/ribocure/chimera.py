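"""Classify reads against an rRNA reference set and excise rRNA moieties.

The cleanup core: reads are triaged into non-rRNA (passthrough), pure rRNA
(discarded) and chimeric; the rRNA-aligned segment of each chimeric read is
cut out and every sufficiently long remaining flank is kept as a "cured"
read. Cured reads are re-examined in subsequent rounds so that reads
carrying more than one rRNA moiety lose one moiety per round.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import re

from .alignment import (
    DEFAULT_MIN_SCORE,
    DEFAULT_SCORING,
    LocalAlignment,
    ScoringScheme,
    best_hit,
    polish_boundaries,
    slice_alignment_columns,
)
from .io_formats import Read, ReferenceSeq, SamAlignment, aligned_read_span

VERDICT_NON_RRNA = "non_rrna"
VERDICT_PURE_RRNA = "pure_rrna"
VERDICT_CHIMERIC = "chimeric"


@dataclass(frozen=True)
class CleanupConfig:
    # reads whose best rRNA alignment covers >= this fraction are pure rRNA
    rrna_fraction_threshold: float = 0.90
    # alignments below this identity are ignored (treated as non-rRNA)
    min_segment_identity: float = 0.80
    # excision flanks shorter than this are dropped, not emitted
    min_retained_length: int = 30
    max_rounds: int = 2
    scoring: ScoringScheme = DEFAULT_SCORING
    min_score: int = DEFAULT_MIN_SCORE
    triage_mode: str = "internal"  # or "sam_ingest"
    # boundary polish: shrink segment ends until they terminate in this many
    # consecutive matching columns, removing chance extensions of the local
    # alignment past the true fusion point; 0 disables
    boundary_match_window: int = 10
    # an interior region of >= this many read bases with no clean match run
    # marks the alignment as spanning two separate rRNA stretches; it is split
    # there and only the better side kept for this round; 0 disables
    split_gap_min_bases: int = 10

    def __post_init__(self) -> None:
        if not (0.0 < self.rrna_fraction_threshold <= 1.0):
            raise ValueError("rrna_fraction_threshold must be in (0, 1]")
        if self.min_retained_length < 1:
            raise ValueError("min_retained_length must be >= 1")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")
        if self.triage_mode not in ("internal", "sam_ingest"):
            raise ValueError(f"unknown triage_mode {self.triage_mode!r}")


@dataclass
class ChimeraCall:
    read_id: str
    verdict: str
    rrna_segments: list[LocalAlignment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.verdict not in (VERDICT_NON_RRNA, VERDICT_PURE_RRNA, VERDICT_CHIMERIC):
            raise ValueError(f"unknown verdict {self.verdict!r}")
        if (self.verdict == VERDICT_NON_RRNA) != (not self.rrna_segments):
            raise ValueError("non_rrna iff rrna_segments empty")
        spans = sorted(a.read_span for a in self.rrna_segments)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("rRNA segments overlap")


@dataclass
class RoundStats:
    round: int
    input: int
    pure_rrna_discarded: int
    chimeric_detected: int
    cured_emitted: int
    passthrough: int
    dropped_short: int

    def check(self) -> None:
        if self.input != self.pure_rrna_discarded + self.chimeric_detected + self.passthrough:
            raise AssertionError(f"round {self.round}: accounting invariant violated: {self}")


@dataclass
class CleanupResult:
    rounds: list[RoundStats]
    final_reads: list[Read]  # all passthrough + last-round cured reads
    calls: list[list[ChimeraCall]]  # per-round classifications
    discarded_pure: list[Read]


def split_chimeric_alignment(
    aln: LocalAlignment, min_gap_bases: int = 10, anchor_len: int = 10
) -> LocalAlignment:
    """Split an alignment that stitches two separate rRNA stretches together.

    When two rRNA moieties of a read happen to be colinear on one reference,
    a single gapped alignment can span them, absorbing the intervening
    non-rRNA read bases as insertions and chance matches and masking the
    chimera. Clean match runs of >= ``anchor_len`` columns are treated as
    anchors; if the region between two anchors consumes >= ``min_gap_bases``
    read bases, the alignment is cut there and the side with more matching
    columns kept (ties to the left). The other stretch is picked up in a
    later cleanup round.
    """
    if min_gap_bases <= 0:
        return aln
    anchor_re = re.compile("M{%d,}" % anchor_len)
    while True:
        ops = aln.column_ops
        anchors = [m.span() for m in anchor_re.finditer(ops)]
        if len(anchors) < 2:
            return aln
        worst = None
        for (_, e1), (s2, _) in zip(anchors, anchors[1:]):
            gap_read_bases = sum(1 for c in ops[e1:s2] if c in "MXI")
            if gap_read_bases >= min_gap_bases and (worst is None or gap_read_bases > worst[0]):
                worst = (gap_read_bases, e1, s2)
        if worst is None:
            return aln
        _, e1, s2 = worst
        if ops[:e1].count("M") >= ops[s2:].count("M"):
            aln = slice_alignment_columns(aln, 0, e1)
        else:
            aln = slice_alignment_columns(aln, s2, len(ops))


def classify_read(
    read: Read, rrna_refs: Sequence[ReferenceSeq], cfg: CleanupConfig = CleanupConfig()
) -> ChimeraCall:
    """Triage one read: non_rrna, pure_rrna or chimeric (one segment recorded)."""
    if len(read) < 1:
        raise ValueError("empty read")
    hit = best_hit(read, rrna_refs, cfg.scoring, cfg.min_score)
    if hit is not None:
        hit = split_chimeric_alignment(
            hit, cfg.split_gap_min_bases, max(cfg.boundary_match_window, 1)
        )
        hit = polish_boundaries(hit, cfg.boundary_match_window)
    if hit is None or hit.identity < cfg.min_segment_identity:
        return ChimeraCall(read.read_id, VERDICT_NON_RRNA)
    if hit.aligned_read_frac >= cfg.rrna_fraction_threshold:
        return ChimeraCall(read.read_id, VERDICT_PURE_RRNA, [hit])
    return ChimeraCall(read.read_id, VERDICT_CHIMERIC, [hit])


def excise(read: Read, segments: Sequence[LocalAlignment], cfg: CleanupConfig = CleanupConfig()) -> list[Read]:
    """Cut every given rRNA segment out of the read.

    Each maximal remaining fragment of length >= min_retained_length becomes
    a cured read whose id gains a ``|cut:<start>-<end>/<L|R|M>`` suffix per
    cut it survived; shorter fragments are dropped. Bases and qualities of a
    fragment are exact contiguous slices of the source read.
    """
    spans = sorted(a.read_span for a in segments)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError("segments overlap")
    # complement of the cut spans within [0, len(read))
    fragments: list[tuple[int, int]] = []
    pos = 0
    for s, e in spans:
        if s > pos:
            fragments.append((pos, s))
        pos = e
    if pos < len(read):
        fragments.append((pos, len(read)))

    cut_desc = ",".join(f"{s}-{e}" for s, e in spans)
    cured: list[Read] = []
    n_frags = len(fragments)
    for k, (s, e) in enumerate(fragments):
        if e - s < cfg.min_retained_length:
            continue
        if s == 0:
            tag = "L"
        elif e == len(read):
            tag = "R"
        else:
            tag = "M"
        cured.append(
            Read(
                read_id=f"{read.read_id}|cut:{cut_desc}/{tag}",
                bases=read.bases[s:e],
                quals=read.quals[s:e],
                lineage=read.lineage + [(read.read_id, span) for span in spans],
            )
        )
    return cured


def _refine_sam_call(
    sam: SamAlignment, rrna_refs: Sequence[ReferenceSeq], cfg: CleanupConfig
) -> ChimeraCall:
    """Triage from an external aligner's record; soft-clipped reads get their
    boundary re-localized by the internal aligner."""
    if sam.cigar is None:  # unmapped
        return ChimeraCall(sam.read.read_id, VERDICT_NON_RRNA)
    start, end = aligned_read_span(sam.cigar)
    mapped_frac = (end - start) / len(sam.read)
    if mapped_frac >= cfg.rrna_fraction_threshold:
        # fully/nearly fully aligned to rRNA: pure; synthesize evidence from
        # the internal aligner for a uniform ChimeraCall contract
        hit = best_hit(sam.read, rrna_refs, cfg.scoring, cfg.min_score)
        if hit is not None and hit.aligned_read_frac >= cfg.rrna_fraction_threshold:
            return ChimeraCall(sam.read.read_id, VERDICT_PURE_RRNA, [hit])
    # soft-clipped (partially aligned): refine boundary internally
    return classify_read(sam.read, rrna_refs, cfg)


def run_round(
    reads: Sequence[Read],
    rrna_refs: Sequence[ReferenceSeq],
    cfg: CleanupConfig = CleanupConfig(),
    sam_records: Optional[Sequence[SamAlignment]] = None,
    round_no: int = 1,
) -> tuple[list[Read], list[Read], list[Read], list[ChimeraCall], RoundStats]:
    """One cleanup round.

    Returns (cured, passthrough, discarded_pure, calls, stats). Every input
    read lands in exactly one of the three bins.
    """
    if cfg.triage_mode == "sam_ingest" and sam_records is not None:
        by_id = {s.read.read_id: s for s in sam_records}
    else:
        by_id = None

    cured: list[Read] = []
    passthrough: list[Read] = []
    discarded: list[Read] = []
    calls: list[ChimeraCall] = []
    dropped_short = 0
    n_chimeric = 0
    for read in reads:
        if by_id is not None and read.read_id in by_id:
            call = _refine_sam_call(by_id[read.read_id], rrna_refs, cfg)
        else:
            call = classify_read(read, rrna_refs, cfg)
        calls.append(call)
        if call.verdict == VERDICT_NON_RRNA:
            passthrough.append(read)
        elif call.verdict == VERDICT_PURE_RRNA:
            discarded.append(read)
        else:
            n_chimeric += 1
            # excise only the single best segment per round; further moieties
            # are handled by iteration
            frags = excise(read, call.rrna_segments[:1], cfg)
            n_possible = _n_fragments(read, call.rrna_segments[0].read_span)
            dropped_short += n_possible - len(frags)
            cured.extend(frags)

    stats = RoundStats(
        round=round_no,
        input=len(reads),
        pure_rrna_discarded=len(discarded),
        chimeric_detected=n_chimeric,
        cured_emitted=len(cured),
        passthrough=len(passthrough),
        dropped_short=dropped_short,
    )
    stats.check()
    return cured, passthrough, discarded, calls, stats


def _n_fragments(read: Read, span: tuple[int, int]) -> int:
    s, e = span
    return (1 if s > 0 else 0) + (1 if e < len(read) else 0)


def iterate_cleanup(
    reads: Sequence[Read],
    rrna_refs: Sequence[ReferenceSeq],
    cfg: CleanupConfig = CleanupConfig(),
    sam_records: Optional[Sequence[SamAlignment]] = None,
) -> CleanupResult:
    """Run cleanup rounds until no read is cured or max_rounds is reached.

    Cured outputs of round k become the inputs of round k+1 (passthrough
    reads are settled the round they are seen). SAM-based triage only applies
    to round 1; cured fragments have no external alignment and are always
    triaged internally.
    """
    rounds: list[RoundStats] = []
    all_calls: list[list[ChimeraCall]] = []
    final: list[Read] = []
    all_discarded: list[Read] = []

    current = list(reads)
    for round_no in range(1, cfg.max_rounds + 1):
        cured, passthrough, discarded, calls, stats = run_round(
            current,
            rrna_refs,
            cfg,
            sam_records=sam_records if round_no == 1 else None,
            round_no=round_no,
        )
        rounds.append(stats)
        all_calls.append(calls)
        final.extend(passthrough)
        all_discarded.extend(discarded)
        if not cured:
            current = []
            break
        current = cured
    final.extend(current)  # last-round cured reads
    return CleanupResult(rounds=rounds, final_reads=final, calls=all_calls, discarded_pure=all_discarded)


def count_exact_duplicates(reads: Iterable[Read]) -> int:
    """Informational only: number of reads whose bases duplicate an earlier read."""
    seen: set[str] = set()
    dups = 0
    for read in reads:
        if read.bases in seen:
            dups += 1
        else:
            seen.add(read.bases)
    return dups
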