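"""Screen candidate sequence databases for embedded rRNA stretches.

Two routes: direct local alignment of each rRNA reference against each
target, and a mock-read route that simulates a sequencing run from the rRNA
references and stacks the reads' mapped intervals on each target. Hits are
reported with 1-based start, length and the percentile bin of the start
position relative to the target length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .alignment import DEFAULT_SCORING, ScoringScheme, best_hit, local_align, polish_boundaries
from .io_formats import ReferenceSeq
from .synthetic import MockConfig, generate_mock_reads

MERGE_GAP = 10  # intervals closer than this are considered one ragged stretch


@dataclass(frozen=True)
class ContaminationHit:
    target_id: str
    contamination_start: int  # 1-based position on the target
    contamination_length: int
    percentile: int  # floor(100 * (start - 1) / target_length)
    identity: float
    read_support: Optional[int] = None  # mock-read route only

    def __post_init__(self) -> None:
        if self.contamination_start < 1:
            raise ValueError("contamination_start is 1-based, must be >= 1")
        if self.contamination_length < 1:
            raise ValueError("contamination_length must be >= 1")


def start_percentile(start_1based: int, target_length: int) -> int:
    return int(100 * (start_1based - 1) // target_length)


def _merge_intervals(intervals: list[tuple[int, int]], gap: int = MERGE_GAP) -> list[tuple[int, int]]:
    """Merge 0-based half-open intervals closer than ``gap`` into maximal runs."""
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1] + gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def screen_targets_direct(
    rrna_refs: Sequence[ReferenceSeq],
    targets: Sequence[ReferenceSeq],
    scoring: ScoringScheme = DEFAULT_SCORING,
    min_len: int = 50,
    min_identity: float = 0.90,
    max_hits_per_pair: int = 50,
) -> list[ContaminationHit]:
    """Direct route: align each rRNA reference against each target.

    Per (rRNA, target) pair, qualifying local alignments are found
    iteratively with the already-found target span masked to N, until no
    alignment of length >= min_len and identity >= min_identity remains.
    Overlapping/nearby intervals from different rRNA refs are merged into
    one hit per stretch.
    """
    if not targets:
        raise ValueError("targets must be non-empty")
    min_score = scoring.match * min_len // 2  # permissive; length/identity filter below
    hits: list[ContaminationHit] = []
    for target in targets:
        intervals: list[tuple[int, int, float]] = []
        for rrna in rrna_refs:
            masked = target.bases
            for _ in range(max_hits_per_pair):
                aln = local_align(rrna.bases, masked, scoring, min_score)
                if aln is None:
                    break
                raw_span = aln.ref_span
                polished = polish_boundaries(aln)
                if polished is None:
                    # no clean boundary; mask the raw span and move on
                    s, e = raw_span
                    masked = masked[:s] + "N" * (e - s) + masked[e:]
                    continue
                s, e = polished.ref_span
                if e - s >= min_len and polished.identity >= min_identity:
                    intervals.append((s, e, polished.identity))
                # mask the raw span (superset of the polished one) so the
                # ragged edges cannot seed another round
                rs, re_ = raw_span
                masked = masked[:rs] + "N" * (re_ - rs) + masked[re_:]
                if e - s < min_len:  # remaining signal too short to qualify
                    break
        merged = _merge_intervals([(s, e) for s, e, _ in intervals])
        for ms, me in merged:
            idents = [i for s, e, i in intervals if s < me and e > ms]
            hits.append(
                ContaminationHit(
                    target_id=target.ref_id,
                    contamination_start=ms + 1,
                    contamination_length=me - ms,
                    percentile=start_percentile(ms + 1, len(target)),
                    identity=float(np.mean(idents)) if idents else 0.0,
                )
            )
    return hits


def screen_targets_mockreads(
    rrna_refs: Sequence[ReferenceSeq],
    targets: Sequence[ReferenceSeq],
    mock_cfg: MockConfig,
    scoring: ScoringScheme = DEFAULT_SCORING,
    min_identity: float = 0.90,
    min_read_score: int = 60,
) -> list[ContaminationHit]:
    """Mock-read route: simulate a sequencing run from the rRNA references,
    map each mock read onto the targets, and merge the mapped intervals."""
    if not targets:
        raise ValueError("targets must be non-empty")
    per_target: dict[str, list[tuple[int, int, float]]] = {t.ref_id: [] for t in targets}
    for read in generate_mock_reads(rrna_refs, mock_cfg):
        hit = best_hit(read, targets, scoring, min_read_score)
        if hit is None or hit.identity < min_identity:
            continue
        s, e = hit.ref_span
        per_target[hit.ref_id].append((s, e, hit.identity))
    hits: list[ContaminationHit] = []
    for target in targets:
        stacked = per_target[target.ref_id]
        merged = _merge_intervals([(s, e) for s, e, _ in stacked])
        for ms, me in merged:
            inside = [(s, e, i) for s, e, i in stacked if s < me and e > ms]
            hits.append(
                ContaminationHit(
                    target_id=target.ref_id,
                    contamination_start=ms + 1,
                    contamination_length=me - ms,
                    percentile=start_percentile(ms + 1, len(target)),
                    identity=float(np.mean([i for _, _, i in inside])),
                    read_support=len(inside),
                )
            )
    return hits


def percentile_histogram(hits: Sequence[ContaminationHit]) -> np.ndarray:
    """Counts of hits per percentile bin (length-100 vector, bins 0..99)."""
    counts = np.zeros(100, dtype=np.int64)
    for hit in hits:
        counts[hit.percentile] += 1
    return counts
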