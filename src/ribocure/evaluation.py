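"""Cleanup-impact metrics: Venn-style overlap counts, a toy greedy
micro-assembler, and contig/genome summary metrics.

The micro-assembler is an exact suffix-prefix overlap merger for error-free
desk-scale data; it exists to demonstrate the chimeric-bridge phenomenon and
the effect of read cleanup, not to stand in for a real assembler.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .alignment import (
    DEFAULT_MIN_SCORE,
    DEFAULT_SCORING,
    ScoringScheme,
    best_hit,
    reverse_complement,
)
from .io_formats import Read, ReferenceSeq


@dataclass(frozen=True)
class OverlapCounts:
    rrna_only: int
    virus_only: int
    both: int  # chimeric
    neither: int

    @property
    def total(self) -> int:
        return self.rrna_only + self.virus_only + self.both + self.neither


def overlap_counts(
    reads: Sequence[Read],
    rrna_refs: Sequence[ReferenceSeq],
    virus_refs: Sequence[ReferenceSeq],
    scoring: ScoringScheme = DEFAULT_SCORING,
    min_score: int = DEFAULT_MIN_SCORE,
) -> OverlapCounts:
    """Assign each read to one Venn cell by whether its best hit against each
    reference set clears min_score."""
    rrna_only = virus_only = both = neither = 0
    for read in reads:
        r = best_hit(read, rrna_refs, scoring, min_score) is not None
        v = best_hit(read, virus_refs, scoring, min_score) is not None
        if r and v:
            both += 1
        elif r:
            rrna_only += 1
        elif v:
            virus_only += 1
        else:
            neither += 1
    return OverlapCounts(rrna_only, virus_only, both, neither)


# ---------------------------------------------------------------------------
# Greedy micro-assembler
# ---------------------------------------------------------------------------

def _longest_overlap(a: str, b: str, min_overlap: int) -> int:
    """Longest k >= min_overlap with a[-k:] == b[:k] (exact), else 0."""
    max_k = min(len(a), len(b))
    seed = b[:min_overlap]
    best = 0
    pos = a.find(seed, len(a) - max_k)
    while pos != -1:
        k = len(a) - pos
        if k >= min_overlap and a[pos:] == b[:k]:
            best = max(best, k)
        pos = a.find(seed, pos + 1)
    return best


def greedy_assemble(reads: Sequence[Read] | Sequence[str], min_overlap: int = 20) -> list[str]:
    """Merge sequences by longest exact suffix-prefix overlap (both strands)
    until no overlap >= min_overlap remains; contigs sorted by length desc.

    Deterministic: ties broken by lowest sequence index, then orientation.
    Sequences fully contained in another (either strand) are absorbed first.
    """
    if min_overlap < 10:
        raise ValueError("min_overlap must be >= 10")
    seqs = [r.bases if isinstance(r, Read) else str(r) for r in reads]
    seqs = [s for s in seqs if s]

    # containment absorption (duplicates, fully covered fragments)
    seqs.sort(key=len, reverse=True)
    kept: list[str] = []
    for s in seqs:
        rc = reverse_complement(s)
        if any(s in k or rc in k for k in kept):
            continue
        kept.append(s)
    seqs = kept

    while True:
        best_k = 0
        best_merge: Optional[tuple[int, int, str]] = None
        n = len(seqs)
        rcs = [reverse_complement(s) for s in seqs]
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                k = _longest_overlap(seqs[i], seqs[j], min_overlap)
                if k > best_k:
                    best_k = k
                    best_merge = (i, j, seqs[i] + seqs[j][k:])
                # suffix of i matching prefix of rc(j)
                k = _longest_overlap(seqs[i], rcs[j], min_overlap)
                if k > best_k:
                    best_k = k
                    best_merge = (i, j, seqs[i] + rcs[j][k:])
                # suffix of rc(i) matching prefix of j (prefix-prefix overlap)
                k = _longest_overlap(rcs[i], seqs[j], min_overlap)
                if k > best_k:
                    best_k = k
                    best_merge = (i, j, rcs[i] + seqs[j][k:])
        if best_merge is None:
            break
        i, j, merged = best_merge
        seqs = [s for idx, s in enumerate(seqs) if idx not in (i, j)]
        # merged contig may now contain or overlap remaining sequences
        seqs.append(merged)
        seqs = _absorb(seqs)
    return sorted(seqs, key=lambda s: (-len(s), s))


def _absorb(seqs: list[str]) -> list[str]:
    ordered = sorted(seqs, key=len, reverse=True)
    kept: list[str] = []
    for s in ordered:
        rc = reverse_complement(s)
        if any(s in k or rc in k for k in kept):
            continue
        kept.append(s)
    return kept


# ---------------------------------------------------------------------------
# Contig / genome metrics
# ---------------------------------------------------------------------------

@dataclass
class AssemblyMetrics:
    mean_contig_length: float
    mean_contig_coverage: float  # mean over mapped contigs of % contig bases aligned
    genome_coverage: float  # % genome bases covered by >= 1 contig alignment
    used_reads: int
    n_contigs: int = 0
    n_mapped_contigs: int = 0
    empty: bool = False

    def __post_init__(self) -> None:
        if not self.empty:
            if not (0.0 <= self.mean_contig_coverage <= 100.0):
                raise ValueError("mean_contig_coverage outside [0, 100]")
            if not (0.0 <= self.genome_coverage <= 100.0):
                raise ValueError("genome_coverage outside [0, 100]")


def evaluate_contigs(
    contigs: Sequence[str],
    genome: ReferenceSeq,
    scoring: ScoringScheme = DEFAULT_SCORING,
    min_score: int = DEFAULT_MIN_SCORE,
    reads: Optional[Sequence[Read]] = None,
) -> AssemblyMetrics:
    """Summary metrics of a contig set against a reference genome.

    Contigs with no qualifying hit are excluded from mean_contig_coverage but
    counted in n_contigs. ``used_reads`` counts reads with a qualifying hit
    on the genome (0 when no reads are supplied).
    """
    if not contigs:
        return AssemblyMetrics(0.0, 0.0, 0.0, 0, n_contigs=0, n_mapped_contigs=0, empty=True)

    covered: set[int] = set()
    coverages: list[float] = []
    n_mapped = 0
    for contig in contigs:
        hit = best_hit(contig, [genome], scoring, min_score)
        if hit is None:
            continue
        n_mapped += 1
        aligned = hit.read_span[1] - hit.read_span[0]
        coverages.append(100.0 * aligned / len(contig))
        covered.update(range(hit.ref_span[0], hit.ref_span[1]))

    used = 0
    if reads is not None:
        for read in reads:
            if best_hit(read, [genome], scoring, min_score) is not None:
                used += 1

    return AssemblyMetrics(
        mean_contig_length=sum(len(c) for c in contigs) / len(contigs),
        mean_contig_coverage=sum(coverages) / len(coverages) if coverages else 0.0,
        genome_coverage=100.0 * len(covered) / len(genome),
        used_reads=used,
        n_contigs=len(contigs),
        n_mapped_contigs=n_mapped,
    )


def rrna_content_kmers(contigs: Sequence[str], rrna_refs: Sequence[ReferenceSeq], k: int = 30) -> int:
    """Number of contigs sharing any exact k-mer with the rRNA references
    (either strand). Error-free data makes this an exact contamination test."""
    kmers: set[str] = set()
    for ref in rrna_refs:
        for seq in (ref.bases, reverse_complement(ref.bases)):
            for i in range(len(seq) - k + 1):
                kmers.add(seq[i : i + k])
    contaminated = 0
    for contig in contigs:
        if any(contig[i : i + k] in kmers for i in range(len(contig) - k + 1)):
            contaminated += 1
    return contaminated


# ---------------------------------------------------------------------------
# Strategy comparison (cure vs filter vs raw)
# ---------------------------------------------------------------------------

def compare_strategies(
    reads: Sequence[Read],
    rrna_refs: Sequence[ReferenceSeq],
    genome: ReferenceSeq,
    cleanup_cfg=None,
    min_overlap: int = 20,
    scoring: ScoringScheme = DEFAULT_SCORING,
    min_score: int = DEFAULT_MIN_SCORE,
) -> dict[str, AssemblyMetrics]:
    """Run the three read strategies end to end on the same input:

    - ``cure``:   iterated chimera cleanup (keep cured fragments)
    - ``filter``: whole-read discard of anything rRNA-touching (the
      drop-the-whole-read baseline)
    - ``raw``:    no treatment

    Each strategy's surviving reads are assembled with the greedy
    micro-assembler and scored against the genome.
    """
    from .chimera import CleanupConfig, iterate_cleanup

    cfg = cleanup_cfg or CleanupConfig(scoring=scoring, min_score=min_score)

    cure_result = iterate_cleanup(reads, rrna_refs, cfg)
    strategies = {
        "cure": cure_result.final_reads,
        "filter": [r for r, c in zip(reads, cure_result.calls[0]) if c.verdict == "non_rrna"],
        "raw": list(reads),
    }
    out: dict[str, AssemblyMetrics] = {}
    for name, selected in strategies.items():
        contigs = greedy_assemble(selected, min_overlap)
        out[name] = evaluate_contigs(contigs, genome, scoring, min_score, reads=selected)
    return out
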