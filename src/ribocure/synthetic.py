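"""Mock-read generation and chimeric dataset simulation with ground truth.

Mock reads are exact substrings of a reference (optionally reverse
complemented), constant quality, seed-deterministic. The chimeric simulator
joins rRNA and virus fragments at recorded junctions so that boundary
recovery can be scored against truth.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .alignment import reverse_complement
from .io_formats import PHRED_OFFSET, Read, ReferenceSeq

CLASS_CLEAN_VIRUS = "clean_virus"
CLASS_PURE_RRNA = "pure_rrna"
CLASS_CHIMERA = "chimera"


@dataclass(frozen=True)
class MockConfig:
    """Parameters of the mock-fastq generator (defaults: 4 million reads of
    90-150 bp at Phred 30)."""

    n_reads: int = 4_000_000
    len_min: int = 90
    len_max: int = 150
    phred: int = 30
    both_strands: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.len_min <= self.len_max):
            raise ValueError("need 1 <= len_min <= len_max")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if not (0 <= self.phred <= 93):
            raise ValueError("phred must be in [0, 93]")


def _sample_spans(ref_len: int, cfg: MockConfig, rng: np.random.Generator):
    if ref_len < cfg.len_min:
        raise ValueError(f"reference length {ref_len} < len_min {cfg.len_min}")
    len_max = min(cfg.len_max, ref_len)
    lens = rng.integers(cfg.len_min, len_max + 1, size=cfg.n_reads)
    starts = np.floor(rng.random(cfg.n_reads) * (ref_len - lens + 1)).astype(np.int64)
    if cfg.both_strands:
        minus = rng.integers(0, 2, size=cfg.n_reads).astype(bool)
    else:
        minus = np.zeros(cfg.n_reads, dtype=bool)
    return lens, starts, minus


def mock_read_id(ref_id: str, index: int, start: int, end: int, strand: str) -> str:
    return f"mock-{ref_id}-{index}|src:{start}-{end}|{strand}"


def parse_mock_read_id(read_id: str) -> tuple[str, int, int, str]:
    """Return (ref_id, src_start, src_end, strand) from a mock read id."""
    head, src, strand = read_id.rsplit("|", 2)
    ref_id, _, _ = head[len("mock-") :].rpartition("-")
    s, e = src[len("src:") :].split("-")
    return ref_id, int(s), int(e), strand


def generate_mock_reads(refs: Sequence[ReferenceSeq], cfg: MockConfig = MockConfig()) -> Iterator[Read]:
    """Yield ``cfg.n_reads`` exact-substring reads per reference.

    The source span and strand are encoded in the read id so coverage can be
    computed from truth rather than re-alignment.
    """
    if not refs:
        raise ValueError("refs must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    for ref in refs:
        lens, starts, minus = _sample_spans(len(ref), cfg, rng)
        rc_ref = reverse_complement(ref.bases)
        L = len(ref)
        for i in range(cfg.n_reads):
            s = int(starts[i])
            e = s + int(lens[i])
            if minus[i]:
                bases = rc_ref[L - e : L - s]
                strand = "-"
            else:
                bases = ref.bases[s:e]
                strand = "+"
            yield Read(
                read_id=mock_read_id(ref.ref_id, i, s, e, strand),
                bases=bases,
                quals=[cfg.phred] * (e - s),
            )


def write_mock_fastq(refs: Sequence[ReferenceSeq], cfg: MockConfig, path: str | Path) -> int:
    """Stream mock reads straight to a FASTQ file (fast path for large n).

    Byte-identical to serializing :func:`generate_mock_reads` with
    ``write_fastq``. Returns the number of records written.
    """
    if not refs:
        raise ValueError("refs must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    qchar = chr(cfg.phred + PHRED_OFFSET)
    qual_cache = {n: qchar * n for n in range(cfg.len_min, cfg.len_max + 1)}
    total = 0
    with open(path, "w") as out:
        for ref in refs:
            lens, starts, minus = _sample_spans(len(ref), cfg, rng)
            rc_ref = reverse_complement(ref.bases)
            fwd_ref = ref.bases
            L = len(ref)
            rid = ref.ref_id
            buf: list[str] = []
            for i in range(cfg.n_reads):
                s = int(starts[i])
                n = int(lens[i])
                e = s + n
                if minus[i]:
                    bases = rc_ref[L - e : L - s]
                    strand = "-"
                else:
                    bases = fwd_ref[s:e]
                    strand = "+"
                buf.append(f"@mock-{rid}-{i}|src:{s}-{e}|{strand}\n{bases}\n+\n{qual_cache[n]}\n")
                if len(buf) >= 100_000:
                    out.write("".join(buf))
                    buf.clear()
            out.write("".join(buf))
            total += cfg.n_reads
    return total


def coverage_profile(mock_reads, ref: ReferenceSeq) -> np.ndarray:
    """Per-base depth over ``ref`` using the truth spans encoded in read ids."""
    depth = np.zeros(len(ref), dtype=np.int64)
    for read in mock_reads:
        ref_id, s, e, _ = parse_mock_read_id(read.read_id)
        if ref_id != ref.ref_id:
            continue
        depth[s:e] += 1
    return depth


# ---------------------------------------------------------------------------
# Chimeric dataset simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChimeraSimConfig:
    n_clean_virus: int = 0
    n_pure_rrna: int = 0
    n_single_chimera: int = 0
    n_double_chimera: int = 0
    flank_min: int = 25
    duplicate_rate: float = 0.0
    len_min: int = 90
    len_max: int = 150
    phred: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_clean_virus, self.n_pure_rrna, self.n_single_chimera, self.n_double_chimera) < 0:
            raise ValueError("counts must be >= 0")
        if not (0.0 <= self.duplicate_rate < 1.0):
            raise ValueError("duplicate_rate must be in [0, 1)")
        if not (1 <= self.len_min <= self.len_max):
            raise ValueError("need 1 <= len_min <= len_max")


@dataclass
class Part:
    kind: str  # 'rrna' or 'virus'
    read_start: int
    read_end: int
    ref_id: str
    ref_start: int
    ref_end: int
    strand: str


@dataclass
class TruthRecord:
    read_id: str
    klass: str
    junctions: list[int] = field(default_factory=list)
    parts: list[Part] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.klass not in (CLASS_CLEAN_VIRUS, CLASS_PURE_RRNA, CLASS_CHIMERA):
            raise ValueError(f"unknown class {self.klass!r}")
        if self.junctions != sorted(self.junctions):
            raise ValueError("junctions must be sorted")

    def rrna_read_intervals(self) -> list[tuple[int, int]]:
        return [(p.read_start, p.read_end) for p in self.parts if p.kind == "rrna"]


def _take_fragment(ref: ReferenceSeq, length: int, rng: np.random.Generator) -> tuple[str, int, int, str]:
    """Random exact fragment of a reference (either strand)."""
    if len(ref) < length:
        raise ValueError(f"reference {ref.ref_id} shorter than fragment length {length}")
    s = int(rng.integers(0, len(ref) - length + 1))
    e = s + length
    frag = ref.bases[s:e]
    if rng.integers(0, 2):
        return reverse_complement(frag), s, e, "-"
    return frag, s, e, "+"


def simulate_chimeric_dataset(
    rrna_refs: Sequence[ReferenceSeq],
    virus_ref: ReferenceSeq,
    cfg: ChimeraSimConfig,
) -> tuple[list[Read], list[TruthRecord]]:
    """Build a labelled read set: clean virus reads, pure rRNA reads,
    single-moiety chimeras (rRNA+virus) and double-moiety chimeras
    (rRNA+virus+rRNA). Junction positions are uniform subject to flank_min
    on every segment; segment order and strands are random. Duplicates are
    exact copies with new ids at ``duplicate_rate``."""
    if not rrna_refs:
        raise ValueError("rrna_refs must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    reads: list[Read] = []
    truth: list[TruthRecord] = []

    def pick_rrna() -> ReferenceSeq:
        return rrna_refs[int(rng.integers(0, len(rrna_refs)))]

    def read_len() -> int:
        return int(rng.integers(cfg.len_min, cfg.len_max + 1))

    counter = 0

    def emit(bases: str, klass: str, junctions: list[int], parts: list[Part]) -> None:
        nonlocal counter
        rid = f"sim-{klass}-{counter}"
        counter += 1
        reads.append(Read(read_id=rid, bases=bases, quals=[cfg.phred] * len(bases)))
        truth.append(TruthRecord(read_id=rid, klass=klass, junctions=junctions, parts=parts))

    for _ in range(cfg.n_clean_virus):
        L = read_len()
        frag, s, e, strand = _take_fragment(virus_ref, L, rng)
        emit(frag, CLASS_CLEAN_VIRUS, [], [Part("virus", 0, L, virus_ref.ref_id, s, e, strand)])

    for _ in range(cfg.n_pure_rrna):
        L = read_len()
        ref = pick_rrna()
        frag, s, e, strand = _take_fragment(ref, L, rng)
        emit(frag, CLASS_PURE_RRNA, [], [Part("rrna", 0, L, ref.ref_id, s, e, strand)])

    fm = cfg.flank_min
    for _ in range(cfg.n_single_chimera):
        L = read_len()
        if L < 2 * fm:
            raise ValueError("read length too short for flank_min on both sides")
        j = int(rng.integers(fm, L - fm + 1))
        rrna_first = bool(rng.integers(0, 2))
        ref = pick_rrna()
        seg_a, seg_b = (j, L - j)
        if rrna_first:
            ra, rs, re_, rstrand = _take_fragment(ref, seg_a, rng)
            vb, vs, ve, vstrand = _take_fragment(virus_ref, seg_b, rng)
            parts = [
                Part("rrna", 0, j, ref.ref_id, rs, re_, rstrand),
                Part("virus", j, L, virus_ref.ref_id, vs, ve, vstrand),
            ]
            bases = ra + vb
        else:
            va, vs, ve, vstrand = _take_fragment(virus_ref, seg_a, rng)
            rb, rs, re_, rstrand = _take_fragment(ref, seg_b, rng)
            parts = [
                Part("virus", 0, j, virus_ref.ref_id, vs, ve, vstrand),
                Part("rrna", j, L, ref.ref_id, rs, re_, rstrand),
            ]
            bases = va + rb
        emit(bases, CLASS_CHIMERA, [j], parts)

    # double moiety: rRNA + virus + rRNA; the middle (virus) segment is kept
    # >= max(flank_min, 30) so a cured middle fragment survives retention
    mid_min = max(fm, 30)
    need = 2 * fm + mid_min
    if cfg.n_double_chimera and need > cfg.len_max:
        raise ValueError(
            f"len_max {cfg.len_max} too short for a double-moiety layout (needs >= {need})"
        )
    for _ in range(cfg.n_double_chimera):
        L = int(rng.integers(max(cfg.len_min, need), cfg.len_max + 1))
        a = int(rng.integers(fm, L - mid_min - fm + 1))
        m = int(rng.integers(mid_min, L - a - fm + 1))
        j1, j2 = a, a + m
        ref1, ref2 = pick_rrna(), pick_rrna()
        fa, s1, e1, st1 = _take_fragment(ref1, a, rng)
        fv, vs, ve, vst = _take_fragment(virus_ref, m, rng)
        fb, s2, e2, st2 = _take_fragment(ref2, L - j2, rng)
        parts = [
            Part("rrna", 0, j1, ref1.ref_id, s1, e1, st1),
            Part("virus", j1, j2, virus_ref.ref_id, vs, ve, vst),
            Part("rrna", j2, L, ref2.ref_id, s2, e2, st2),
        ]
        emit(fa + fv + fb, CLASS_CHIMERA, [j1, j2], parts)

    # PCR duplicates: exact copies with new ids
    n_dups = int(round(cfg.duplicate_rate * len(reads)))
    if n_dups:
        picks = rng.integers(0, len(reads), size=n_dups)
        for k, idx in enumerate(picks):
            src = reads[int(idx)]
            src_truth = truth[int(idx)]
            rid = f"{src.read_id}|dup{k}"
            reads.append(Read(read_id=rid, bases=src.bases, quals=list(src.quals)))
            truth.append(
                TruthRecord(
                    read_id=rid,
                    klass=src_truth.klass,
                    junctions=list(src_truth.junctions),
                    parts=[Part(**vars(p)) for p in src_truth.parts],
                )
            )
    return reads, truth


TRUTH_COLUMNS = ["read_id", "class", "junctions", "parts"]


def _format_part(p: Part) -> str:
    return f"{p.kind}:{p.read_start}-{p.read_end}:{p.ref_id}:{p.ref_start}-{p.ref_end}:{p.strand}"


def _parse_part(s: str) -> Part:
    kind, rspan, ref_id, refspan, strand = s.split(":")
    rs, re_ = rspan.split("-")
    fs, fe = refspan.split("-")
    return Part(kind, int(rs), int(re_), ref_id, int(fs), int(fe), strand)


def write_truth_tsv(truth: Sequence[TruthRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as out:
        writer = csv.writer(out, delimiter="\t", lineterminator="\n")
        writer.writerow(TRUTH_COLUMNS)
        for rec in truth:
            writer.writerow(
                [
                    rec.read_id,
                    rec.klass,
                    ",".join(str(j) for j in rec.junctions),
                    ";".join(_format_part(p) for p in rec.parts),
                ]
            )


def read_truth_tsv(path: str | Path) -> list[TruthRecord]:
    out: list[TruthRecord] = []
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader)
        if header != TRUTH_COLUMNS:
            raise ValueError(f"unexpected truth file header: {header}")
        for row in reader:
            read_id, klass, junctions, parts = row
            out.append(
                TruthRecord(
                    read_id=read_id,
                    klass=klass,
                    junctions=[int(j) for j in junctions.split(",")] if junctions else [],
                    parts=[_parse_part(p) for p in parts.split(";")] if parts else [],
                )
            )
    return out


def random_reference(ref_id: str, length: int, seed: int, role: str = "target_db") -> ReferenceSeq:
    """Uniform-random ACGT reference; convenience for fixtures and demos."""
    rng = np.random.default_rng(seed)
    bases = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
    return ReferenceSeq(ref_id=ref_id, bases=bases, role=role)
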