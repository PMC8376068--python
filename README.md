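# ribocure

Detect rRNA–virus chimeric sequencing reads and *cure* them — excise the
rRNA moiety precisely instead of discarding the whole read — so the viral
portion stays available for genome assembly. The package also screens
sequence databases for embedded rRNA stretches and quantifies the effect of
read cleanup on assembly quality.

Total-RNA-seq libraries from low-abundance virus samples contain reads fused
from host ribosomal RNA and viral RNA during library preparation. Dropping
every rRNA-touching read (the SortMeRNA-style baseline) can discard half of
the virus-derived reads; leaving them in seeds chimeric contigs. `ribocure`
classifies each read as non-rRNA / pure rRNA / chimeric, localizes the exact
fusion boundary with an exact affine-gap local aligner, cuts the rRNA
segment out, and iterates so reads carrying more than one moiety lose one
moiety per round (two rounds by default).

## Modules

| module       | contents |
|--------------|----------|
| `io_formats` | FASTQ/FASTA/SAM readers and writers, `Read` / `ReferenceSeq` types, CIGAR helpers |
| `alignment`  | exact Smith–Waterman with affine gaps over both strands, boundary polish, `best_hit` |
| `chimera`    | read triage, rRNA-moiety excision, iterated cleanup rounds |
| `synthetic`  | mock-read generator and chimeric dataset simulator with ground truth |
| `screening`  | rRNA contamination screening of candidate databases (direct and mock-read routes) |
| `evaluation` | read overlap (Venn) counts, toy greedy micro-assembler, contig/genome metrics |
| `cli`        | `ribocure` command line entry point |

All coordinates are 0-based half-open internally; reports are 1-based.
Cured read ids carry a `|cut:<start>-<end>/<L|R|M>` suffix per excision, so
provenance survives without sidecar files.

## Command line

```sh
# generate mock reads (exact substrings of a reference, constant quality)
ribocure mock --ref rrna.fasta --n 4000000 --len-min 90 --len-max 150 \
    --phred 30 --seed 1 --out mock.fastq

# simulate a labelled chimeric dataset (FASTQ + truth TSV)
ribocure simulate --rrna rrna.fasta --virus virus.fasta \
    --n-clean-virus 50 --n-pure-rrna 50 --n-single-chimera 100 \
    --n-double-chimera 20 --seed 1 --out-reads sim.fastq --out-truth truth.tsv

# iterated chimeric-read cleanup
ribocure clean --reads reads.fastq --rrna rrna.fasta --out-dir cleaned/ \
    --rrna-fraction 0.90 --min-identity 0.80 --min-retained 30 --max-rounds 2

# triage from an external aligner's SAM instead of the internal aligner
ribocure clean --reads reads.fastq --rrna rrna.fasta --out-dir cleaned/ \
    --triage sam --sam aligned.sam

# screen a database for embedded rRNA stretches
ribocure screen --rrna rrna.fasta --targets candidates.fasta \
    --mode direct --min-len 50 --min-identity 0.90 --out hits.tsv

# score contigs against a reference genome
ribocure evaluate --contigs contigs.fasta --genome genome.fasta \
    --reads reads.fastq --out metrics.tsv

# cure / filter / raw three-way comparison on one read set
ribocure compare --reads reads.fastq --rrna rrna.fasta \
    --genome genome.fasta --out table.tsv
```

`clean` writes `cured.fastq` (cured fragments only), `merged.fastq`
(passthrough + cured, the assembly input), `discarded_rrna.fastq`,
`round_stats.tsv`, `calls.tsv` and `manifest.json`.

Every subcommand writes a `manifest.json` with keys `subcommand`, `config`
(all parameters, defaults materialized), `inputs` (name → SHA-256),
`version` and `timestamp`. All commands are seed-deterministic: identical
config + seed reproduces byte-identical FASTQ/TSV outputs.

## Defaults worth knowing

- Scoring: match +2, mismatch −3, gap open 5, gap extend 2 (BLASTN-like);
  minimum alignment score 30 (≈15 matched bases).
- A read whose best rRNA alignment covers ≥90% of it is pure rRNA
  (discarded); partial coverage with identity ≥0.80 is chimeric.
- Excision keeps *both* flanks of an internal moiety when they are ≥30 bp
  (`--min-retained`); per round only the single best segment is excised, and
  iteration handles multi-moiety reads.
- Boundary polish trims alignment ends until they finish in 10 consecutive
  matching columns, removing chance extensions past the true fusion point;
  alignments stitching two colinear rRNA stretches across ≥10 unanchored
  read bases are split rather than treated as one segment.
- PCR duplicates are never collapsed; an informational duplicate count is
  logged.
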