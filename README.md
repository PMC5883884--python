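# bsalign3

A self-contained toolkit for whole-genome bisulfite sequencing (WGBS):
three-letter read alignment, bisulfite-aware mismatch post-processing,
per-cytosine methylation calling, post-alignment QC/visualization, and a
read simulator with a mapping-accuracy evaluator.

## The problem

Sodium bisulfite converts unmethylated cytosine to uracil (sequenced as T)
while methylated cytosine is protected. A bisulfite aligner must therefore
let a read T match a genome C — but *not* let a read C match a genome T —
and afterwards recover, for every covered cytosine, the fraction of reads
in which it survived conversion:

```
level(i) = m_i / (m_i + u_i)
```

where `m_i` counts reads with C at cytosine *i* (methylated) and `u_i`
reads with T (converted, i.e. unmethylated). Sites are classified by their
downstream reference context as CG, CHG or CHH (H ∈ {A, C, T}), the
standard plant/animal classification.

## How it works

1. **One index, both strands.** The Watson strand and the reverse
   complement (Crick) strand of every chromosome are C→T converted and
   concatenated into a single reference; a hash index maps every 20-mer to
   its positions. A read, itself C→T converted, then needs a single lookup
   pass regardless of its strand of origin.
2. **Seed-and-extend.** Non-overlapping 20 bp substrings of the read (plus
   one flush-right seed) vote for candidate diagonals; each candidate
   window is scored with a banded edit-distance check (Ukkonen band, early
   row-minimum cutoff) that is linear in the read length. A hit is
   reported *unique* only when the runner-up is at least 2 edits worse.
3. **Bisulfite-aware recount.** Three-letter alignment is blind to the
   asymmetry above, so each unique alignment is re-scored against the
   unconverted genome in the read's origin-strand frame: genome-C/read-T is
   a conversion event, read-C/genome-T a true mismatch. Positions are
   visited in a read-id-seeded random order with early termination at the
   mismatch budget.
4. **Calling and analytics.** Unique alignments are piled up into a
   MethGo-compatible 8-column CGmap; downstream helpers compute per-cycle
   mismatch QC, spike-in (lambda phage) conversion efficiency, genome-wide
   methylation windows and metagene (metaplot) profiles.

## Worked example

Everything below runs from the shell with the `bsalign3` entry point; no
external data is needed because the simulator fabricates a genome:

```sh
bsalign3 simulate --random-genome-bp 50000 --n 500 --indel-rate 0.01 \
    --seed 5 --out sim.fq --truth truth.tsv --genome-out ref.fa
bsalign3 index --fasta ref.fa --seed-len 20 --out ref.idx
bsalign3 align --index ref.idx --fastq sim.fq --out out.sam
bsalign3 call  --sam out.sam --fasta ref.fa --out sample.CGmap
bsalign3 evaluate --sam out.sam --truth truth.tsv --tol 5
```

The align step prints the run report:

```json
{
 "n_reads": 500,
 "n_unique": 498,
 "n_multiple": 0,
 "n_unmapped": 2,
 "n_discarded": 0,
 "n_meth_sites": 9759
}
```

498/500 reads aligned uniquely (the two failures carried more edits than
the budget allows); 9,759 cytosines received at least one call. The
evaluator confirms the placements against the simulator's ledger:

```json
{
 "n_reads": 500, "n_mapped": 498, "n_correct": 498,
 "mapability": 0.996, "pct_correct": 0.996
}
```

and the first CGmap rows look like

```
chr1	G	114	CG	CG	1.00	1	1
chr1	G	115	CHG	CC	0.00	0	1
```

— chromosome, the Watson base (C for a Watson-strand cytosine, G for a
Crick-strand one), 1-based position, context, dinucleotide, methylation
level, methylated count, total count.

A full pipeline (`bsalign3 run --config run.toml`) chains index → trim →
align → recount → call → QC and writes `alignments.sam`, `sample.CGmap`,
QC tables/plots and `report.json` into one output directory.

### SAM tags

| tag | meaning |
| --- | ------- |
| `XO` | origin strand: `+W` (Watson) or `-C` (Crick) |
| `XM` | bisulfite-aware mismatches (conversions excluded, indel bases included) |
| `XC` | conversion events (genome C read as T on the origin strand) |
| `NM` | set equal to `XM` (already includes indel bases) |
| `XR` | reason a record is unmapped (`multiple`, `no_alignment`, `too_many_bis_mismatches`, ...) |

Multi-mapped reads are emitted with FLAG 4 and `XR:Z:multiple` and are
excluded from methylation calling.

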