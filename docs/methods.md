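# Methods

## Model and procedure

The toolkit aligns bisulfite-converted single-end reads in "three-letter"
space: every C in both reads and reference is mapped to T before
comparison, which makes legitimate conversion events (unmethylated genome
C read as T) invisible to the aligner, at the cost of a reduced alphabet.
The asymmetric cases are restored afterwards by the recount step (below).

**Index.** For each chromosome the Watson sequence and its reverse
complement (Crick) are C→T converted and laid head-to-tail into a single
concatenation — all Watson blocks first, then all Crick blocks, in
chromosome order. Every k-mer of the concatenation that contains no N is
2-bit packed into a uint64 and stored as a sorted key array with aligned
start positions; lookup is two binary searches. Crick-origin reads, once
C→T converted like every other read, match Crick blocks directly, so one
conversion and one lookup pass per read suffices. Coordinates are 0-based
half-open internally; SAM and CGmap writers shift to 1-based. A Crick
block hit at local offset `q` with reference span `L` maps back to Watson
coordinate `chrom_len − q − L`.

**Alignment.** Seeds are taken at offsets 0, k, 2k, … plus one flush-right
seed ending on the last base; seeds containing N, and seeds whose hit list
exceeds `max_seed_hits`, are skipped. Each hit at concatenation position
`p` for seed offset `o` votes for diagonal `p − o`; diagonals within the
edit budget of each other merge into one candidate (position = smallest
diagonal, votes = pooled hits). Candidates are evaluated in vote order
(ties by position) with a banded semi-global edit distance: the read is
aligned end-to-end against the window `[diag − d, diag + n + d)` clipped
to its block, with free leading/trailing target offset and the band
`j − i ∈ [−d, (m−n) + d]`; a row whose minimum exceeds `d` aborts the
candidate (Ukkonen cutoff), giving O(n·d) work per candidate. The best
and second-best distances decide the outcome: *unique* needs best ≤ d and
runner-up at least `uniqueness_gap` worse; otherwise *multiple* (emitted
unmapped-by-ambiguity) or *unmapped*.

Termination rule: once a candidate reaches distance 0 the scan continues
only through candidates with the same vote count — the only ones that can
also reach distance 0 short of seed dropouts — so exact repeats are still
detected as ambiguous, then stops. At most `max_candidates` (50) windows
are evaluated per read.

**Recount.** Unique alignments are re-scored against the unconverted
genome in the origin-strand frame: equal bases match, genome-C/read-T is a
conversion (not an error), anything else — in particular read-C/genome-T —
is a mismatch; indel bases count as mismatches in full. Substitution
positions are visited in a pseudo-random order seeded from a CRC of the
read id, and the scan stops as soon as the count exceeds the budget.
Mismatches on a wrong alignment are roughly uniformly placed, so a random
order hits the bound early; the per-read seeding makes the verdict (and
the exact counts, when accepted) independent of chunking and thread
count. Reads failing the recount are demoted to unmapped rather than
rescued at a secondary candidate.

**Calling.** For every aligned M-block position whose origin-strand
reference base is C, a read C increments the methylated count and a read T
the total; other read bases and indel-covered positions are ignored.
Context is taken from the reference (never the read, whose Cs may be
converted): downstream base G → CG, H then G → CHG, H,H → CHH; any N in
the window, or running off the chromosome end, → NA (dropped from CGmap
output). Aggregations everywhere (windows, metaplot bins, pooled levels,
conversion efficiency) are count-weighted — pool counts, divide once —
which keeps 1x sites from dominating means.

## Parameters

| parameter | default | rationale |
| --------- | ------- | --------- |
| `seed_len` | 20 bp | long seeds keep false-positive hits rare (expected random 20-mer hit rate ≈ 0.375²⁰ per position in three-letter space); configurable 8–32 (2-bit packing caps at 32) |
| `stride` | = seed_len | non-overlapping seeds bound lookups per read; the flush-right seed covers the tail |
| `max_edit_distance` | max(4, ⌈0.06·read_len⌉) | at the highest simulated error load (indel rate 0.025 + substitutions 0.01 on 100 bp) the three-letter edit count is ≈ Poisson(3.3); a budget of 6 accepts ≈ 95% of reads, a budget of 4 only ≈ 76% |
| `uniqueness_gap` | 2 | a best hit counts as unique only if the runner-up is ≥ 2 edits worse, preventing coin-flip placements from contaminating methylation calls |
| `max_seed_hits` | 1000 | query-time repeat masking; keeps worst-case candidate lists bounded without making the index build lossy |
| `max_candidates` | 50 | caps extension work on repetitive reads |
| recount budget | = max_edit_distance | separate override available |
| evaluation tolerance | 5 bp | indels shift the leftmost aligned coordinate by a few bases even for a correct placement |
| metaplot | 60 body bins, 2 kb flanks, 20 flank bins | gene-scale profiles with ~100 bp resolution |

Simulator defaults mirror the evaluation design: 100 bp reads,
substitution rate 0.01, conversion efficiency 0.99, indel grid
{0, 0.005, 0.01, 0.025}, methylome probabilities (p_CG, p_CHG, p_CHH)
drawn per cytosine as independent Bernoulli states.

## What the simulator does and does not emulate

It reproduces the statistical structure the aligner cares about: uniform
sampling from both strands, per-context Bernoulli methylomes, incomplete
conversion, uniform substitutions and single-base indels, optional
PCR-complement reads for non-directional libraries, and a truth ledger
for scoring. It does **not** model quality-score decay, sequence-context
error profiles, GC/coverage bias, PCR duplicates or adapter read-through,
so passing tests demonstrate algorithmic correctness on idealized reads,
not robustness to platform artefacts. Random genomes are uniform ACGT:
they are nearly repeat-free, so observed uniqueness rates are upper
bounds relative to real genomes with repeat families.

Evaluation problem sizes are desk-scale by design: a 1 Mb random genome
with 100,000 reads per indel rate for the accuracy grid, 200 kb/50k reads
for methylation parameter recovery, a 48 kb unmethylated "lambda"
chromosome for conversion efficiency. These keep the full suite in the
minutes range while leaving binomial errors far smaller than the effects
being measured.

## Numerical and design choices

- **Band definition.** The semi-global band allows target offsets
  `[−d, (m−n)+d]` relative to the query position, with row 0 free (any
  window start) and the distance taken as the minimum over the last row
  (any window end). The stand-alone `banded_edit_distance` is the classic
  global variant (`|i−j| ≤ d`, `D[0][j] = j`) and is checked against an
  unbanded DP and edlib in tests.
- **Tie-breaks.** Backtraces prefer diagonal moves, then insertions, then
  deletions; the alignment end prefers the smallest target offset. Ties
  between candidate windows resolve by vote count, then leftmost
  concatenation position. All choices are deterministic.
- **N handling.** Genome N and read N carry distinct internal codes, so N
  never matches N during extension; seeds containing N are neither
  indexed nor queried.
- **Degenerate inputs.** Empty genomes and zero-read requests are
  rejected; chromosomes shorter than the seed length stay in the
  concatenation (warning) but cannot seed; reads shorter than the seed
  length become unmapped; adapter trimming below the minimum read length
  marks the read discarded before alignment.
- **Chunk invariance.** Read files are split into contiguous chunks whose
  concatenation reproduces the record stream; since every per-read step
  is deterministic given the read id, SAM record sets and CGmap bytes are
  identical for any chunk count or worker count (asserted in tests).
- **Serialization.** Index directories hold a JSON manifest, raw `.npy`
  arrays and a FASTA copy of the genome; save→load→save is byte-identical
  (zip-based containers were avoided because they embed timestamps).
- **Non-directional mode** aligns both the read and its reverse
  complement through the directional path and keeps the better alignment.
  The reverse complement of a PCR-complement read *is* the original
  bisulfite strand, so methylation logic is unchanged downstream.
- **NM tag** equals the recounted bisulfite-aware mismatch count, which
  already includes indel bases, so indels are not double-counted.
- **Conversion efficiency** pools all contexts on the spike chromosome by
  default (`efficiency = converted / (converted + unconverted)`), with a
  `--ch-only` switch to restrict to CHG+CHH where residual CpG
  methylation of the spike is suspected.

## Estimator variance note

With complete conversion, every read over a cytosine reports that site's
Bernoulli methylome state deterministically; the binomial sample size of a
pooled methylation level is therefore the number of distinct covered
sites, not the number of calls. Recovery tests use the site-level
standard error accordingly, and additionally require the pooled level to
track the realized methylome fraction itself within 0.005.

## Known limitations

Single-end reads only; no soft-clipped local alignment (extension is
end-to-end over the read, so adapter read-through should be trimmed
first); no base-quality-aware scoring or quality trimming; multi-mapped
reads are reported unmapped-by-ambiguity rather than assigned; reads
failing the bisulfite recount are not rescued at secondary candidates;
the in-memory index targets genomes up to the tens-of-megabase range, not
mammalian-scale references.
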