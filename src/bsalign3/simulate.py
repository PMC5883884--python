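"""Bisulfite read simulation with known truth, and mapping-accuracy scoring.

The generator emulates a directional WGBS library: reads sampled uniformly
from both strands of a reference, unmethylated cytosines converted to T
with a given efficiency, then uniform substitution errors and single-base
insertions/deletions.  It does not model quality-score decay, GC bias or
PCR duplicates; tests passing on these reads demonstrate algorithmic
correctness, not robustness to platform-specific artefacts.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from .genome import CODE_COMPLEMENT, Genome, decode
from .methylation import _context_codes

DEFAULT_READ_LEN = 100
DEFAULT_SUB_RATE = 0.01
DEFAULT_CONVERSION_RATE = 0.99
INDEL_RATE_GRID = (0.0, 0.005, 0.01, 0.025)


def random_genome(
    lengths: Dict[str, int],
    seed: int,
    n_blocks: int = 0,
    n_block_len: int = 50,
) -> Genome:
    """Uniform-ACGT random genome; optionally with N stretches per chromosome."""
    rng = np.random.default_rng(seed)
    seqs = {}
    for name, length in lengths.items():
        codes = rng.integers(0, 4, size=length).astype(np.uint8)
        for _ in range(n_blocks):
            if length > n_block_len:
                start = int(rng.integers(0, length - n_block_len))
                codes[start : start + n_block_len] = 4
        seqs[name] = decode(codes)
    return Genome(list(lengths), seqs)


@dataclass
class Methylome:
    """Binary methylation state for every cytosine on both strands.

    ``plus[chrom][p]`` is meaningful where the Watson base is C,
    ``minus[chrom][p]`` where it is G (a Crick-strand cytosine).
    """

    plus: Dict[str, np.ndarray]
    minus: Dict[str, np.ndarray]

    def fraction_methylated(self, genome: Genome, context: str) -> float:
        """Fraction of methylated cytosines in one context (both strands)."""
        ctx_idx = {"CG": 0, "CHG": 1, "CHH": 2}[context]
        m = n = 0
        for chrom in genome.chrom_names:
            codes = genome.codes(chrom)
            for strand, states, base in (("+", self.plus[chrom], 1), ("-", self.minus[chrom], 2)):
                pos = np.flatnonzero(codes == base)
                if pos.size == 0:
                    continue
                ctx, _ = _context_codes(codes, pos, strand)
                sel = pos[ctx == ctx_idx]
                m += int(states[sel].sum())
                n += sel.size
        return m / n if n else float("nan")

    def clear_chrom(self, chrom: str) -> None:
        """Force a chromosome fully unmethylated (e.g. a lambda spike-in)."""
        self.plus[chrom][:] = False
        self.minus[chrom][:] = False


def simulate_methylome(
    genome: Genome,
    p_cg: float,
    p_chg: float,
    p_chh: float,
    seed: int,
    unmethylated_chroms: Sequence[str] = (),
) -> Methylome:
    """Independent Bernoulli methylation states with per-context probabilities."""
    for p in (p_cg, p_chg, p_chh):
        if not 0 <= p <= 1:
            raise ValueError("probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = np.array([p_cg, p_chg, p_chh, 0.0])
    plus: Dict[str, np.ndarray] = {}
    minus: Dict[str, np.ndarray] = {}
    for chrom in genome.chrom_names:
        codes = genome.codes(chrom)
        n = codes.size
        for strand, store, base in (("+", plus, 1), ("-", minus, 2)):
            states = np.zeros(n, dtype=bool)
            pos = np.flatnonzero(codes == base)
            if pos.size:
                ctx, _ = _context_codes(codes, pos, strand)
                states[pos] = rng.random(pos.size) < probs[ctx]
            store[chrom] = states
    meth = Methylome(plus, minus)
    for chrom in unmethylated_chroms:
        meth.clear_chrom(chrom)
    return meth


@dataclass(frozen=True)
class TruthRecord:
    chrom: str
    pos: int  # 0-based leftmost Watson coordinate of the pre-error locus
    strand: str
    n_subs: int
    n_indels: int


ReadTruth = Dict[str, TruthRecord]


def simulate_reads(
    genome: Genome,
    methylome: Methylome,
    n_reads: int,
    read_len: int = DEFAULT_READ_LEN,
    sub_rate: float = DEFAULT_SUB_RATE,
    indel_rate: float = 0.0,
    conversion_rate: float = DEFAULT_CONVERSION_RATE,
    directional: bool = True,
    seed: int = 0,
    fastq_path=None,
    truth_path=None,
    read_id_prefix: str = "simread",
) -> Tuple[Optional[Path], ReadTruth]:
    """Simulate bisulfite reads; returns (fastq path, truth ledger).

    Per read: origin uniform over both strands and all start positions;
    unmethylated Cs convert to T with probability *conversion_rate*; each
    base substitutes with *sub_rate* (uniform other base); each base
    additionally triggers an indel event with *indel_rate* (insertion of a
    random base or deletion, equal odds).  With ``directional=False`` half
    the reads are emitted as the PCR complement (reverse complement of the
    bisulfite strand).  Fully reproducible from *seed*.
    """
    for r in (sub_rate, indel_rate, conversion_rate):
        if not 0 <= r <= 1:
            raise ValueError("rates must be in [0, 1]")
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    lengths = genome.chrom_lengths
    usable = {c: n - read_len + 1 for c, n in lengths.items() if n >= read_len}
    if not usable:
        raise ValueError("read_len exceeds every chromosome length")
    chroms = list(usable)
    weights = np.array([usable[c] for c in chroms], dtype=float)
    weights /= weights.sum()

    rng = np.random.default_rng(seed)
    chrom_idx = rng.choice(len(chroms), size=n_reads, p=weights)
    strands = rng.integers(0, 2, size=n_reads)  # 0 '+', 1 '-'

    truth: ReadTruth = {}
    records = []
    for i in range(n_reads):
        chrom = chroms[chrom_idx[i]]
        codes = genome.codes(chrom)
        start = int(rng.integers(0, usable[chrom]))
        strand = "+" if strands[i] == 0 else "-"
        w = codes[start : start + read_len]
        if strand == "+":
            origin = w.copy()
            meth_states = methylome.plus[chrom][start : start + read_len]
        else:
            origin = CODE_COMPLEMENT[w[::-1]].copy()
            meth_states = methylome.minus[chrom][start : start + read_len][::-1]

        # bisulfite conversion of unmethylated cytosines
        is_c = origin == 1
        if is_c.any():
            convert = is_c & ~meth_states & (rng.random(read_len) < conversion_rate)
            origin[convert] = 3

        # substitution errors
        sub_mask = rng.random(read_len) < sub_rate
        n_subs = int(sub_mask.sum())
        if n_subs:
            shift = rng.integers(1, 4, size=n_subs).astype(np.uint8)
            origin[sub_mask] = (origin[sub_mask] + shift) % 4

        # single-base indels
        indel_mask = rng.random(read_len) < indel_rate
        n_indels = int(indel_mask.sum())
        if n_indels:
            out: List[int] = []
            where = set(np.flatnonzero(indel_mask).tolist())
            for j in range(read_len):
                if j in where:
                    if rng.random() < 0.5:  # deletion: drop this base
                        continue
                    out.append(int(origin[j]))
                    out.append(int(rng.integers(0, 4)))  # insertion after
                else:
                    out.append(int(origin[j]))
            final = np.array(out, dtype=np.uint8)
        else:
            final = origin

        if not directional and rng.random() < 0.5:
            final = CODE_COMPLEMENT[final[::-1]]

        rid = f"{read_id_prefix}_{i:07d}"
        seq = decode(final)
        records.append((rid, seq, "I" * len(seq)))
        truth[rid] = TruthRecord(chrom, start, strand, n_subs, n_indels)

    out_path = None
    if fastq_path is not None:
        from .read_prep import write_fastq

        write_fastq(records, fastq_path)
        out_path = Path(fastq_path)
    if truth_path is not None:
        write_truth(truth, truth_path)
    if fastq_path is None:
        return records, truth
    return out_path, truth


def write_truth(truth: ReadTruth, path) -> None:
    with open(path, "wt", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        for rid, t in truth.items():
            w.writerow([rid, t.chrom, t.pos, t.strand, t.n_subs, t.n_indels])


def read_truth(path) -> ReadTruth:
    truth: ReadTruth = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            truth[row[0]] = TruthRecord(row[1], int(row[2]), row[3], int(row[4]), int(row[5]))
    return truth


@dataclass
class AccuracyReport:
    n_reads: int
    n_mapped: int
    n_correct: int

    @property
    def mapability(self) -> float:
        return self.n_mapped / self.n_reads

    @property
    def pct_correct(self) -> float:
        return self.n_correct / self.n_reads


def evaluate_mapping(sam_path, truth: ReadTruth, tolerance_bp: int = 5) -> AccuracyReport:
    """Score alignments against the simulator's truth ledger.

    A read is correct iff uniquely mapped to the true chromosome and strand
    within *tolerance_bp* of the true leftmost coordinate (indels shift the
    reported coordinate by a few bases).  Multi-mapped reads are emitted
    unmapped-by-ambiguity by this pipeline and therefore count as unmapped.
    """
    n_mapped = 0
    n_correct = 0
    seen = set()
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            rid = rec.query_name
            if rid not in truth:
                raise ValueError(f"SAM read id {rid!r} absent from truth ledger")
            seen.add(rid)
            if rec.is_unmapped:
                continue
            n_mapped += 1
            t = truth[rid]
            strand = "-" if rec.is_reverse else "+"
            if (
                rec.reference_name == t.chrom
                and strand == t.strand
                and abs(rec.reference_start - t.pos) <= tolerance_bp
            ):
                n_correct += 1
    return AccuracyReport(n_reads=len(seen), n_mapped=n_mapped, n_correct=n_correct)
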