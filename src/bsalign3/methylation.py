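"""Per-cytosine methylation calling and CGmap output.

Every uniquely aligned read base that sits on a genome cytosine of the
read's origin strand is a methylation observation: a retained C means the
cytosine was protected (methylated), a T means it was converted
(unmethylated).  Sites are classified by their reference context — CG, CHG
or CHH (H = A, C or T), read downstream on the strand carrying the
cytosine — the standard plant/animal classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import pysam

from .genome import CODE_COMPLEMENT, Genome

logger = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")
_CTX_NAMES = np.array(["CG", "CHG", "CHH", "NA"])
_BASE = "ACGTN"

# codes: A=0 C=1 G=2 T=3, N>=4


@dataclass(frozen=True)
class MethSite:
    chrom: str
    pos: int  # 0-based Watson coordinate
    strand: str  # '+' cytosine on Watson, '-' on Crick
    context: str  # CG / CHG / CHH / NA
    dinucleotide: str  # the C and its next origin-strand base
    meth_count: int
    total_count: int

    @property
    def level(self) -> float:
        return self.meth_count / self.total_count


class MethTable:
    """Per-cytosine counts keyed by (chrom, pos, strand), sorted by position.

    Backed by a pandas DataFrame with columns
    ``chrom, pos, strand, context, dinucleotide, meth, total``.
    """

    def __init__(self, df: pd.DataFrame, chrom_lengths: Optional[Dict[str, int]] = None):
        df = df.reset_index(drop=True)
        if len(df) and df.duplicated(["chrom", "pos", "strand"]).any():
            raise ValueError("duplicate (chrom, pos, strand) keys in MethTable")
        self.df = df
        self.chrom_lengths = dict(chrom_lengths or {})

    def __len__(self) -> int:
        return len(self.df)

    def get(self, chrom: str, pos: int, strand: str) -> Optional[MethSite]:
        sel = self.df[
            (self.df.chrom == chrom) & (self.df.pos == pos) & (self.df.strand == strand)
        ]
        if sel.empty:
            return None
        r = sel.iloc[0]
        return MethSite(r.chrom, int(r.pos), r.strand, r.context, r.dinucleotide,
                        int(r.meth), int(r.total))

    def pooled_level(self, context: Optional[str] = None, chrom: Optional[str] = None) -> float:
        """Count-weighted methylation level Σmeth/Σtotal over a subset."""
        df = self.df
        if context is not None:
            df = df[df.context == context]
        if chrom is not None:
            df = df[df.chrom == chrom]
        total = df.total.sum()
        if total == 0:
            raise ValueError("no covered sites in selection")
        return float(df.meth.sum() / total)


def cytosine_context(genome: Genome, chrom: str, pos: int, strand: str) -> Tuple[str, str]:
    """Context (CG/CHG/CHH/NA) and dinucleotide of the cytosine at (chrom, pos, strand).

    Reads downstream on the origin strand: next base G -> CG; H then G ->
    CHG; H then H -> CHH.  Any N in the two-base window (or running off the
    chromosome end) gives NA.
    """
    seq = genome.chrom_seqs[chrom]
    if strand == "+":
        if pos >= len(seq) or seq[pos] != "C":
            raise ValueError(f"{chrom}:{pos} is not a Watson-strand cytosine")
        n1 = seq[pos + 1] if pos + 1 < len(seq) else "N"
        n2 = seq[pos + 2] if pos + 2 < len(seq) else "N"
    elif strand == "-":
        if pos < 0 or seq[pos] != "G":
            raise ValueError(f"{chrom}:{pos} is not a Crick-strand cytosine")
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
        n1 = comp[seq[pos - 1]] if pos - 1 >= 0 else "N"
        n2 = comp[seq[pos - 2]] if pos - 2 >= 0 else "N"
    else:
        raise ValueError(f"bad strand {strand!r}")
    dinuc = "C" + n1
    if n1 == "N" or (n1 != "G" and n2 == "N"):
        return "NA", dinuc
    if n1 == "G":
        return "CG", dinuc
    if n2 == "G":
        return "CHG", dinuc
    return "CHH", dinuc


def _context_codes(codes: np.ndarray, pos: np.ndarray, strand: str) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized context classification; returns (ctx_idx 0..3, next-base code)."""
    n = codes.size
    if strand == "+":
        n1 = np.where(pos + 1 < n, codes[np.minimum(pos + 1, n - 1)], 4)
        n2 = np.where(pos + 2 < n, codes[np.minimum(pos + 2, n - 1)], 4)
    else:
        n1 = np.where(pos - 1 >= 0, CODE_COMPLEMENT[codes[np.maximum(pos - 1, 0)]], 4)
        n2 = np.where(pos - 2 >= 0, CODE_COMPLEMENT[codes[np.maximum(pos - 2, 0)]], 4)
    is_h1 = (n1 != 2) & (n1 <= 3)
    is_h2 = (n2 != 2) & (n2 <= 3)
    ctx = np.full(pos.size, 3, dtype=np.int8)  # NA
    ctx[n1 == 2] = 0  # CG
    ctx[is_h1 & (n2 == 2)] = 1  # CHG
    ctx[is_h1 & is_h2] = 2  # CHH
    return ctx, n1


def _aligned_blocks(cigartuples, ref_start: int):
    """Yield (qstart, rstart, length) for each M block of a CIGAR."""
    q = 0
    r = ref_start
    for op, n in cigartuples:
        if op == 0:  # M
            yield q, r, n
            q += n
            r += n
        elif op == 1:  # I
            q += n
        elif op == 2:  # D
            r += n


def call_methylation(sam_path, genome: Genome, min_coverage: int = 1) -> MethTable:
    """Pile up methylation calls from unique alignments in a SAM file.

    Only records with an XO tag (this pipeline's origin-strand annotation)
    are used; records lacking it are skipped with a warning.  Read bases
    other than C/T on the origin strand, and indel-covered positions, are
    ignored.
    """
    meth = {c: {"+": None, "-": None} for c in genome.chrom_names}
    tot = {c: {"+": None, "-": None} for c in genome.chrom_names}
    for c in genome.chrom_names:
        n = len(genome.chrom_seqs[c])
        for s in "+-":
            meth[c][s] = np.zeros(n, dtype=np.int32)
            tot[c][s] = np.zeros(n, dtype=np.int32)

    n_skipped = 0
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            if not rec.has_tag("XO"):
                n_skipped += 1
                continue
            chrom = rec.reference_name
            ref_codes = genome.codes(chrom)
            read_codes = np.frombuffer(rec.query_sequence.encode(), dtype=np.uint8)
            read_codes = _READ_LUT[read_codes]
            strand = "-" if rec.is_reverse else "+"
            for qs, rs, ln in _aligned_blocks(rec.cigartuples, rec.reference_start):
                rseg = ref_codes[rs : rs + ln]
                qseg = read_codes[qs : qs + ln]
                if strand == "+":
                    # origin-strand C = Watson C; read base C/T observed directly
                    onref = rseg == 1
                    is_meth = qseg == 1
                    is_unmeth = qseg == 3
                else:
                    # origin-strand C = Watson G; forward read G=origin C, A=origin T
                    onref = rseg == 2
                    is_meth = qseg == 2
                    is_unmeth = qseg == 0
                obs = onref & (is_meth | is_unmeth)
                if not obs.any():
                    continue
                posn = rs + np.flatnonzero(obs)
                np.add.at(tot[chrom][strand], posn, 1)
                mpos = rs + np.flatnonzero(onref & is_meth)
                if mpos.size:
                    np.add.at(meth[chrom][strand], mpos, 1)
    if n_skipped:
        logger.warning("skipped %d mapped records lacking XO tag", n_skipped)

    frames = []
    for chrom in genome.chrom_names:
        codes = genome.codes(chrom)
        for strand in "+-":
            covered = np.flatnonzero(tot[chrom][strand] >= max(1, min_coverage))
            if covered.size == 0:
                continue
            ctx, n1 = _context_codes(codes, covered, strand)
            dinucs = np.array(["C" + _BASE[min(int(b), 4)] for b in n1])
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": covered,
                        "strand": strand,
                        "context": _CTX_NAMES[ctx],
                        "dinucleotide": dinucs,
                        "meth": meth[chrom][strand][covered],
                        "total": tot[chrom][strand][covered],
                    }
                )
            )
    if frames:
        df = pd.concat(frames, ignore_index=True)
        order = {c: i for i, c in enumerate(genome.chrom_names)}
        df = df.sort_values(
            ["chrom", "pos", "strand"],
            key=lambda col: col.map(order) if col.name == "chrom" else col,
            kind="stable",
        ).reset_index(drop=True)
    else:
        df = pd.DataFrame(
            columns=["chrom", "pos", "strand", "context", "dinucleotide", "meth", "total"]
        )
    return MethTable(df, genome.chrom_lengths)


_READ_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _READ_LUT[ord(_b)] = _i


def write_cgmap(table: MethTable, path) -> None:
    """Write the 8-column CGmap dialect (MethGo-compatible).

    Columns: chrom, Watson nucleotide (C for '+' sites, G for '-'),
    1-based position, context, dinucleotide, methylation level, methylated
    count, total count.  Sites with NA context are dropped.
    """
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "wt") as fh:
        for r in table.df.itertuples(index=False):
            if r.context == "NA":
                continue
            nuc = "C" if r.strand == "+" else "G"
            level = r.meth / r.total
            fh.write(
                f"{r.chrom}\t{nuc}\t{r.pos + 1}\t{r.context}\t{r.dinucleotide}\t"
                f"{level:.2f}\t{r.meth}\t{r.total}\n"
            )


def read_cgmap(path, chrom_lengths: Optional[Dict[str, int]] = None) -> MethTable:
    """Read a CGmap file back into a :class:`MethTable`."""
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "rt") as fh:
        df = pd.read_csv(
            fh,
            sep="\t",
            header=None,
            names=["chrom", "nuc", "pos1", "context", "dinucleotide", "level", "meth", "total"],
            dtype={"chrom": str},
        )
    out = pd.DataFrame(
        {
            "chrom": df.chrom,
            "pos": df.pos1 - 1,
            "strand": np.where(df.nuc == "C", "+", "-"),
            "context": df.context,
            "dinucleotide": df.dinucleotide,
            "meth": df.meth,
            "total": df.total,
        }
    )
    return MethTable(out, chrom_lengths)
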