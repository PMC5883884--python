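"""Post-alignment analytics: per-cycle mismatch QC, spike-in conversion
efficiency, genome-wide methylation windows, and metagene (metaplot)
profiles.

All aggregation is count-weighted: bins and windows pool methylated/total
counts and divide once, rather than averaging per-site levels, which keeps
low-coverage sites from dominating.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
import pysam

from .genome import Genome
from .methylation import CONTEXTS, MethTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# per-cycle mismatch profile


@dataclass
class MismatchProfile:
    """Bisulfite-aware mismatch rate per sequencing cycle."""

    mismatches: np.ndarray  # int64 per cycle
    coverage: np.ndarray  # aligned reads covering each cycle

    @property
    def rates(self) -> np.ndarray:
        """Mismatch rate per cycle; NaN where no observations."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.coverage > 0, self.mismatches / self.coverage, np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cycle": np.arange(self.coverage.size), "mismatches": self.mismatches,
             "coverage": self.coverage, "rate": self.rates}
        )


_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _LUT[ord(_b)] = _i


def mismatch_by_position(sam_path, genome: Genome, max_len: int = 512) -> MismatchProfile:
    """Per-cycle bisulfite-aware mismatch rates over unique alignments.

    A position counts as a mismatch when read and reference disagree in the
    origin-strand frame and the disagreement is not a conversion event
    (genome C / read T on the origin strand).  Reverse-strand reads are
    indexed in machine-cycle order (cycle 0 = first sequenced base).
    """
    mism = np.zeros(max_len, dtype=np.int64)
    cov = np.zeros(max_len, dtype=np.int64)
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or not rec.has_tag("XO"):
                continue
            ref_codes = genome.codes(rec.reference_name)
            read_codes = _LUT[np.frombuffer(rec.query_sequence.encode(), dtype=np.uint8)]
            rlen = len(rec.query_sequence)
            q = 0
            r = rec.reference_start
            for op, n in rec.cigartuples:
                if op == 0:
                    rseg = ref_codes[r : r + n]
                    qseg = read_codes[q : q + n]
                    if rec.is_reverse:
                        # forward frame: conversion = genome G with read A
                        bad = (qseg != rseg) & ~((rseg == 2) & (qseg == 0))
                        cycles = rlen - 1 - np.arange(q, q + n)
                    else:
                        bad = (qseg != rseg) & ~((rseg == 1) & (qseg == 3))
                        cycles = np.arange(q, q + n)
                    cyc = np.minimum(cycles, max_len - 1)
                    np.add.at(cov, cyc, 1)
                    np.add.at(mism, cyc[bad], 1)
                    q += n
                    r += n
                elif op == 1:
                    q += n
                elif op == 2:
                    r += n
    used = int(np.max(np.flatnonzero(cov)) + 1) if cov.any() else 0
    return MismatchProfile(mism[:used], cov[:used])


# ---------------------------------------------------------------------------
# conversion efficiency


@dataclass
class ConversionStats:
    converted: int
    unconverted: int

    @property
    def efficiency(self) -> float:
        return self.converted / (self.converted + self.unconverted)


def conversion_efficiency(table: MethTable, spike_chrom: str, ch_only: bool = False) -> ConversionStats:
    """Bisulfite conversion efficiency from an unmethylated spike-in genome.

    Every cytosine call on the spike chromosome should be converted (read
    T); residual C calls measure failed conversion.  ``ch_only`` restricts
    to CHG+CHH sites for genomes where CpG methylation is suspected.
    """
    df = table.df[table.df.chrom == spike_chrom]
    if ch_only:
        df = df[df.context.isin(("CHG", "CHH"))]
    total = int(df.total.sum())
    if total == 0:
        raise ValueError(f"no spike-in coverage on {spike_chrom!r}")
    unconverted = int(df.meth.sum())
    return ConversionStats(converted=total - unconverted, unconverted=unconverted)


# ---------------------------------------------------------------------------
# genome-wide windows


def genome_windows(table: MethTable, window_bp: int) -> Dict[str, pd.DataFrame]:
    """Count-weighted methylation level in non-overlapping windows.

    Returns, per chromosome, a DataFrame indexed by window start with one
    column per context (CG/CHG/CHH); windows with no covered sites are NaN.
    Chromosome extents come from the table's recorded chromosome lengths.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    out: Dict[str, pd.DataFrame] = {}
    for chrom, length in table.chrom_lengths.items():
        n_win = max(1, -(-length // window_bp))
        idx = np.arange(n_win) * window_bp
        frame = pd.DataFrame(
            {ctx: np.full(n_win, np.nan) for ctx in CONTEXTS}, index=pd.Index(idx, name="start")
        )
        sub = table.df[(table.df.chrom == chrom) & (table.df.context != "NA")]
        if len(sub):
            g = sub.groupby([sub.pos // window_bp, "context"], observed=True)[["meth", "total"]].sum()
            for (w, ctx), row in g.iterrows():
                if row.total > 0 and ctx in CONTEXTS:
                    frame.loc[w * window_bp, ctx] = row.meth / row.total
        out[chrom] = frame
    return out


# ---------------------------------------------------------------------------
# metaplot


@dataclass
class MetaplotProfile:
    """Mean methylation across scaled feature bodies with fixed flanks.

    ``levels[ctx]`` has ``flank_bins + body_bins + flank_bins`` entries; bin
    0 is always the upstream-most flank bin regardless of feature strand.
    """

    body_bins: int
    flank_bp: int
    flank_bins: int
    levels: Dict[str, np.ndarray]
    counts: Dict[str, np.ndarray]

    @property
    def n_bins(self) -> int:
        return 2 * self.flank_bins + self.body_bins

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({ctx: self.levels[ctx] for ctx in CONTEXTS})
        df.insert(0, "bin", np.arange(self.n_bins))
        seg = np.full(self.n_bins, "body", dtype=object)
        seg[: self.flank_bins] = "upstream"
        seg[self.flank_bins + self.body_bins :] = "downstream"
        df.insert(1, "segment", seg)
        return df


def metaplot(
    table: MethTable,
    features: List[Tuple[str, int, int, str]],
    body_bins: int = 60,
    flank_bp: int = 2000,
    flank_bins: int = 20,
) -> MetaplotProfile:
    """Average methylation profile over features (metagene plot).

    Each feature body (half-open interval) is split into *body_bins* equal
    fractions; *flank_bp* on each side is split into *flank_bins*.
    Reverse-strand features are mirrored so bin 0 is upstream.  Counts are
    pooled across features.
    """
    if not features:
        raise ValueError("empty feature set")
    n_bins = 2 * flank_bins + body_bins
    meth = {ctx: np.zeros(n_bins, dtype=np.int64) for ctx in CONTEXTS}
    tot = {ctx: np.zeros(n_bins, dtype=np.int64) for ctx in CONTEXTS}

    by_chrom = {}
    for chrom, sub in table.df.groupby("chrom", observed=True):
        sub = sub[sub.context != "NA"]
        by_chrom[chrom] = (
            sub.pos.to_numpy(),
            sub.context.to_numpy(),
            sub.meth.to_numpy(),
            sub.total.to_numpy(),
        )

    n_skipped = 0
    for chrom, start, end, strand in features:
        length = table.chrom_lengths.get(chrom)
        if end <= start or (length is not None and (start < 0 or end > length)):
            n_skipped += 1
            continue
        if chrom not in by_chrom:
            continue
        pos, ctxs, m, t = by_chrom[chrom]
        lo = np.searchsorted(pos, start - flank_bp, side="left")
        hi = np.searchsorted(pos, end + flank_bp, side="left")
        if hi <= lo:
            continue
        p = pos[lo:hi]
        body = end - start
        bins = np.empty(p.size, dtype=np.int64)
        up = p < start
        down = p >= end
        mid = ~up & ~down
        bins[up] = (p[up] - (start - flank_bp)) * flank_bins // flank_bp
        bins[mid] = flank_bins + (p[mid] - start) * body_bins // body
        bins[down] = flank_bins + body_bins + (p[down] - end) * flank_bins // flank_bp
        if strand == "-":
            bins = n_bins - 1 - bins
        for ctx in CONTEXTS:
            sel = ctxs[lo:hi] == ctx
            if sel.any():
                np.add.at(meth[ctx], bins[sel], m[lo:hi][sel])
                np.add.at(tot[ctx], bins[sel], t[lo:hi][sel])
    if n_skipped:
        logger.warning("skipped %d features outside genome bounds", n_skipped)

    levels = {}
    for ctx in CONTEXTS:
        with np.errstate(invalid="ignore", divide="ignore"):
            levels[ctx] = np.where(tot[ctx] > 0, meth[ctx] / tot[ctx], np.nan)
    return MetaplotProfile(body_bins, flank_bp, flank_bins, levels, tot)


def plot_metaplot(profile: MetaplotProfile, path) -> None:
    """Render a metaplot profile to an image file (thin layer; not tested)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    x = np.arange(profile.n_bins)
    for ctx in CONTEXTS:
        ax.plot(x, profile.levels[ctx], label=ctx)
    for edge in (profile.flank_bins, profile.flank_bins + profile.body_bins):
        ax.axvline(edge - 0.5, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("bin (upstream | body | downstream)")
    ax.set_ylabel("methylation level")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(str(path), dpi=120)
    plt.close(fig)


def plot_mismatch_profile(profile: MismatchProfile, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3))
    ax.plot(np.arange(profile.coverage.size), profile.rates)
    ax.set_xlabel("read position (cycle)")
    ax.set_ylabel("mismatch rate")
    fig.tight_layout()
    fig.savefig(str(path), dpi=120)
    plt.close(fig)


def read_features(path) -> List[Tuple[str, int, int, str]]:
    """Read features from BED6 (0-based half-open) or GFF3 (1-based closed).

    Format is chosen by extension (.bed vs .gff/.gff3); returns
    (chrom, start, end, strand) half-open 0-based tuples.
    """
    p = str(path)
    feats: List[Tuple[str, int, int, str]] = []
    if p.endswith((".gff", ".gff3")):
        df = pd.read_csv(
            p, sep="\t", comment="#", header=None,
            names=["chrom", "source", "type", "start", "end", "score", "strand", "phase", "attrs"],
            dtype={"chrom": str},
        )
        for r in df.itertuples(index=False):
            feats.append((r.chrom, int(r.start) - 1, int(r.end), r.strand if r.strand in "+-" else "+"))
    else:
        df = pd.read_csv(
            p, sep="\t", comment="#", header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
            dtype={"chrom": str}, usecols=range(6),
        )
        for r in df.itertuples(index=False):
            feats.append((r.chrom, int(r.start), int(r.end), r.strand if r.strand in "+-" else "+"))
    return feats
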