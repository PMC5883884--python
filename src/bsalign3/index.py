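"""Three-letter genome index: one hash index over Watson + Crick, C->T converted.

The Watson strand of every chromosome and the reverse complement (Crick)
strand are C->T converted and laid head-to-tail into a single concatenated
sequence — all Watson blocks first, then all Crick blocks, in chromosome
order.  A bisulfite read, itself C->T converted, then needs a single lookup
regardless of its strand of origin: Watson-origin reads hit a Watson block,
Crick-origin reads hit a Crick block.

Seeds (fixed-length k-mers, 2-bit packed) are stored as a sorted key array
with aligned positions; lookup is a binary search.  Seeds overlapping an N
are not indexed.
"""

from __future__ import annotations

import json
import logging
import warnings
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import List, Literal, Optional

import numpy as np

from . import _kernels
from .genome import Genome, decode, encode, revcomp, validate_dna

logger = logging.getLogger(__name__)

ConversionMode = Literal["C2T", "G2A"]

_C2T = str.maketrans("C", "T")
_G2A = str.maketrans("G", "A")

DEFAULT_SEED_LEN = 20
DEFAULT_MAX_SEED_HITS = 1000


def bisulfite_convert(seq: str, mode: ConversionMode) -> str:
    """In-silico bisulfite conversion: ``C2T`` maps C->T, ``G2A`` maps G->A.

    Length and every other character (including N) are preserved.
    """
    validate_dna(seq)
    if mode == "C2T":
        return seq.translate(_C2T)
    if mode == "G2A":
        return seq.translate(_G2A)
    raise ValueError(f"unknown conversion mode {mode!r}")


@dataclass(frozen=True)
class GenomicLocus:
    """A placed position: 0-based Watson coordinate of the leftmost aligned base."""

    chrom: str
    pos: int
    strand: str  # '+' read derives from Watson, '-' from Crick


@dataclass(frozen=True)
class Block:
    """One strand of one chromosome inside the concatenated sequence."""

    chrom: str
    strand: str  # '+' Watson block, '-' Crick block
    offset: int  # start in concat coordinates
    length: int


class BlockBoundaryError(ValueError):
    """An interval straddles a Watson/Crick or chromosome boundary."""


@dataclass
class ThreeLetterIndex:
    """Single hash index over the C2T-converted Watson+Crick concatenation."""

    genome: Genome
    seed_len: int
    max_seed_hits: int
    blocks: List[Block]
    concat_codes: np.ndarray  # uint8 codes of the converted concatenation
    sorted_keys: np.ndarray  # uint64, ascending
    sorted_pos: np.ndarray  # int64, concat start positions aligned to sorted_keys

    _block_starts: Optional[np.ndarray] = None

    @property
    def block_starts(self) -> np.ndarray:
        if self._block_starts is None:
            self._block_starts = np.array(
                [b.offset for b in self.blocks] + [self.concat_codes.size], dtype=np.int64
            )
        return self._block_starts

    @property
    def concat_seq(self) -> str:
        """The converted concatenation as a string (for inspection/tests)."""
        return decode(self.concat_codes)

    def n_seeds(self) -> int:
        return int(self.sorted_keys.size)

    # -- queries ---------------------------------------------------------

    def lookup_seed(self, seed: str) -> List[int]:
        """Exact-match start positions of *seed* in the concatenation, ascending."""
        if len(seed) != self.seed_len:
            raise ValueError(f"seed length {len(seed)} != index seed_len {self.seed_len}")
        codes = encode(seed)
        if (codes > 3).any():
            return []  # N-containing seeds are never indexed
        key = np.uint64(0)
        for c in codes:
            key = (key << np.uint64(2)) | np.uint64(c)
        lo = int(np.searchsorted(self.sorted_keys, key, side="left"))
        hi = int(np.searchsorted(self.sorted_keys, key, side="right"))
        return [int(p) for p in self.sorted_pos[lo:hi]]

    def block_of(self, concat_pos: int) -> Block:
        starts = self.block_starts
        if not (0 <= concat_pos < self.concat_codes.size):
            raise BlockBoundaryError(f"concat position {concat_pos} outside concatenation")
        i = bisect_right(starts.tolist(), concat_pos) - 1
        return self.blocks[i]

    def concat_to_genomic(self, concat_pos: int, aln_len: int) -> GenomicLocus:
        """Map a concat interval back to (chrom, Watson-leftmost pos, strand).

        Raises :class:`BlockBoundaryError` when the interval straddles a
        block boundary.
        """
        if aln_len < 0:
            raise ValueError("aln_len must be non-negative")
        block = self.block_of(concat_pos)
        if concat_pos + aln_len > block.offset + block.length:
            raise BlockBoundaryError(
                f"interval [{concat_pos},{concat_pos + aln_len}) straddles a block boundary"
            )
        local = concat_pos - block.offset
        if block.strand == "+":
            return GenomicLocus(block.chrom, local, "+")
        return GenomicLocus(block.chrom, block.length - local - aln_len, "-")

    def genomic_to_concat(self, chrom: str, pos: int, strand: str, length: int) -> int:
        """Inverse of :meth:`concat_to_genomic`: concat start of a genomic interval."""
        for block in self.blocks:
            if block.chrom == chrom and block.strand == strand:
                if strand == "+":
                    return block.offset + pos
                return block.offset + (block.length - pos - length)
        raise KeyError(f"no block for {chrom!r} strand {strand!r}")

    # -- persistence -----------------------------------------------------

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = {
            "format_version": 1,
            "seed_len": self.seed_len,
            "max_seed_hits": self.max_seed_hits,
            "genome_checksum": self.genome.checksum(),
            "chrom_names": self.genome.chrom_names,
            "chrom_lengths": [len(self.genome.chrom_seqs[c]) for c in self.genome.chrom_names],
            "blocks": [
                {"chrom": b.chrom, "strand": b.strand, "offset": b.offset, "length": b.length}
                for b in self.blocks
            ],
        }
        with open(outdir / "manifest.json", "wt") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        np.save(outdir / "seed_keys.npy", self.sorted_keys)
        np.save(outdir / "seed_pos.npy", self.sorted_pos)
        self.genome.to_fasta(outdir / "genome.fa")

    @classmethod
    def load(cls, indexdir) -> "ThreeLetterIndex":
        indexdir = Path(indexdir)
        with open(indexdir / "manifest.json") as fh:
            manifest = json.load(fh)
        genome = Genome.from_fasta(indexdir / "genome.fa")
        if genome.checksum() != manifest["genome_checksum"]:
            raise ValueError("index genome checksum mismatch")
        blocks = [Block(b["chrom"], b["strand"], b["offset"], b["length"]) for b in manifest["blocks"]]
        concat_codes = _build_concat_codes(genome)
        return cls(
            genome=genome,
            seed_len=int(manifest["seed_len"]),
            max_seed_hits=int(manifest["max_seed_hits"]),
            blocks=blocks,
            concat_codes=concat_codes,
            sorted_keys=np.load(indexdir / "seed_keys.npy"),
            sorted_pos=np.load(indexdir / "seed_pos.npy"),
        )


def _build_concat_codes(genome: Genome) -> np.ndarray:
    parts = []
    for _, seq in genome:
        parts.append(encode(bisulfite_convert(seq, "C2T")))
    for _, seq in genome:
        parts.append(encode(bisulfite_convert(revcomp(seq), "C2T")))
    return np.concatenate(parts) if parts else np.empty(0, np.uint8)


def build_genome_index(
    genome: Genome,
    seed_len: int = DEFAULT_SEED_LEN,
    max_seed_hits: int = DEFAULT_MAX_SEED_HITS,
) -> ThreeLetterIndex:
    """Build the three-letter index for *genome*.

    Chromosomes shorter than *seed_len* stay in the concatenation (they
    cannot contribute seeds) and trigger a warning.
    """
    if not genome.chrom_names:
        raise ValueError("empty genome")
    # practical range is 8-32; tiny seeds are permitted for toy genomes/tests
    if not (2 <= seed_len <= 32):
        raise ValueError("seed_len must be in [2, 32]")
    short = [c for c, n in genome.chrom_lengths.items() if n < seed_len]
    if short:
        warnings.warn(f"chromosomes shorter than seed_len contribute no seeds: {short}")

    blocks: List[Block] = []
    offset = 0
    for name, seq in genome:
        blocks.append(Block(name, "+", offset, len(seq)))
        offset += len(seq)
    for name, seq in genome:
        blocks.append(Block(name, "-", offset, len(seq)))
        offset += len(seq)

    concat_codes = _build_concat_codes(genome)
    keys, valid = _kernels.genome_seed_scan(concat_codes, seed_len)
    pos = np.flatnonzero(valid).astype(np.int64)
    kv = keys[valid]
    order = np.argsort(kv, kind="stable")  # stable keeps positions ascending per key
    index = ThreeLetterIndex(
        genome=genome,
        seed_len=seed_len,
        max_seed_hits=max_seed_hits,
        blocks=blocks,
        concat_codes=concat_codes,
        sorted_keys=np.ascontiguousarray(kv[order]),
        sorted_pos=np.ascontiguousarray(pos[order]),
    )
    logger.info(
        "built index: %d bp concatenation, %d seeds (k=%d)",
        concat_codes.size,
        index.n_seeds(),
        seed_len,
    )
    return index
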