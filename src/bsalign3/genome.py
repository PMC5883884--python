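"""Reference genome container and low-level DNA utilities.

Sequences are stored as uppercase Python strings over ``{A, C, G, T, N}``.
Hot paths work on ``uint8`` code arrays instead: A=0, C=1, G=2, T=3, with
two distinct codes for ``N`` (4 for genome sequences, 5 for read sequences)
so that an N on one side never silently matches an N on the other during
alignment.
"""

from __future__ import annotations

import gzip
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Tuple

import numpy as np
from Bio import SeqIO

DNA_ALPHABET = frozenset("ACGTN")

GENOME_N = 4
READ_N = 5

_BASES = "ACGTN"
_CODE_GENOME = np.full(256, GENOME_N, dtype=np.uint8)
_CODE_READ = np.full(256, READ_N, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE_GENOME[ord(_b)] = _i
    _CODE_READ[ord(_b)] = _i

# complement in code space; both N codes map to themselves
CODE_COMPLEMENT = np.array([3, 2, 1, 0, 4, 5], dtype=np.uint8)

_COMPLEMENT_TABLE = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return seq.translate(_COMPLEMENT_TABLE)[::-1]


def validate_dna(seq: str) -> None:
    """Raise ``ValueError`` if *seq* contains a non-ACGTN character."""
    extra = set(seq) - DNA_ALPHABET
    if extra:
        raise ValueError(f"invalid DNA alphabet: unexpected characters {sorted(extra)!r}")


def encode(seq: str, *, read: bool = False) -> np.ndarray:
    """Encode a DNA string as a uint8 code array (A=0 C=1 G=2 T=3, N=4/5)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    table = _CODE_READ if read else _CODE_GENOME
    return table[raw]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode` (both N codes render as ``N``)."""
    lut = np.frombuffer(b"ACGTNN", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def _open_text(path) -> Iterator[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


@dataclass
class Genome:
    """An ordered collection of named chromosomes.

    Parameters
    ----------
    chrom_names:
        Chromosome names in file order; must be unique.
    chrom_seqs:
        Mapping name -> uppercase sequence over ``{A,C,G,T,N}``.
    """

    chrom_names: List[str]
    chrom_seqs: Dict[str, str]
    _codes: Dict[str, np.ndarray] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        if set(self.chrom_names) != set(self.chrom_seqs):
            raise ValueError("chrom_names and chrom_seqs disagree")
        for name in self.chrom_names:
            seq = self.chrom_seqs[name].upper()
            validate_dna(seq)
            self.chrom_seqs[name] = seq

    @property
    def chrom_lengths(self) -> Dict[str, int]:
        return {name: len(self.chrom_seqs[name]) for name in self.chrom_names}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chrom_seqs.values())

    def codes(self, chrom: str) -> np.ndarray:
        """Cached uint8 encoding of a chromosome (genome N code)."""
        if chrom not in self._codes:
            self._codes[chrom] = encode(self.chrom_seqs[chrom])
        return self._codes[chrom]

    def checksum(self) -> str:
        """MD5 over names and sequences; identifies the genome in index manifests."""
        h = hashlib.md5()
        for name in self.chrom_names:
            h.update(name.encode())
            h.update(b"\0")
            h.update(self.chrom_seqs[name].encode())
            h.update(b"\0")
        return h.hexdigest()

    def __iter__(self) -> Iterator[Tuple[str, str]]:
        for name in self.chrom_names:
            yield name, self.chrom_seqs[name]

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        names: List[str] = []
        seqs: Dict[str, str] = {}
        with _open_text(path) as fh:
            for rec in SeqIO.parse(fh, "fasta"):
                names.append(rec.id)
                seqs[rec.id] = str(rec.seq).upper()
        if not names:
            raise ValueError(f"no FASTA records in {path}")
        return cls(names, seqs)

    def to_fasta(self, path, width: int = 60) -> None:
        with open(path, "wt") as fh:
            for name, seq in self:
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")
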