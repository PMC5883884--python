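"""FASTQ handling: adapter trimming, in-silico read conversion, chunking."""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, List, Literal, Optional, Tuple

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .genome import validate_dna
from .index import bisulfite_convert

# TruSeq single-index read-1 adapter prefix
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"
DEFAULT_MIN_OVERLAP = 3
DEFAULT_MIN_READ_LEN = 20

LibraryMode = Literal["directional", "non_directional"]


@dataclass
class BisRead:
    """A sequencing read with its in-silico C2T conversion alongside.

    ``converted_seq`` is what gets aligned against the three-letter index;
    ``original_seq`` is kept for bisulfite-aware mismatch recounting and
    methylation calling.
    """

    read_id: str
    original_seq: str
    quals: str
    library_mode: LibraryMode = "directional"
    discarded: bool = False
    converted_seq: str = field(default="")

    def __post_init__(self) -> None:
        if len(self.original_seq) != len(self.quals):
            raise ValueError(f"read {self.read_id}: sequence/quality length mismatch")
        self.original_seq = self.original_seq.upper()
        validate_dna(self.original_seq)
        if not self.converted_seq:
            self.converted_seq = bisulfite_convert(self.original_seq, "C2T")

    def __len__(self) -> int:
        return len(self.original_seq)


def convert_read(read_seq: str, orientation: Literal["C2T", "G2A"]) -> str:
    """Convert a read for three-letter lookup (C2T; G2A for non-directional)."""
    return bisulfite_convert(read_seq, orientation)


def trim_adapter(
    read: BisRead,
    adapter: str = DEFAULT_ADAPTER,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_read_len: int = DEFAULT_MIN_READ_LEN,
) -> BisRead:
    """Remove the longest read suffix that matches a prefix of *adapter*.

    A suffix starting at read position i matches when the overlap is at
    least *min_overlap* bases with at most 10% mismatches (no indels).  The
    longest such suffix (smallest i) is removed; quality string and the
    converted sequence are trimmed in lockstep.  Reads shorter than
    *min_read_len* after trimming are marked discarded.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    seq = read.original_seq
    n = len(seq)
    alen = len(adapter)
    cut = n
    for i in range(0, n - min_overlap + 1):
        olen = min(n - i, alen)
        if olen < min_overlap:
            break
        allowed = olen // 10
        mism = 0
        for a, b in zip(seq[i : i + olen], adapter[:olen]):
            if a != b:
                mism += 1
                if mism > allowed:
                    break
        if mism <= allowed:
            cut = i
            break
    if cut == n:
        return read
    trimmed = replace(
        read,
        original_seq=seq[:cut],
        quals=read.quals[:cut],
        converted_seq=read.converted_seq[:cut],
        discarded=cut < min_read_len,
    )
    return trimmed


def read_fastq(path) -> Iterator[Tuple[str, str, str]]:
    """Yield (read_id, sequence, quality) tuples; gzip transparent.

    Malformed records raise ``ValueError`` naming the failing record index.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    count = 0
    with opener(path, "rt") as fh:
        it = FastqGeneralIterator(fh)
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record #{count} in {path}: {exc}") from exc
            count += 1
            yield title.split()[0], seq, qual


def write_fastq(records, path) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def count_fastq_records(path) -> int:
    return sum(1 for _ in read_fastq(path))


def chunk_fastq(path, n_chunks: int, outdir: Optional[Path] = None) -> List[Path]:
    """Split a FASTQ file into *n_chunks* contiguous, order-preserving chunks.

    The first ``n_records % n_chunks`` chunks carry one extra record;
    concatenating the chunks reproduces the input record stream.  Chunks
    that would be empty are not created.
    """
    if n_chunks < 1:
        raise ValueError("n_chunks must be >= 1")
    path = Path(path)
    if outdir is None:
        outdir = path.parent
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    total = count_fastq_records(path)
    base, extra = divmod(total, n_chunks)
    sizes = [base + (1 if i < extra else 0) for i in range(n_chunks)]
    sizes = [s for s in sizes if s > 0]

    stem = path.name.removesuffix(".gz")
    paths: List[Path] = []
    reader = read_fastq(path)
    for i, size in enumerate(sizes):
        chunk_path = outdir / f"{stem}.chunk{i:03d}.fq"
        with open(chunk_path, "wt") as fh:
            for _ in range(size):
                rid, seq, qual = next(reader)
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
        paths.append(chunk_path)
    return paths
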