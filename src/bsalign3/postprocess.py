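"""Bisulfite-aware mismatch recounting in original base space, and SAM output.

The three-letter alignment is blind to the asymmetry of bisulfite matching:
a genome C read as T is legitimate conversion, but a read C over a genome T
is a real mismatch that the converted comparison cannot see.  Every unique
alignment is therefore re-scored against the *unconverted* reference in the
read's origin-strand frame.  Positions are visited in a pseudo-random order
seeded from the read id — mismatches on a bad alignment are roughly
uniformly spread, so a random visit order lets the scan hit the mismatch
budget and bail out early — and the per-read seeding keeps results
independent of chunking and thread count.
"""

from __future__ import annotations

import random
import zlib
from dataclasses import dataclass
from typing import Iterable, Optional, Tuple

import pysam

from .align import AlignmentResult
from .genome import Genome, revcomp
from .read_prep import BisRead

UNMAPPED_REASONS = {
    "ambiguous": "multiple",
    "no_alignment": "no_alignment",
    "block_boundary": "block_boundary",
    "recount": "too_many_bis_mismatches",
}


@dataclass
class BisMismatchReport:
    bis_mismatches: int
    conversions: int
    positions_evaluated: int
    accepted: bool


def _read_rng(read_id: str) -> random.Random:
    return random.Random(zlib.crc32(read_id.encode()) & 0x7FFFFFFF)


def origin_strand_reference(genome: Genome, aln: AlignmentResult) -> str:
    """Unconverted reference segment in the read's origin-strand orientation."""
    locus = aln.locus
    seg = genome.chrom_seqs[locus.chrom][locus.pos : locus.pos + aln.aln_len]
    return seg if locus.strand == "+" else revcomp(seg)


def recount_mismatches(
    aln: AlignmentResult,
    original_seq: str,
    genome: Genome,
    max_mismatches: int,
    read_id: str,
) -> BisMismatchReport:
    """Re-count mismatches bisulfite-aware against the unconverted reference.

    Per aligned position (origin-strand frame): equal bases match; genome C
    with read T is a conversion event (not a mismatch); any other
    inequality — notably read C over genome T — is a mismatch.  Indel ops
    contribute their full length.  Substitution positions are visited in a
    read-id-seeded random order and the scan stops as soon as the mismatch
    count exceeds *max_mismatches*.
    """
    if aln.status != "unique":
        raise ValueError("recount requires a unique alignment")
    script = aln.script
    if script.read_len != len(original_seq) or script.target_len != aln.aln_len:
        raise ValueError(
            f"read {read_id}: edit script inconsistent with sequence lengths "
            f"(script read {script.read_len} vs {len(original_seq)}, "
            f"target {script.target_len} vs {aln.aln_len})"
        )
    ref = origin_strand_reference(genome, aln)

    pairs = [
        (q, t) for q, t in script.aligned_pairs() if q is not None and t is not None
    ]
    bis = script.n_indel_bases  # indels are mismatches by definition
    conversions = 0
    evaluated = 0
    if bis > max_mismatches:
        return BisMismatchReport(bis, 0, 0, False)

    order = list(range(len(pairs)))
    _read_rng(read_id).shuffle(order)
    for k in order:
        q, t = pairs[k]
        rb = original_seq[q]
        gb = ref[t]
        evaluated += 1
        if rb == gb:
            continue
        if gb == "C" and rb == "T":
            conversions += 1
            continue
        bis += 1
        if bis > max_mismatches:
            return BisMismatchReport(bis, conversions, evaluated, False)
    return BisMismatchReport(bis, conversions, evaluated, True)


def sam_header(genome: Genome, program: str = "bsalign3") -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": name, "LN": length}
                for name, length in genome.chrom_lengths.items()
            ],
            "PG": [{"ID": program, "PN": program}],
        }
    )


def to_sam_record(
    read: BisRead,
    aln: AlignmentResult,
    report: Optional[BisMismatchReport],
    header: pysam.AlignmentHeader,
    effective_seq: Optional[str] = None,
) -> pysam.AlignedSegment:
    """Build one SAM record.

    Unique alignments get FLAG 0/16, 1-based POS, CIGAR with X folded into
    M, NM (bisulfite-aware mismatches incl. indel bases) and tags
    XO (origin strand), XM (bis mismatches), XC (conversion events).
    Everything else is emitted unmapped (FLAG 4) with reason tag XR.
    """
    seg = pysam.AlignedSegment(header)
    seg.query_name = read.read_id
    seq = effective_seq if effective_seq is not None else read.original_seq
    quals = read.quals
    if aln.status != "unique":
        seg.flag = 4
        seg.query_sequence = seq
        seg.query_qualities = pysam.qualitystring_to_array(quals)
        reason = UNMAPPED_REASONS.get(aln.reason or "", aln.reason or "unmapped")
        seg.set_tag("XR", reason, "Z")
        return seg

    locus = aln.locus
    script = aln.script if locus.strand == "+" else aln.script.reversed()
    if locus.strand == "-":
        seq = revcomp(seq)
        quals = quals[::-1]
    seg.flag = 0 if locus.strand == "+" else 16
    seg.reference_id = header.get_tid(locus.chrom)
    seg.reference_start = locus.pos
    seg.mapping_quality = 40
    seg.cigarstring = script.cigar()
    seg.query_sequence = seq
    seg.query_qualities = pysam.qualitystring_to_array(quals)
    nm = report.bis_mismatches if report is not None else aln.edit_distance
    seg.set_tag("NM", int(nm), "i")
    seg.set_tag("XO", "+W" if locus.strand == "+" else "-C", "Z")
    if report is not None:
        seg.set_tag("XM", int(report.bis_mismatches), "i")
        seg.set_tag("XC", int(report.conversions), "i")
    return seg


def emit_sam(
    records: Iterable[Tuple[BisRead, AlignmentResult, Optional[BisMismatchReport]]],
    genome: Genome,
    path,
) -> int:
    """Write finished pipeline records to a SAM file; returns record count."""
    header = sam_header(genome)
    n = 0
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for read, aln, report in records:
            out.write(to_sam_record(read, aln, report, header))
            n += 1
    return n
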