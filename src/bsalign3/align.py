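"""Seed-and-extend alignment of converted reads against the three-letter index.

A read is broken into fixed-length seeds, each looked up exactly in the
index; seed hits vote for diagonals (implied read-start positions in the
concatenation); diagonal clusters become candidates which are extended with
a banded edit-distance check (Ukkonen cutoff) of the whole read against the
candidate window.  The best candidate wins if its distance is within the
edit budget and the runner-up is at least ``uniqueness_gap`` edits worse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import _kernels
from ._kernels import INF
from .genome import encode, revcomp
from .index import BlockBoundaryError, GenomicLocus, ThreeLetterIndex, bisulfite_convert
from .read_prep import BisRead

_OP_CHARS = "MXID"


@dataclass(frozen=True)
class CandidateHit:
    """A diagonal (implied read start in concat coordinates) with seed support."""

    concat_pos: int
    votes: int


@dataclass
class EditScript:
    """Run-length alignment operations in query (origin-strand) order.

    M = match, X = substitution, I = insertion in read (consumes query),
    D = deletion from read (consumes target).  Adjacent runs of the same op
    are merged on construction.
    """

    ops: List[Tuple[str, int]]

    def __post_init__(self) -> None:
        merged: List[Tuple[str, int]] = []
        for op, length in self.ops:
            if op not in _OP_CHARS:
                raise ValueError(f"bad op {op!r}")
            if length <= 0:
                continue
            if merged and merged[-1][0] == op:
                merged[-1] = (op, merged[-1][1] + length)
            else:
                merged.append((op, length))
        self.ops = merged

    @classmethod
    def from_op_codes(cls, codes: Sequence[int]) -> "EditScript":
        return cls([(_OP_CHARS[c], 1) for c in codes])

    @property
    def read_len(self) -> int:
        return sum(n for op, n in self.ops if op in "MXI")

    @property
    def target_len(self) -> int:
        return sum(n for op, n in self.ops if op in "MXD")

    @property
    def n_substitutions(self) -> int:
        return sum(n for op, n in self.ops if op == "X")

    @property
    def n_indel_bases(self) -> int:
        return sum(n for op, n in self.ops if op in "ID")

    @property
    def distance(self) -> int:
        return self.n_substitutions + self.n_indel_bases

    def cigar(self) -> str:
        """CIGAR string with X folded into M."""
        parts: List[Tuple[str, int]] = []
        for op, n in self.ops:
            c = "M" if op in "MX" else op
            if parts and parts[-1][0] == c:
                parts[-1] = (c, parts[-1][1] + n)
            else:
                parts.append((c, n))
        return "".join(f"{n}{c}" for c, n in parts)

    def reversed(self) -> "EditScript":
        return EditScript(list(reversed(self.ops)))

    def aligned_pairs(self) -> List[Tuple[Optional[int], Optional[int]]]:
        """(query_offset, target_offset) pairs; None marks a gap side."""
        out: List[Tuple[Optional[int], Optional[int]]] = []
        qi = ti = 0
        for op, n in self.ops:
            for _ in range(n):
                if op in "MX":
                    out.append((qi, ti))
                    qi += 1
                    ti += 1
                elif op == "I":
                    out.append((qi, None))
                    qi += 1
                else:
                    out.append((None, ti))
                    ti += 1
        return out


@dataclass
class AlignmentResult:
    status: str  # 'unique' | 'multiple' | 'unmapped'
    locus: Optional[GenomicLocus] = None
    edit_distance: Optional[int] = None  # three-letter-space distance
    script: Optional[EditScript] = None
    second_best_distance: Optional[int] = None
    aln_len: int = 0  # reference span length
    orientation: str = "fwd"  # 'rc' when the reverse complement aligned (non-directional)
    reason: Optional[str] = None  # set for unmapped/multiple


@dataclass
class AlignerParams:
    """Tunable alignment parameters.

    ``max_edit_distance=None`` resolves per read to
    ``max(4, ceil(0.06 * read_len))`` — wide enough that reads carrying the
    expected error load of a high-indel library (~3.3 three-letter edits
    per 100 bp at indel rate 0.025) still pass the budget.
    """

    stride: Optional[int] = None  # None -> seed_len (non-overlapping seeds)
    max_edit_distance: Optional[int] = None
    uniqueness_gap: int = 2
    max_seed_hits: Optional[int] = None  # None -> index default
    max_candidates: int = 50
    non_directional: bool = False

    def resolve_max_d(self, read_len: int) -> int:
        if self.max_edit_distance is not None:
            return self.max_edit_distance
        return max(4, math.ceil(0.06 * read_len))


def extract_seeds(converted_seq: str, seed_len: int, stride: int) -> List[Tuple[int, str]]:
    """Seeds at offsets 0, stride, ... plus a flush-right seed; N seeds skipped."""
    offs, _keys = _kernels.read_seed_keys(encode(converted_seq, read=True), seed_len, stride)
    return [(int(o), converted_seq[o : o + seed_len]) for o in offs]


def collect_candidates(
    index: ThreeLetterIndex,
    seeds: List[Tuple[int, str]],
    max_seed_hits: Optional[int] = None,
) -> List[CandidateHit]:
    """Vote seed hits onto diagonals and merge nearby diagonals.

    Diagonals within ``max_edit_distance`` of each other collapse into one
    candidate whose position is the smallest diagonal and whose vote count
    is the total hit count of the cluster.  Candidates are sorted by votes
    descending, ties by position ascending.
    """
    if max_seed_hits is None:
        max_seed_hits = index.max_seed_hits
    diags: List[np.ndarray] = []
    for off, seed in seeds:
        hits = index.lookup_seed(seed)
        if not hits or len(hits) > max_seed_hits:
            continue
        diags.append(np.asarray(hits, dtype=np.int64) - off)
    # merge radius: per-read max_d is not known here, use a conservative default
    return _cluster_diagonals(diags, merge_radius=8)


def _cluster_diagonals(diags: List[np.ndarray], merge_radius: int) -> List[CandidateHit]:
    if not diags:
        return []
    ds = np.sort(np.concatenate(diags))
    if ds.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(ds) > merge_radius) + 1
    starts = np.concatenate(([0], breaks))
    ends = np.concatenate((breaks, [ds.size]))
    reps = ds[starts]
    votes = ends - starts
    order = np.lexsort((reps, -votes))
    return [CandidateHit(int(reps[i]), int(votes[i])) for i in order]


def banded_edit_distance(query, target, max_d: int):
    """Unit-cost Levenshtein distance with an Ukkonen band of half-width *max_d*.

    Returns ``(distance, EditScript)`` when the distance is at most *max_d*,
    else ``(math.inf, None)``.  Only DP cells with ``|i - j| <= max_d`` are
    explored; whenever the true (unbanded) distance is within the band the
    result equals the full dynamic program.  Works on arbitrary sequences.
    """
    if max_d < 0:
        raise ValueError("max_d must be >= 0")
    n, m = len(query), len(target)
    if abs(n - m) > max_d:
        return math.inf, None
    width = 2 * max_d + 1
    big = INF
    D = [[big] * width for _ in range(n + 1)]
    # col for (i, j): j - i + max_d
    for j in range(0, min(m, max_d) + 1):
        D[0][j + max_d] = j
    for i in range(1, n + 1):
        rowmin = big
        qi = query[i - 1]
        for col in range(width):
            j = i + col - max_d
            if j < 0 or j > m:
                continue
            v = big
            if j >= 1 and D[i - 1][col] < big:
                v = D[i - 1][col] + (0 if target[j - 1] == qi else 1)
            if col + 1 < width and D[i - 1][col + 1] < big:
                v = min(v, D[i - 1][col + 1] + 1)
            if col >= 1 and j >= 1 and D[i][col - 1] < big:
                v = min(v, D[i][col - 1] + 1)
            D[i][col] = v
            rowmin = min(rowmin, v)
        if rowmin > max_d:
            return math.inf, None
    dist = D[n][m - n + max_d]
    if dist > max_d:
        return math.inf, None
    # backtrace: prefer diagonal, then insertion (up), then deletion (left)
    ops: List[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        col = j - i + max_d
        v = D[i][col]
        if i > 0 and j > 0 and D[i - 1][col] < big:
            sub = 0 if target[j - 1] == query[i - 1] else 1
            if D[i - 1][col] + sub == v:
                ops.append("M" if sub == 0 else "X")
                i -= 1
                j -= 1
                continue
        if i > 0 and col + 1 < width and D[i - 1][col + 1] < big and D[i - 1][col + 1] + 1 == v:
            ops.append("I")
            i -= 1
            continue
        ops.append("D")
        j -= 1
    return dist, EditScript([(op, 1) for op in reversed(ops)])


# ---------------------------------------------------------------------------
# per-read alignment


def _align_codes(
    conv_codes: np.ndarray,
    index: ThreeLetterIndex,
    params: AlignerParams,
) -> Tuple[int, int, int, int, int]:
    """Core candidate evaluation on a converted read code array.

    Returns (best_d, best_wstart, best_jstart_dist_call_marker, second_d, n_cands)
    packed as (best_d, win_start, win_end, second_d, n_candidates); best_d is
    INF when nothing aligns.  The winning window is re-traced by the caller.
    """
    n = conv_codes.size
    seed_len = index.seed_len
    stride = params.stride or seed_len
    max_d = params.resolve_max_d(n)
    max_hits = params.max_seed_hits or index.max_seed_hits

    offs, keys = _kernels.read_seed_keys(conv_codes, seed_len, stride)
    if offs.size == 0:
        return INF, -1, -1, INF, 0
    lo = np.searchsorted(index.sorted_keys, keys, side="left")
    hi = np.searchsorted(index.sorted_keys, keys, side="right")
    diags: List[np.ndarray] = []
    for s in range(offs.size):
        cnt = hi[s] - lo[s]
        if cnt == 0 or cnt > max_hits:
            continue
        diags.append(index.sorted_pos[lo[s] : hi[s]] - offs[s])
    cands = _cluster_diagonals(diags, merge_radius=max_d)
    if not cands:
        return INF, -1, -1, INF, 0

    concat = index.concat_codes
    starts = index.block_starts
    total = concat.size
    best_d = INF
    best_win = (-1, -1)
    best_votes = -1
    second_d = INF
    for rank, cand in enumerate(cands):
        if rank >= params.max_candidates:
            break
        if best_d == 0 and cand.votes < best_votes:
            break  # no equally-supported rival left that could tie at zero
        diag = min(max(cand.concat_pos, 0), total - 1)
        b = int(np.searchsorted(starts, diag, side="right")) - 1
        bstart, bend = int(starts[b]), int(starts[b + 1])
        wstart = max(bstart, cand.concat_pos - max_d)
        wend = min(bend, cand.concat_pos + n + max_d)
        if wend - wstart < n - max_d:
            continue
        d, _jend = _kernels.semiglobal_distance(conv_codes, concat[wstart:wend], max_d)
        if d < best_d:
            second_d = best_d
            best_d = d
            best_win = (wstart, wend)
            best_votes = cand.votes
        elif d < second_d:
            second_d = d
        if best_d == 0 and second_d == 0:
            break
    return best_d, best_win[0], best_win[1], second_d, len(cands)


def _finish_alignment(
    conv_codes: np.ndarray,
    index: ThreeLetterIndex,
    params: AlignerParams,
    best_d: int,
    wstart: int,
    wend: int,
    second_d: int,
) -> AlignmentResult:
    n = conv_codes.size
    max_d = params.resolve_max_d(n)
    if best_d >= INF or best_d > max_d:
        return AlignmentResult(status="unmapped", reason="no_alignment")
    if second_d < INF and second_d - best_d < params.uniqueness_gap:
        return AlignmentResult(
            status="multiple",
            edit_distance=best_d,
            second_best_distance=second_d,
            reason="ambiguous",
        )
    d, j_start, j_end, opcodes = _kernels.semiglobal_backtrace(
        conv_codes, index.concat_codes[wstart:wend], max_d
    )
    script = EditScript.from_op_codes(opcodes.tolist())
    aln_len = j_end - j_start
    try:
        locus = index.concat_to_genomic(wstart + j_start, aln_len)
    except BlockBoundaryError:
        return AlignmentResult(status="unmapped", reason="block_boundary")
    return AlignmentResult(
        status="unique",
        locus=locus,
        edit_distance=int(d),
        script=script,
        second_best_distance=None if second_d >= INF else int(second_d),
        aln_len=aln_len,
    )


def align_read(read: BisRead, index: ThreeLetterIndex, params: Optional[AlignerParams] = None) -> AlignmentResult:
    """Align one read; in non-directional mode the reverse complement is
    also tried (equivalent to a G2A query) and the better alignment wins."""
    if params is None:
        params = AlignerParams()
    conv = encode(read.converted_seq, read=True)
    res = _align_and_finish(conv, index, params)
    if params.non_directional:
        rc_conv = encode(bisulfite_convert(revcomp(read.original_seq), "C2T"), read=True)
        rc_res = _align_and_finish(rc_conv, index, params)
        if _better(rc_res, res):
            rc_res.orientation = "rc"
            return rc_res
    return res


def _align_and_finish(conv_codes: np.ndarray, index: ThreeLetterIndex, params: AlignerParams) -> AlignmentResult:
    best_d, wstart, wend, second_d, _ = _align_codes(conv_codes, index, params)
    return _finish_alignment(conv_codes, index, params, best_d, wstart, wend, second_d)


def _better(a: AlignmentResult, b: AlignmentResult) -> bool:
    """True when alignment *a* strictly beats *b* (lower distance, mapped first)."""
    rank = {"unique": 0, "multiple": 1, "unmapped": 2}
    if rank[a.status] != rank[b.status]:
        return rank[a.status] < rank[b.status]
    if a.edit_distance is None or b.edit_distance is None:
        return False
    return a.edit_distance < b.edit_distance
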