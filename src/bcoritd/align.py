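"""Soft-clipping semi-global read aligner.

Maps short reads onto a small reference locus the way a breakpoint-aware
genome aligner does at a single locus: the best-scoring placement under
affine-gap scoring where unaligned *read ends are free* and become CIGAR
soft clips.  Reads crossing a tandem-duplication junction therefore align
their reference-colinear part and clip the rest -- the primary detection
signal -- while reads split too evenly across a junction fall below the
reporting threshold and are emitted unmapped (the discordant-mate class).

Scoring: match +1, mismatch -2; a gap of length k costs -4 - (k-1)*1
(open -4 on the first gap base, extend -1 thereafter); terminal clipping is
free.  Reporting threshold: best score >= 0.6 * read length, else unmapped.
Ties are broken toward the earliest (read, reference) end cell in row-major
order, which for equal-length candidate placements selects the leftmost
reference position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

MATCH = 1
MISMATCH = -2
GAP_OPEN = -4
GAP_EXT = -1
MIN_SCORE_FRAC = 0.6

_NEG = -(10**6)

# CIGAR op codes (SAM order): 0=M 1=I 2=D 4=S
OP_M, OP_I, OP_D, OP_S = 0, 1, 2, 4
_OP_CHAR = {OP_M: "M", OP_I: "I", OP_D: "D", OP_S: "S"}

_COMP = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@njit(cache=False)
def _fill(read, ref, match, mismatch, gopen, gext):  # pragma: no cover - numba
    m, n = read.shape[0], ref.shape[0]
    H = np.zeros((m + 1, n + 1), np.int32)
    E = np.full((m + 1, n + 1), _NEG, np.int32)
    F = np.full((m + 1, n + 1), _NEG, np.int32)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = H[i, j - 1] + gopen
            t = E[i, j - 1] + gext
            if t > e:
                e = t
            f = H[i - 1, j] + gopen
            t = F[i - 1, j] + gext
            if t > f:
                f = t
            diag = H[i - 1, j - 1]
            if diag < 0:
                diag = 0  # fresh start == free clip of read prefix
            s = match if read[i - 1] == ref[j - 1] else mismatch
            h = diag + s
            if e > h:
                h = e
            if f > h:
                h = f
            H[i, j] = h
            E[i, j] = e
            F[i, j] = f
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj


@njit(cache=False)
def _traceback(read, ref, H, E, F, bi, bj, match, mismatch, gopen, gext):  # pragma: no cover
    # returns (codes, lens, count, i_start, j_start) with ops reversed
    maxops = 2 * read.shape[0] + 4
    codes = np.empty(maxops, np.int32)
    lens = np.empty(maxops, np.int32)
    k = -1
    i, j = bi, bj
    state = 0  # 0=H 1=E(del, consumes ref) 2=F(ins, consumes read)
    while True:
        if state == 0:
            s = match if read[i - 1] == ref[j - 1] else mismatch
            diag = H[i - 1, j - 1]
            if diag < 0:
                diag = 0
            if H[i, j] == diag + s:
                if k >= 0 and codes[k] == OP_M:
                    lens[k] += 1
                else:
                    k += 1
                    codes[k] = OP_M
                    lens[k] = 1
                stop = H[i - 1, j - 1] <= 0
                i -= 1
                j -= 1
                if stop:
                    break
            elif H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            if k >= 0 and codes[k] == OP_D:
                lens[k] += 1
            else:
                k += 1
                codes[k] = OP_D
                lens[k] = 1
            if E[i, j] == H[i, j - 1] + gopen:
                state = 0
            j -= 1
        else:
            if k >= 0 and codes[k] == OP_I:
                lens[k] += 1
            else:
                k += 1
                codes[k] = OP_I
                lens[k] = 1
            if F[i, j] == H[i - 1, j] + gopen:
                state = 0
            i -= 1
    return codes, lens, k + 1, i + 1, j + 1


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), np.uint8)


@dataclass
class Placement:
    """One scored placement of a read on the reference."""

    score: int
    pos: int  # 1-based leftmost aligned reference position
    cigar: list[tuple[int, int]]  # (op, length) incl. terminal soft clips
    reverse: bool

    @property
    def cigar_string(self) -> str:
        return "".join(f"{n}{_OP_CHAR[op]}" for op, n in self.cigar)

    @property
    def end_pos(self) -> int:
        """1-based rightmost aligned reference position."""
        return self.pos + sum(n for op, n in self.cigar if op in (OP_M, OP_D)) - 1


def _align_oriented(read: str, ref: str) -> tuple[int, int, list[tuple[int, int]]]:
    """Best placement of ``read`` as given (no strand flip).

    Returns (score, pos, cigar); score 0 means no positive-scoring alignment.
    Exact full-length substring matches short-circuit the dynamic program --
    they attain the maximum possible score so the DP could not do better,
    and ``str.find`` yields the leftmost (tie-breaking) placement.
    """
    hit = ref.find(read)
    if hit >= 0:
        return len(read), hit + 1, [(OP_M, len(read))]
    r = _encode(read)
    f = _encode(ref)
    H, E, F, best, bi, bj = _fill(r, f, MATCH, MISMATCH, GAP_OPEN, GAP_EXT)
    if best <= 0:
        return 0, 0, []
    codes, lens, k, i0, j0 = _traceback(
        r, f, H, E, F, bi, bj, MATCH, MISMATCH, GAP_OPEN, GAP_EXT
    )
    cigar = [(int(codes[t]), int(lens[t])) for t in range(k - 1, -1, -1)]
    if i0 > 1:
        cigar.insert(0, (OP_S, i0 - 1))
    if bi < len(read):
        cigar.append((OP_S, len(read) - bi))
    return int(best), int(j0), cigar


def align_read(
    read: str,
    ref: str,
    *,
    min_score_frac: float = MIN_SCORE_FRAC,
    both_strands: bool = True,
) -> Placement | None:
    """Align one read to the reference; ``None`` if below threshold.

    The returned placement's CIGAR consumes the full read (soft clips
    included).  With ``both_strands`` the reverse complement is also tried
    and the higher score wins (forward preferred on ties).
    """
    # exact full-length hits attain the maximum possible score: no DP needed
    hit = ref.find(read)
    if hit >= 0:
        return Placement(len(read), hit + 1, [(OP_M, len(read))], False)
    if both_strands:
        hit = ref.find(revcomp(read))
        if hit >= 0:
            return Placement(len(read), hit + 1, [(OP_M, len(read))], True)
    score_f, pos_f, cig_f = _align_oriented(read, ref)
    best = Placement(score_f, pos_f, cig_f, False)
    if both_strands:
        score_r, pos_r, cig_r = _align_oriented(revcomp(read), ref)
        if score_r > score_f:
            best = Placement(score_r, pos_r, cig_r, True)
    if best.score < min_score_frac * len(read):
        return None
    return best


# -- SAM records -----------------------------------------------------------

FLAG_PAIRED = 0x1
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80


@dataclass
class AlignmentRecord:
    """A SAM-like alignment record (sequence stored in aligned orientation)."""

    name: str
    seq: str
    mapped: bool = False
    ref_name: str = "*"
    pos: int = 0
    cigar: list[tuple[int, int]] = field(default_factory=list)
    reverse: bool = False
    score: int = 0
    paired: bool = False
    read1: bool = True
    mate_mapped: bool = True
    mate_reverse: bool = False
    mate_pos: int = 0

    def __post_init__(self) -> None:
        if self.mapped:
            consumed = sum(n for op, n in self.cigar if op in (OP_M, OP_I, OP_S))
            if consumed != len(self.seq):
                raise ValueError(
                    f"CIGAR consumes {consumed} query bases for a "
                    f"{len(self.seq)}-base read"
                )

    @property
    def flag(self) -> int:
        f = 0
        if self.paired:
            f |= FLAG_PAIRED | (FLAG_READ1 if self.read1 else FLAG_READ2)
            if not self.mate_mapped:
                f |= FLAG_MATE_UNMAPPED
            if self.mate_reverse:
                f |= FLAG_MATE_REVERSE
        if not self.mapped:
            f |= FLAG_UNMAPPED
        if self.reverse:
            f |= FLAG_REVERSE
        return f

    @property
    def cigar_string(self) -> str:
        if not self.mapped:
            return "*"
        return "".join(f"{n}{_OP_CHAR[op]}" for op, n in self.cigar)

    @property
    def end_pos(self) -> int:
        return self.pos + sum(n for op, n in self.cigar if op in (OP_M, OP_D)) - 1

    def left_clip(self) -> int:
        if self.mapped and self.cigar and self.cigar[0][0] == OP_S:
            return self.cigar[0][1]
        return 0

    def right_clip(self) -> int:
        if self.mapped and self.cigar and self.cigar[-1][0] == OP_S:
            return self.cigar[-1][1]
        return 0

    def to_sam_line(self) -> str:
        rname = self.ref_name if self.mapped else "*"
        pos = self.pos if self.mapped else 0
        mapq = 60 if self.mapped else 0
        if self.paired:
            rnext = "=" if (self.mate_mapped and self.mapped) else (
                self.ref_name if self.mate_mapped else ("=" if self.mapped else "*")
            )
            pnext = self.mate_pos
        else:
            rnext, pnext = "*", 0
        qual = "I" * len(self.seq)
        return "\t".join(
            [
                self.name,
                str(self.flag),
                rname,
                str(pos),
                str(mapq),
                self.cigar_string,
                rnext,
                str(pnext),
                "0",
                self.seq,
                qual,
            ]
        )


def sam_header(ref_name: str, ref_len: int) -> str:
    return f"@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:{ref_name}\tLN:{ref_len}\n"


def _record_for(read_name: str, seq: str, placement: Placement | None,
                ref_name: str) -> AlignmentRecord:
    if placement is None:
        return AlignmentRecord(name=read_name, seq=seq, mapped=False)
    oriented = revcomp(seq) if placement.reverse else seq
    return AlignmentRecord(
        name=read_name,
        seq=oriented,
        mapped=True,
        ref_name=ref_name,
        pos=placement.pos,
        cigar=placement.cigar,
        reverse=placement.reverse,
        score=placement.score,
    )


def align_pairs(
    pairs,
    ref: str,
    ref_name: str = "locus",
    *,
    min_score_frac: float = MIN_SCORE_FRAC,
) -> list[tuple[AlignmentRecord, AlignmentRecord]]:
    """Align mate pairs and cross-fill mate fields.

    ``pairs`` is an iterable of (name, seq1, seq2).  Pairs where one mate
    falls below the reporting threshold yield a mapped/unmapped pair -- the
    discordant class the downstream detector mines.
    """
    out = []
    for name, s1, s2 in pairs:
        p1 = align_read(s1, ref, min_score_frac=min_score_frac)
        p2 = align_read(s2, ref, min_score_frac=min_score_frac)
        r1 = _record_for(name, s1, p1, ref_name)
        r2 = _record_for(name, s2, p2, ref_name)
        for a, b, first in ((r1, r2, True), (r2, r1, False)):
            a.paired = True
            a.read1 = first
            a.mate_mapped = b.mapped
            a.mate_reverse = b.reverse
            a.mate_pos = b.pos if b.mapped else 0
        out.append((r1, r2))
    return out


def write_sam(records, ref_name: str, ref_len: int, path) -> None:
    """Write alignment records (flat iterable) as a SAM text file."""
    with open(path, "w") as fh:
        fh.write(sam_header(ref_name, ref_len))
        for rec in records:
            fh.write(rec.to_sam_line() + "\n")


# -- fast substitution-only placement (used by the EM quantifier) ----------


class KmerIndex:
    """Exact k-mer index over a reference for seeded placement."""

    def __init__(self, ref: str, k: int = 15):
        self.ref = ref.upper()
        self.k = k
        self.index: dict[str, list[int]] = {}
        for i in range(len(self.ref) - k + 1):
            self.index.setdefault(self.ref[i : i + k], []).append(i)

    def candidate_offsets(self, read: str) -> set[int]:
        """Candidate 0-based full-read placements from non-overlapping seeds."""
        k = self.k
        cands: set[int] = set()
        for off in range(0, max(len(read) - k + 1, 1), k):
            for hit in self.index.get(read[off : off + k], ()):
                start = hit - off
                if 0 <= start <= len(self.ref) - len(read):
                    cands.add(start)
        return cands


def best_substitution_placement(read: str, index: KmerIndex):
    """Best full-length ungapped placement (pos0, reverse, mismatches).

    Suits the no-indel error model of the simulator: candidate diagonals
    come from exact seed hits; returns ``None`` when no seed matches at all
    (the read shares no exact k-mer with the reference on either strand).
    """
    best = None
    ref_arr = np.frombuffer(index.ref.encode(), np.uint8)
    for rev, seq in ((False, read.upper()), (True, revcomp(read.upper()))):
        arr = np.frombuffer(seq.encode(), np.uint8)
        for start in sorted(index.candidate_offsets(seq)):
            mm = int(np.count_nonzero(ref_arr[start : start + len(seq)] != arr))
            if best is None or mm < best[2]:
                best = (start, rev, mm)
    return best
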