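"""ITD calling from alignments.

The detection recipe mirrors how recurrent BCOR exon-15 duplications were
found in tumour sequencing data:

1. harvest terminal soft-clipped segments from reads near the locus;
2. locally realign each clipped subsequence back to the reference (the
   seed-and-extend analogue of running the clips through BLAST);
3. keep hits with the tandem-duplication signature -- a right-clip whose
   clip matches *inside and upstream of* its own aligned span (and the
   mirror case for left clips) -- and reconstruct the duplicated interval
   plus any non-templated junctional insertion from the unmatched clip
   prefix between the copies;
4. corroborate with discordant mate pairs: mates that failed to map are
   permissively realigned to the transcript, where an ITD produces a focal
   coverage peak over the duplicated segment.

Calls are 3'-normalized and carry clip/discordant support counts and a
variant allele fraction (junction-supporting reads over reads overlapping
the junction by at least ``min_clip_len`` bases).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .align import (
    AlignmentRecord,
    KmerIndex,
    OP_S,
    align_read,
    best_substitution_placement,
    revcomp,
)
from .annotate import normalize_itd
from .locus import AlleleSpec, CdnaInterval, GenomicInterval, LocusModel, apply_allele

DEFAULT_MIN_CLIP_LEN = 10
DEFAULT_MIN_SUPPORT = 3
DEFAULT_MIN_IDENTITY = 0.9
DEFAULT_SEARCH_RADIUS = 500
DEFAULT_MAX_INSERTION = 20
PERMISSIVE_SCORE_FRAC = 0.4


class AmbiguousCallError(ValueError):
    """Left- and right-clip evidence reconstruct different ITDs."""

    def __init__(self, candidates):
        self.candidates = candidates
        super().__init__(f"irreconcilable junction evidence: {candidates}")


@dataclass(frozen=True)
class ClippedSegment:
    """A terminal soft-clipped subsequence with its anchor."""

    read_name: str
    side: str  # "left" | "right"
    anchor: int  # 1-based ref position of the first/last aligned base
    seq: str


@dataclass(frozen=True)
class ClipHit:
    """Local realignment hit of a clipped segment on the reference."""

    ref_start: int  # 1-based
    ref_end: int
    matched: int
    identity: float
    unmatched: str  # clip prefix (right clips) / suffix (left clips)


@dataclass
class ITDCall:
    """A reconstructed internal tandem duplication."""

    dup_transcript: tuple[int, int]  # 1-based transcript interval
    dup_cdna: CdnaInterval
    dup_genomic: GenomicInterval
    insertion_seq: str
    clip_support: int
    discordant_support: int
    vaf: float
    in_frame: bool

    @property
    def allele(self) -> AlleleSpec:
        return AlleleSpec(dup=self.dup_cdna, insertion_seq=self.insertion_seq)

    @property
    def dup_length(self) -> int:
        return len(self.dup_cdna)


@dataclass
class CoverageProfile:
    """Realigned discordant-mate read depth across the transcript."""

    depth: np.ndarray  # per 1-based position (index 0 = position 1)
    threshold: float
    peak: tuple[int, int] | None  # 1-based inclusive, None when no peak

    def plot(self, ax=None):
        """Depth profile with the detected peak shaded (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 2.5))
        x = np.arange(1, len(self.depth) + 1)
        ax.fill_between(x, self.depth, step="mid", alpha=0.7)
        ax.axhline(self.threshold, ls="--", lw=0.8, color="grey")
        if self.peak:
            ax.axvspan(self.peak[0], self.peak[1], color="red", alpha=0.2)
        ax.set_xlabel("transcript position")
        ax.set_ylabel("discordant-mate depth")
        return ax


# -- step 1: soft-clip harvest ---------------------------------------------


def harvest_softclips(
    records,
    region: tuple[int, int] | None = None,
    min_clip_len: int = DEFAULT_MIN_CLIP_LEN,
) -> list[ClippedSegment]:
    """Collect terminal soft clips >= ``min_clip_len`` within ``region``.

    ``records`` is any iterable of mapped/unmapped :class:`AlignmentRecord`;
    record sequences are in aligned orientation, so clip sequences read in
    reference direction.
    """
    out = []
    for rec in records:
        if not rec.mapped:
            continue
        lc = rec.left_clip()
        if lc >= min_clip_len and _in_region(rec.pos, region):
            out.append(ClippedSegment(rec.name, "left", rec.pos, rec.seq[:lc]))
        rc = rec.right_clip()
        if rc >= min_clip_len and _in_region(rec.end_pos, region):
            out.append(
                ClippedSegment(rec.name, "right", rec.end_pos, rec.seq[len(rec.seq) - rc :])
            )
    return out


def _in_region(pos: int, region: tuple[int, int] | None) -> bool:
    return region is None or region[0] <= pos <= region[1]


# -- step 2: local realignment of clips ------------------------------------


def match_clip(
    clip: str,
    ref: str,
    anchor: int,
    *,
    side: str = "right",
    radius: int = DEFAULT_SEARCH_RADIUS,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_unmatched: int = DEFAULT_MAX_INSERTION,
    seed_len: int = 8,
    min_matched: int = 8,
) -> ClipHit | None:
    """Seed-and-extend local search for a clipped segment near its anchor.

    Exact ``seed_len``-mers of the clip are looked up in the window
    ``anchor +/- radius``; each seeded diagonal is evaluated ungapped.  A
    junctional insertion appears as an unmatched clip *prefix* (right
    clips) or *suffix* (left clips) of up to ``max_unmatched`` bases; the
    best hit maximizes the matched span subject to identity >=
    ``min_identity``.  Returns ``None`` when nothing clears the thresholds.
    """
    lo = max(0, anchor - 1 - radius)
    hi = min(len(ref), anchor + radius)
    window = ref[lo:hi]
    if len(clip) < min_matched or len(window) < seed_len:
        return None
    # seed positions of clip k-mers within the window
    diagonals: set[int] = set()
    for off in range(0, len(clip) - seed_len + 1):
        kmer = clip[off : off + seed_len]
        start = window.find(kmer)
        while start != -1:
            diagonals.add(start - off)  # window offset of clip[0]
            start = window.find(kmer, start + 1)
    clip_arr = np.frombuffer(clip.encode(), np.uint8)
    win_arr = np.frombuffer(window.encode(), np.uint8)
    best: tuple[int, int, ClipHit] | None = None  # (matched, -ref_start, hit)
    for d in sorted(diagonals):
        # overlap of the full clip with the window on this diagonal
        q0 = max(0, -d)
        q1 = min(len(clip), len(window) - d)
        if q1 - q0 < min_matched:
            continue
        eq = clip_arr[q0:q1] == win_arr[d + q0 : d + q1]
        # trim non-templated junction-side bases: the matched segment must
        # begin (right clips) / end (left clips) with a clean match run, so
        # an insertion is not silently absorbed as junction mismatches
        run = min(5, q1 - q0 - 1)
        for t in range(0, min(max_unmatched, q1 - q0 - min_matched) + 1):
            if side == "right":
                seg = eq[t:]
                qs, qe = q0 + t, q1
                edge_ok = bool(seg[:run].all())
            else:
                seg = eq[: len(eq) - t] if t else eq
                qs, qe = q0, q1 - t
                edge_ok = bool(seg[-run:].all())
            n = qe - qs
            ident = float(np.count_nonzero(seg)) / n
            if edge_ok and ident >= min_identity:
                if side == "right":
                    unmatched = clip[:qs]
                else:
                    unmatched = clip[qe:]
                hit = ClipHit(
                    ref_start=lo + d + qs + 1,
                    ref_end=lo + d + qe,
                    matched=n,
                    identity=ident,
                    unmatched=unmatched,
                )
                key = (n, -(hit.ref_start))
                if best is None or key > best[:2]:
                    best = (*key, hit)
                break  # smallest trim wins for this diagonal
    return best[2] if best else None


# -- step 3: reconstruction ------------------------------------------------


def _candidate_from_clip(seg: ClippedSegment, hit: ClipHit):
    """(start, end, insertion) candidate in transcript coordinates, or None
    when the hit lacks the tandem-duplication signature."""
    if seg.side == "right":
        # clip must re-match inside the aligned span, upstream of the anchor
        if hit.ref_start > seg.anchor:
            return None
        return (hit.ref_start, seg.anchor, hit.unmatched)
    if hit.ref_end < seg.anchor:
        return None
    return (seg.anchor, hit.ref_end, hit.unmatched)


def reconstruct_itd(
    records,
    model: LocusModel,
    *,
    min_clip_len: int = DEFAULT_MIN_CLIP_LEN,
    min_support: int = DEFAULT_MIN_SUPPORT,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    radius: int = DEFAULT_SEARCH_RADIUS,
    region: tuple[int, int] | None = None,
) -> ITDCall | None:
    """Reconstruct an ITD call from clip evidence, or ``None``.

    Clip candidates from both junction sides are 3'-normalized and voted;
    the modal candidate wins if supported by >= ``min_support`` distinct
    reads.  If the two junction sides each reach ``min_support`` with
    irreconcilable geometries, :class:`AmbiguousCallError` is raised.
    """
    records = list(records)
    ref = model.transcript_seq
    clips = harvest_softclips(records, region=region, min_clip_len=min_clip_len)
    votes: dict[tuple[int, int, str], set[str]] = {}
    side_votes = {"left": Counter(), "right": Counter()}
    for seg in clips:
        hit = match_clip(
            seg.seq, ref, seg.anchor, side=seg.side,
            radius=radius, min_identity=min_identity,
        )
        if hit is None:
            continue
        cand = _candidate_from_clip(seg, hit)
        if cand is None:
            continue
        s, e, ins = normalize_itd(ref, cand[0], cand[1], cand[2])
        votes.setdefault((s, e, ins), set()).add(seg.read_name)
        side_votes[seg.side][(s, e, ins)] += 1
    if not votes:
        return None
    ranked = sorted(votes.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    top, supporters = ranked[0]
    if len(supporters) < min_support:
        return None
    # reconcile junction sides: when both are saturated but disagree
    # (e.g. the aligner absorbed insertion bases into one anchor), keep
    # the candidate whose exact junction string more reads contain; a tie
    # is genuinely ambiguous
    tops = []
    for side in ("left", "right"):
        if side_votes[side]:
            cand, cnt = side_votes[side].most_common(1)[0]
            if cnt >= min_support:
                tops.append(cand)
    if len(tops) == 2 and tops[0] != tops[1]:
        counts = [
            _exact_junction_reads(records, model, cand) for cand in tops
        ]
        if counts[0] == counts[1]:
            raise AmbiguousCallError(tops)
        top = tops[int(counts[1] > counts[0])]
        supporters = votes[top]
        if len(supporters) < min_support:
            return None

    s, e, ins = top
    dup_c = CdnaInterval(model.transcript_to_cdna(s), model.transcript_to_cdna(e))
    dup_g = model.cdna_interval_to_genomic(dup_c)
    support, discordant, vaf = _junction_support(
        records, model, s, e, ins, min_clip_len=min_clip_len
    )
    call = ITDCall(
        dup_transcript=(s, e),
        dup_cdna=dup_c,
        dup_genomic=dup_g,
        insertion_seq=ins,
        clip_support=len(supporters),
        discordant_support=discordant,
        vaf=vaf,
        in_frame=(e - s + 1 + len(ins)) % 3 == 0,
    )
    return call


def _exact_junction_reads(
    records, model: LocusModel, cand: tuple[int, int, str], flank: int = 15
) -> int:
    """Reads containing the candidate's exact junction string verbatim."""
    s, e, ins = cand
    allele = AlleleSpec(
        dup=CdnaInterval(model.transcript_to_cdna(s), model.transcript_to_cdna(e)),
        insertion_seq=ins,
    )
    mutant = apply_allele(model, allele)
    junction = mutant[max(0, e - flank) : e + len(ins) + flank]
    count = 0
    for rec in records:
        if junction in rec.seq or junction in revcomp(rec.seq):
            count += 1
    return count


def _junction_support(
    records, model: LocusModel, s: int, e: int, ins: str,
    *, min_clip_len: int, max_mismatch_frac: float = 0.1,
) -> tuple[int, int, float]:
    """Count junction-supporting reads and the VAF denominator.

    A read supports the junction when it places on the reconstructed mutant
    transcript across the novel adjacency with >= ``min_clip_len`` bases on
    each side; reads fully aligned across either junction flank on the
    wild-type reference join the denominator.
    """
    mcl = min_clip_len
    li = len(ins)
    d = e - s + 1
    allele = AlleleSpec(
        dup=CdnaInterval(model.transcript_to_cdna(s), model.transcript_to_cdna(e)),
        insertion_seq=ins,
    )
    mutant = apply_allele(model, allele)
    idx = KmerIndex(mutant, k=15)

    def spans(lo: int, hi: int, x: int) -> bool:
        # does [lo, hi] cover the adjacency between x and x+1 by >= mcl
        # bases on each side?
        return lo <= x - mcl + 1 and hi >= x + mcl

    supporters: set[tuple[str, bool]] = set()
    discordant: set[tuple[str, bool]] = set()
    junction_occ = 0  # novel-adjacency spans
    reference_occ = 0  # reference-adjacency spans (wild-type-compatible)
    for rec in records:
        key = (rec.name, rec.read1)
        if rec.mapped and rec.left_clip() < mcl and rec.right_clip() < mcl:
            # fully aligned reads are reference-colinear: count spans of the
            # two reference junction adjacencies (s-1|s and e|e+1)
            for x in (s - 1, e):
                if spans(rec.pos, rec.end_pos, x):
                    reference_occ += 1
            continue
        pl = best_substitution_placement(rec.seq, idx)
        if pl is None:
            continue
        pos0, _, mm = pl
        if mm > max_mismatch_frac * len(rec.seq):
            continue
        lo1, hi1 = pos0 + 1, pos0 + len(rec.seq)  # 1-based mutant span
        if spans(lo1, hi1, e):  # insertion bases are junction-diagnostic
            junction_occ += 1
            supporters.add(key)
            if not rec.mapped:
                discordant.add(key)
        # colinear adjacencies in mutant coordinates: s-adjacency of the
        # first copy and e-adjacency of the second copy
        for x in (s - 1, e + li + d):
            if spans(lo1, hi1, x):
                reference_occ += 1
    # allele-counting VAF: each haplotype copy exposes one novel adjacency
    # (mutant) but two reference adjacencies (both haplotypes), hence the
    # factor of two
    if reference_occ:
        vaf = min(1.0, 2.0 * junction_occ / reference_occ)
    else:
        vaf = 1.0 if junction_occ else 0.0
    return len(supporters), len(discordant), vaf


# -- step 4: discordant mate-pair coverage peak ----------------------------


def discordant_peak(
    records,
    model: LocusModel,
    *,
    permissive_frac: float = PERMISSIVE_SCORE_FRAC,
    mad_factor: float = 3.0,
    min_peak_depth: float = 3.0,
) -> CoverageProfile:
    """Realign unmapped mates of mapped reads; locate the coverage peak.

    The peak threshold is background median + ``mad_factor`` * MAD of the
    realigned depth profile, floored at ``min_peak_depth`` so that isolated
    stray reads in ITD-free samples do not surface as peaks.
    """
    ref = model.transcript_seq
    depth = np.zeros(len(ref), float)
    for rec in records:
        if rec.mapped or not (rec.paired and rec.mate_mapped):
            continue
        pl = align_read(rec.seq, ref, min_score_frac=permissive_frac)
        if pl is None:
            continue
        depth[pl.pos - 1 : pl.end_pos] += 1
    med = float(np.median(depth))
    mad = float(np.median(np.abs(depth - med)))
    threshold = max(med + mad_factor * mad, min_peak_depth)
    above = np.nonzero(depth > threshold)[0]
    peak = (int(above[0]) + 1, int(above[-1]) + 1) if above.size else None
    return CoverageProfile(depth=depth, threshold=threshold, peak=peak)


# -- call output -----------------------------------------------------------


def calls_to_frame(calls, model: LocusModel, sample: str = "sample"):
    """Tabulate calls (one row each) with their HGVS-style annotations."""
    import pandas as pd

    from .annotate import annotate

    rows = []
    for call in calls:
        ann = annotate(call.allele, model, normalize=False)
        rows.append(
            {
                "sample": sample,
                "gdna": ann.gdna_hgvs,
                "gdna_interval": ann.gdna,
                "cdna": ann.cdna,
                "cdna_start": call.dup_cdna.start_c,
                "cdna_end": call.dup_cdna.end_c,
                "insertion": call.insertion_seq,
                "itd_length": call.dup_length,
                "clip_support": call.clip_support,
                "discordant_support": call.discordant_support,
                "vaf": round(call.vaf, 4),
                "in_frame": call.in_frame,
                "protein": ann.protein or "frameshift",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample", "gdna", "gdna_interval", "cdna", "cdna_start",
            "cdna_end", "insertion", "itd_length", "clip_support",
            "discordant_support", "vaf", "in_frame", "protein",
        ],
    )


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def calls_to_vcf(calls, model: LocusModel, path: str | Path,
                 sample: str = "sample") -> None:
    """Write calls as a minimal VCF with SVTYPE=DUP:TANDEM records."""
    contig_len = max(e.end for e in model.exons) + 1000
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={model.contig},length={contig_len}>",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="Duplication end">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Duplicated length">',
        '##INFO=<ID=INSSEQ,Number=1,Type=String,Description="Junctional insertion">',
        '##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele fraction">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for i, call in enumerate(calls):
        g = call.dup_genomic
        # plus-strand base at POS: complement of the coding-strand base
        t = model.genomic_to_transcript(g.start)
        ref_base = model.transcript_seq[t - 1].translate(_COMPLEMENT)
        info = f"SVTYPE=DUP:TANDEM;END={g.end};SVLEN={len(g)};VAF={call.vaf:.4f}"
        if call.insertion_seq:
            info += f";INSSEQ={call.insertion_seq}"
        lines.append(
            f"{g.contig}\t{g.start}\t{sample}_itd{i + 1}\t{ref_base}\t"
            f"<DUP:TANDEM>\t.\tPASS\t{info}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# -- SAM input -------------------------------------------------------------

_CIG_CODE = {"M": 0, "I": 1, "D": 2, "S": 4, "=": 0, "X": 0}


def records_from_sam(path: str | Path) -> list[AlignmentRecord]:
    """Load a SAM file (via pysam) into detector-ready records."""
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for read in sam.fetch(until_eof=True):
            cigar = []
            if read.cigartuples:
                for op, n in read.cigartuples:
                    if op == 5:  # hard clip: no query bases
                        continue
                    cigar.append(({0: 0, 1: 1, 2: 2, 4: 4, 7: 0, 8: 0}[op], n))
            out.append(
                AlignmentRecord(
                    name=read.query_name,
                    seq=read.query_sequence or "",
                    mapped=not read.is_unmapped,
                    ref_name=read.reference_name or "*",
                    pos=(read.reference_start + 1) if not read.is_unmapped else 0,
                    cigar=cigar,
                    reverse=read.is_reverse,
                    paired=read.is_paired,
                    read1=not read.is_read2,
                    mate_mapped=not read.mate_is_unmapped if read.is_paired else True,
                    mate_reverse=read.mate_is_reverse if read.is_paired else False,
                    mate_pos=(read.next_reference_start + 1)
                    if (read.is_paired and not read.mate_is_unmapped)
                    else 0,
                )
            )
    return out
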