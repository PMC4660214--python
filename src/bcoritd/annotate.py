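"""HGVS-style annotation of internal tandem duplications.

Converts a reconstructed ITD allele into linked genomic, cDNA and protein
descriptions, reproducing the three annotation patterns recurrent BCOR
exon-15 duplications take:

* clean duplication                ``p.L1724_W1755dup``
* duplication + junctional insert  ``p.V1741_E1742insV+p.L1713_V1741dup``
* duplication + junctional missense ``p.G1738E+p.V1701_L1737dup``

Duplications are reported at their transcript-3'-most equivalent position
(the HGVS normalization rule), which makes junctions with microhomology
unique.  Protein consequences are obtained by translating the mutant CDS
(through into the modeled 3'-UTR when the duplication disrupts the stop
codon), trimming the common prefix and suffix against the reference
protein, and decomposing the inserted peptide into the longest duplicated
segment plus a residual reported as insertion (when the allele carries a
non-templated junctional insertion) or as a boundary missense.
"""

from __future__ import annotations

from dataclasses import dataclass

from .locus import (
    AlleleSpec,
    CdnaInterval,
    GenomicInterval,
    LocusModel,
    LocusError,
    apply_allele,
    mutant_cds_translation,
)


class FrameshiftError(LocusError):
    """Protein-level annotation refused: the allele shifts the frame."""


def check_frame(dup_len: int, insertion_len: int = 0) -> bool:
    """True iff the total inserted length keeps the reading frame."""
    return (dup_len + insertion_len) % 3 == 0


# -- 3' normalization ------------------------------------------------------


def _common_prefix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def normalize_itd(
    seq: str, start_t: int, end_t: int, insertion: str = ""
) -> tuple[int, int, str]:
    """Canonicalize an ITD to its unique 3'-most representation.

    ``(start_t, end_t)`` is the duplicated interval in 1-based transcript
    positions; ``insertion`` sits between the tandem copies.  Among all
    (duplication, insertion) decompositions producing an identical mutant
    sequence the canonical one has the *shortest* insertion (templated
    bases belong to the duplication, the HGVS preference for dup over ins)
    and, at that length, the transcript-3'-most interval.  Idempotent.

    The search is closed-form: with ``P``/``S`` the longest common
    prefix/suffix of the mutant and reference sequences, a decomposition
    with insertion length ``li`` exists iff ``li >= n - (P + S - len(seq))``
    where ``n`` is the total inserted length, and the 3'-most interval at
    the minimal ``li`` always ends at position ``P``.
    """
    d = end_t - start_t + 1
    n = d + len(insertion)
    mutant = seq[:end_t] + insertion + seq[start_t - 1 :]
    p = _common_prefix_len(mutant, seq)
    s = _common_prefix_len(mutant[::-1], seq[::-1])
    slack = p + s - len(seq)
    li = max(0, n - slack)
    d2 = n - li
    if d2 < 1 or p - d2 + 1 < 1:
        return (start_t, end_t, insertion)  # not expressible as a tandem dup
    e2 = p
    s2 = e2 - d2 + 1
    return (s2, e2, mutant[e2 : e2 + li])


def normalize_3prime(dup: CdnaInterval, model: LocusModel,
                     insertion: str = "") -> tuple[CdnaInterval, str]:
    """3'-normalize a duplication given in cDNA coordinates."""
    s_t = model.cdna_to_transcript(dup.start_c)
    e_t = model.cdna_to_transcript(dup.end_c)
    s2, e2, ins2 = normalize_itd(model.transcript_seq, s_t, e_t, insertion)
    return (
        CdnaInterval(model.transcript_to_cdna(s2), model.transcript_to_cdna(e2)),
        ins2,
    )


# -- annotation ------------------------------------------------------------


@dataclass(frozen=True)
class HGVSAnnotation:
    """Linked genomic/cDNA/protein descriptions of one ITD allele."""

    gdna: str  # table typography, e.g. "chrX:39,911,364–39,911,459"
    gdna_hgvs: str  # machine form, e.g. "chrX:g.39911364_39911459dup"
    cdna: str  # e.g. "c.5171_5266dup"
    cdna_ins: str | None  # e.g. "c.5224_5225insTGT"
    protein: str | None  # None for frameshift alleles
    in_frame: bool
    genomic_interval: GenomicInterval
    cdna_interval: CdnaInterval
    insertion_seq: str


def annotate_cdna(allele: AlleleSpec, model: LocusModel) -> tuple[str, str | None]:
    """cDNA description(s): the duplication and any junctional insertion."""
    if allele.dup is None:
        raise LocusError("cannot annotate the wild-type allele")
    dup = allele.dup
    main = f"c.{dup.start_c}_{dup.end_c}dup"
    ins = None
    if allele.insertion_seq:
        after = allele.ins_after
        ins = f"c.{after}_{after + 1}ins{allele.insertion_seq}"
    return main, ins


def annotate_protein(allele: AlleleSpec, model: LocusModel) -> str:
    """Protein consequence of an in-frame ITD allele.

    Translates the mutant CDS to the next in-frame stop (through the
    3'-UTR for stop-disrupting duplications), isolates the inserted
    peptide, and emits one of the three duplication patterns.  Raises
    :class:`FrameshiftError` for frame-shifting alleles.
    """
    if allele.dup is None:
        raise LocusError("cannot annotate the wild-type allele")
    if not allele.in_frame:
        raise FrameshiftError(
            f"{len(allele.dup)}+{len(allele.insertion_seq)} inserted bases "
            "shift the reading frame"
        )
    ref_p = model.protein_seq
    mut_p = mutant_cds_translation(model, allele).rstrip("*")

    # common prefix, then maximal common suffix of the remainders
    pmax = min(len(ref_p), len(mut_p))
    prefix = 0
    while prefix < pmax and ref_p[prefix] == mut_p[prefix]:
        prefix += 1
    smax = min(len(ref_p), len(mut_p)) - prefix
    suffix = 0
    while suffix < smax and ref_p[-1 - suffix] == mut_p[-1 - suffix]:
        suffix += 1
    deleted = ref_p[prefix : len(ref_p) - suffix]
    insert = mut_p[prefix : len(mut_p) - suffix]
    if deleted:
        # not a pure insertion at protein level; out of the ITD patterns
        raise LocusError(
            f"allele substitutes reference residues ({deleted!r}); "
            "not a tandem-duplication protein pattern"
        )

    # longest suffix of the insert that duplicates the reference segment
    # ending at the trim point
    dup_len = 0
    while (
        dup_len < len(insert)
        and dup_len < prefix
        and insert[len(insert) - 1 - dup_len] == ref_p[prefix - 1 - dup_len]
    ):
        dup_len += 1
    residual = insert[: len(insert) - dup_len]

    def res(i: int) -> str:
        return f"{model.residue(i)}{i}"

    parts: list[str] = []
    if residual:
        if allele.insertion_seq or len(residual) > 1:
            parts.append(f"p.{res(prefix)}_{res(prefix + 1)}ins{residual}")
        else:
            parts.append(f"p.{model.residue(prefix + 1)}{prefix + 1}{residual}")
    if dup_len:
        ds = prefix - dup_len + 1
        parts.append(f"p.{res(ds)}_{res(prefix)}dup")
    if not parts:
        raise LocusError("empty protein consequence")
    return "+".join(parts)


def annotate(allele: AlleleSpec, model: LocusModel,
             normalize: bool = True) -> HGVSAnnotation:
    """Full genomic/cDNA/protein annotation of an ITD allele."""
    if allele.dup is None:
        raise LocusError("cannot annotate the wild-type allele")
    dup, ins = allele.dup, allele.insertion_seq
    if normalize:
        dup, ins = normalize_3prime(dup, model, ins)
    norm = AlleleSpec(dup=dup, insertion_seq=ins)
    g = model.cdna_interval_to_genomic(dup)
    cdna, cdna_ins = annotate_cdna(norm, model)
    in_frame = norm.in_frame
    protein: str | None
    if in_frame:
        protein = annotate_protein(norm, model)
    else:
        protein = None
    return HGVSAnnotation(
        gdna=str(g),
        gdna_hgvs=f"{g.contig}:g.{g.start}_{g.end}dup",
        cdna=cdna,
        cdna_ins=cdna_ins,
        protein=protein,
        in_frame=in_frame,
        genomic_interval=g,
        cdna_interval=dup,
        insertion_seq=ins,
    )
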