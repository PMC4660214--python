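"""Synthetic BCOR-like fixture locus.

The real BCOR terminal-exon sequence is not redistributed here.  Instead this
module builds, deterministically, a *synthetic* minus-strand locus with the
same published geometry as BCOR (NM_001123385-like): a 1,755-residue protein,
a 5,268-base CDS ending in TGA, hg19-style chrX coordinates with the
c.5171 <-> chrX:39,911,459 exonic anchor, and codons fixed at every position
that the recurrent clear-cell-sarcoma ITD alleles name (V1701, D1712, L1713,
E1722, L1724, L1737, G1738, V1741, E1742, D1752, W1755).

Those codon choices are not arbitrary: they are the solution of the junction
constraints the five recurrent ITD types impose, so on this synthetic
sequence every published allele reproduces its full genomic/cDNA/protein
annotation, including the type-I stop-loss junction (the duplication
breakpoint at the second base of the TGA stop recreates a TTA leucine) and
the type-IV/V junctional insertion and missense patterns.  All other codons
are random draws from the sense codons.
"""

from __future__ import annotations

import numpy as np

from .locus import AlleleSpec, CdnaInterval, GenomicInterval, LocusModel

PROTEIN_LEN = 1755
ANCHOR_C = 5171
ANCHOR_G = 39_911_459
UTR3_LEN = 400
_EXON_SPLIT_T = 4800  # transcript position where the terminal exon begins
_FIXTURE_SEED = 2015_1117

# codons pinned by the published allele junctions (residue -> codon)
_PINNED = {
    1700: "CAA",  # ...AA so the type-V junction codon G+AA reads E (G1738E)
    1701: "GTG",  # V
    1712: "GAT",  # D; b3=T blocks 3' shift of the type-III duplication
    1713: "CTG",  # L; T+TG at the type-IV junction re-reads L
    1722: "GAA",  # E
    1724: "TTA",  # L; stop-loss junction T+TA -> TTA (type I)
    1737: "CTG",  # L
    1738: "GGC",  # G
    1741: "GTT",  # V
    1742: "GAA",  # E; GA. so type-III/IV junctions restore D/E
    1752: "GAC",  # D
    1753: "CAT",  # H; b1 != G blocks 3' shift of the type-II duplication
    1755: "TGG",  # W
}

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def bcor_like_locus() -> LocusModel:
    """Build the synthetic BCOR-like two-exon minus-strand locus.

    Deterministic: the unpinned codons and the 3'-UTR are drawn from a fixed
    internal seed, so every call returns an identical model.
    """
    rng = np.random.default_rng(_FIXTURE_SEED)
    codons = [_SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), PROTEIN_LEN)]
    for residue, codon in _PINNED.items():
        codons[residue - 1] = codon
    cds = "".join(codons) + "TGA"
    utr3 = "".join("ACGT"[i] for i in rng.integers(0, 4, UTR3_LEN))
    transcript = cds + utr3

    # minus strand: transcript position t <-> genomic ANCHOR_G + (ANCHOR_C - t)
    def g(t: int) -> int:
        return ANCHOR_G + (ANCHOR_C - t)

    n = len(transcript)
    terminal_exon = GenomicInterval("chrX", g(n), g(_EXON_SPLIT_T))
    gap = 1001
    first_lo = g(_EXON_SPLIT_T) + gap
    first_exon = GenomicInterval("chrX", first_lo, first_lo + (_EXON_SPLIT_T - 2))
    return LocusModel(
        contig="chrX",
        strand="-",
        exons=[first_exon, terminal_exon],
        transcript_seq=transcript,
        cds_start=1,
        cds_end=len(cds),
        name="BCOR-like-synthetic",
    )


# The eleven published tumour alleles: sample -> (genomic interval,
# cDNA dup interval, junctional insertion, expected annotations).
TABLE1_ROWS = [
    # sample, itd_len, type, g_start, g_end, c_start, c_end, ins, cdna_str, protein_str
    ("347T", 96, "I", 39_911_364, 39_911_459, 5171, 5266, "", "c.5171_5266dup", "p.L1724_W1755dup"),
    ("383T", 96, "I", 39_911_364, 39_911_459, 5171, 5266, "", "c.5171_5266dup", "p.L1724_W1755dup"),
    ("385T", 87, "IV", 39_911_406, 39_911_492, 5138, 5224, "TGT", "c.5138_5224dup", "p.V1741_E1742insV+p.L1713_V1741dup"),
    ("380T", 93, "II", 39_911_374, 39_911_466, 5164, 5256, "", "c.5164_5256dup", "p.E1722_D1752dup"),
    ("382T", 90, "III", 39_911_405, 39_911_494, 5136, 5225, "", "c.5136_5225dup", "p.D1712_V1741dup"),
    ("384T", 96, "I", 39_911_364, 39_911_459, 5171, 5266, "", "c.5171_5266dup", "p.L1724_W1755dup"),
    ("474T", 93, "II", 39_911_374, 39_911_466, 5164, 5256, "", "c.5164_5256dup", "p.E1722_D1752dup"),
    ("499T", 96, "I", 39_911_364, 39_911_459, 5171, 5266, "", "c.5171_5266dup", "p.L1724_W1755dup"),
    ("501T", 93, "II", 39_911_374, 39_911_466, 5164, 5256, "", "c.5164_5256dup", "p.E1722_D1752dup"),
    ("504T", 114, "V", 39_911_418, 39_911_531, 5099, 5212, "", "c.5099_5212dup", "p.G1738E+p.V1701_L1737dup"),
    ("624T", 96, "I", 39_911_364, 39_911_459, 5171, 5266, "", "c.5171_5266dup", "p.L1724_W1755dup"),
]


def table1_allele(sample: str) -> AlleleSpec:
    """AlleleSpec for one of the published tumour samples."""
    for row in TABLE1_ROWS:
        if row[0] == sample:
            return AlleleSpec(
                dup=CdnaInterval(row[5], row[6]),
                insertion_seq=row[7],
            )
    raise KeyError(sample)
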