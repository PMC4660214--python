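"""Transcript locus model and coordinate arithmetic.

Represents a single gene locus -- in practice a BCOR-exon-15-like region on
the minus strand of chrX -- and performs the coordinate transforms the ITD
pipeline needs: genomic <-> cDNA (coding) <-> protein residue.

Conventions
-----------
* All genomic and cDNA coordinates are 1-based inclusive, matching HGVS and
  the way tandem duplications are reported in the clinical literature.
  Half-open coordinates appear only at explicit serialization boundaries.
* ``transcript_seq`` is the coding-strand (mRNA sense) sequence.  On the
  minus strand genomic coordinates therefore *decrease* along the transcript.
* c.1 is the first base of the start codon; the stop codon occupies the last
  three coding positions, so ``cds length == 3 * (len(protein) + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import yaml
from Bio.Seq import Seq


class LocusError(ValueError):
    """Base class for locus/coordinate errors."""


class OutOfLocusError(LocusError):
    """Genomic position is intronic or outside the modeled exons."""


class NoResidueError(LocusError):
    """cDNA position lies in a UTR and has no protein residue."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """1-based inclusive genomic interval."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise LocusError(f"empty genomic interval {self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __str__(self) -> str:
        # Table-style "chrX:39,911,364-39,911,459" typography
        return f"{self.contig}:{self.start:,}–{self.end:,}"


@dataclass(frozen=True, order=True)
class CdnaInterval:
    """1-based inclusive interval in coding (c.) coordinates."""

    start_c: int
    end_c: int

    def __post_init__(self) -> None:
        if self.start_c > self.end_c:
            raise LocusError(f"empty cDNA interval {self.start_c}-{self.end_c}")

    def __len__(self) -> int:
        return self.end_c - self.start_c + 1


@dataclass(frozen=True)
class AlleleSpec:
    """A tandem-duplication allele in cDNA coordinates.

    ``dup`` is the duplicated interval; ``insertion_seq`` is an optional
    non-templated junctional insertion placed *between* the two tandem
    copies, immediately after coding position ``insertion_after_c`` (which
    defaults to the duplication end, the only junction in a tandem dup).
    An empty spec (``dup is None``) is the wild-type identity allele.
    """

    dup: CdnaInterval | None = None
    insertion_seq: str = ""
    insertion_after_c: int | None = None

    def __post_init__(self) -> None:
        if not self.insertion_seq and self.insertion_after_c is not None:
            raise LocusError("insertion_after_c set without insertion_seq")
        if self.insertion_seq and self.dup is None:
            raise LocusError("junctional insertion requires a duplication")

    @property
    def ins_after(self) -> int | None:
        if not self.insertion_seq:
            return None
        if self.insertion_after_c is not None:
            return self.insertion_after_c
        return self.dup.end_c  # type: ignore[union-attr]

    @property
    def inserted_length(self) -> int:
        n = 0 if self.dup is None else len(self.dup)
        return n + len(self.insertion_seq)

    @property
    def in_frame(self) -> bool:
        return self.inserted_length % 3 == 0


STOP_CODONS = {"TAA", "TAG", "TGA"}


def translate(nt: str) -> str:
    """Translate a nucleotide string (standard code, '*' for stops)."""
    n = len(nt) - len(nt) % 3
    return str(Seq(nt[:n]).translate())


@dataclass
class LocusModel:
    """A single-transcript gene model with coordinate transforms.

    Parameters
    ----------
    contig : reference sequence name, e.g. ``"chrX"``.
    strand : ``"+"`` or ``"-"``.
    exons : exon intervals in *transcript* order (for minus-strand loci the
        genomic coordinates decrease from one exon to the next).
    transcript_seq : spliced coding-strand sequence.
    cds_start, cds_end : 1-based transcript positions of the first base of
        the start codon and the last base of the stop codon.
    name : free-form label.
    """

    contig: str
    strand: str
    exons: list[GenomicInterval]
    transcript_seq: str
    cds_start: int
    cds_end: int
    name: str = "locus"
    protein_seq: str = field(default="", repr=False)

    def __post_init__(self) -> None:
        self.transcript_seq = self.transcript_seq.upper()
        if self.strand not in "+-":
            raise LocusError(f"bad strand {self.strand!r}")
        exon_len = sum(len(e) for e in self.exons)
        if exon_len != len(self.transcript_seq):
            raise LocusError(
                f"exon lengths sum to {exon_len} but transcript has "
                f"{len(self.transcript_seq)} bases"
            )
        ordered = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(ordered, ordered[1:]):
            if a.end >= b.start:
                raise LocusError(f"overlapping exons {a} and {b}")
        if self.strand == "-":
            starts = [e.start for e in self.exons]
            if starts != sorted(starts, reverse=True):
                raise LocusError("minus-strand exons must descend in transcript order")
        else:
            starts = [e.start for e in self.exons]
            if starts != sorted(starts):
                raise LocusError("plus-strand exons must ascend in transcript order")
        if not (1 <= self.cds_start < self.cds_end <= len(self.transcript_seq)):
            raise LocusError("CDS outside transcript")
        if self.cds_len % 3:
            raise LocusError(f"CDS length {self.cds_len} not divisible by 3")
        cds = self.cds_seq
        if cds[-3:] not in STOP_CODONS:
            raise LocusError(f"CDS does not end in a stop codon ({cds[-3:]})")
        aa = translate(cds)
        if "*" in aa[:-1]:
            raise LocusError("internal stop codon in CDS")
        derived = aa[:-1]
        if self.protein_seq and self.protein_seq != derived:
            raise LocusError("protein_seq does not match translated CDS")
        self.protein_seq = derived
        if 3 * (len(self.protein_seq) + 1) != self.cds_len:
            raise LocusError("protein length inconsistent with CDS length")

    # -- basic geometry ----------------------------------------------------

    @property
    def cds_len(self) -> int:
        return self.cds_end - self.cds_start + 1

    @property
    def utr3_len(self) -> int:
        return len(self.transcript_seq) - self.cds_end

    @property
    def cds_seq(self) -> str:
        return self.transcript_seq[self.cds_start - 1 : self.cds_end]

    # -- transcript <-> genomic -------------------------------------------

    def genomic_to_transcript(self, g: int) -> int:
        """Map a genomic position to a 1-based transcript position."""
        offset = 0
        for exon in self.exons:
            if exon.start <= g <= exon.end:
                if self.strand == "-":
                    return offset + (exon.end - g) + 1
                return offset + (g - exon.start) + 1
            offset += len(exon)
        raise OutOfLocusError(
            f"{self.contig}:{g} is intronic or outside the modeled exons"
        )

    def transcript_to_genomic(self, t: int) -> int:
        if not 1 <= t <= len(self.transcript_seq):
            raise OutOfLocusError(f"transcript position {t} out of range")
        offset = 0
        for exon in self.exons:
            if t <= offset + len(exon):
                within = t - offset - 1
                if self.strand == "-":
                    return exon.end - within
                return exon.start + within
            offset += len(exon)
        raise AssertionError("unreachable")

    # -- cDNA coordinates --------------------------------------------------

    def transcript_to_cdna(self, t: int) -> int:
        """Transcript position -> coding coordinate (c.1 = CDS start).

        Positions past the stop codon are returned as continuing integers
        (cds_len + k for the k-th 3'-UTR base); callers format them as *k
        where HGVS typography matters.
        """
        return t - self.cds_start + 1

    def cdna_to_transcript(self, c: int) -> int:
        t = c + self.cds_start - 1
        if not 1 <= t <= len(self.transcript_seq):
            raise OutOfLocusError(f"c.{c} outside the modeled transcript")
        return t

    def genomic_to_cdna(self, g: int) -> int:
        """Genomic position -> coding coordinate.

        On the minus strand this is, within one exon, the affine map
        ``c = A - (g - g0)`` anchored at any exonic pair ``(g0, A)``.
        """
        return self.transcript_to_cdna(self.genomic_to_transcript(g))

    def cdna_to_genomic(self, c: int) -> int:
        return self.transcript_to_genomic(self.cdna_to_transcript(c))

    def cdna_interval_to_genomic(self, iv: CdnaInterval) -> GenomicInterval:
        """Map a cDNA interval to its genomic interval (single-exon spans)."""
        g1 = self.cdna_to_genomic(iv.start_c)
        g2 = self.cdna_to_genomic(iv.end_c)
        lo, hi = min(g1, g2), max(g1, g2)
        got = hi - lo + 1
        if got != len(iv):
            raise LocusError(
                f"cDNA interval c.{iv.start_c}_{iv.end_c} spans an exon junction"
            )
        return GenomicInterval(self.contig, lo, hi)

    def genomic_interval_to_cdna(self, iv: GenomicInterval) -> CdnaInterval:
        c1 = self.genomic_to_cdna(iv.start)
        c2 = self.genomic_to_cdna(iv.end)
        lo, hi = min(c1, c2), max(c1, c2)
        if hi - lo + 1 != len(iv):
            raise LocusError(f"genomic interval {iv} spans an exon junction")
        return CdnaInterval(lo, hi)

    # -- protein coordinates ----------------------------------------------

    def cdna_to_residue(self, c: int) -> tuple[int, int]:
        """Coding position -> (1-based residue index, codon phase 1..3)."""
        if not 1 <= c <= self.cds_len:
            raise NoResidueError(f"c.{c} is not a coding position")
        residue = -(-c // 3)  # ceil(c/3)
        phase = (c - 1) % 3 + 1
        return residue, phase

    def residue(self, index: int) -> str:
        """One-letter amino acid at a 1-based residue index ('*' = stop)."""
        if index == len(self.protein_seq) + 1:
            return "*"
        return self.protein_seq[index - 1]


def apply_allele(model: LocusModel, allele: AlleleSpec) -> str:
    """Build the mutant transcript sequence for a tandem-duplication allele.

    The duplicated segment appears twice in tandem with any junctional
    insertion between the copies; everything outside the junction is
    unchanged, so the output is exactly ``len(dup) + len(insertion)`` bases
    longer than the input transcript.
    """
    seq = model.transcript_seq
    if allele.dup is None:
        return seq
    s = model.cdna_to_transcript(allele.dup.start_c)
    e = model.cdna_to_transcript(allele.dup.end_c)
    if not (1 <= s <= e <= len(seq)):
        raise LocusError("duplication outside transcript bounds")
    ins_after = allele.ins_after
    if ins_after is not None and ins_after != allele.dup.end_c:
        raise LocusError("insertion must sit at the duplication junction")
    return seq[:e] + allele.insertion_seq.upper() + seq[s - 1 :]


def mutant_cds_translation(model: LocusModel, allele: AlleleSpec) -> str:
    """Translate the mutant CDS from the start codon to the first stop.

    Alleles whose duplication disrupts the stop codon (stop-loss mimicry)
    are translated through into the modeled 3'-UTR until the next in-frame
    stop; if none exists before the transcript ends, translation runs to the
    end of the sequence (no trailing '*').
    """
    mutant = apply_allele(model, allele)
    aa = translate(mutant[model.cds_start - 1 :])
    stop = aa.find("*")
    return aa if stop == -1 else aa[: stop + 1]


# -- serialization ---------------------------------------------------------


def save_locus(model: LocusModel, path: str | Path) -> None:
    """Write a locus config as flat YAML (exons in transcript order)."""
    doc = {
        "name": model.name,
        "contig": model.contig,
        "strand": model.strand,
        "exons": [[e.start, e.end] for e in model.exons],
        "cds_start": model.cds_start,
        "cds_end": model.cds_end,
        "transcript_seq": model.transcript_seq,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_locus(path: str | Path) -> LocusModel:
    """Load a locus config; LocusModel invariants are enforced on load."""
    doc = yaml.safe_load(Path(path).read_text())
    try:
        exons = [GenomicInterval(doc["contig"], s, e) for s, e in doc["exons"]]
        return LocusModel(
            contig=doc["contig"],
            strand=doc["strand"],
            exons=exons,
            transcript_seq=doc["transcript_seq"],
            cds_start=int(doc["cds_start"]),
            cds_end=int(doc["cds_end"]),
            name=doc.get("name", "locus"),
        )
    except KeyError as exc:
        raise LocusError(f"locus config missing field {exc}") from exc
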