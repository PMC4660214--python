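"""Synthetic data generation: loci, ITD haplotypes, reads, and tables.

Everything here is seeded and deterministic.  The paired-end read model
emulates the study design the detection pipeline assumes: 2 x 100-bp mates
drawn from normally distributed fragments (resampled while shorter than a
read), independent per-base substitution errors with constant quality, and
a tumour mixture of mutant/wild-type haplotypes.  Sample states:

* ``normal``       -- wild type only.
* ``hemizygous``   -- single allele (X-linked male); ``mutant_fraction`` acts
                      as tumour purity, so reads are mutant with that
                      probability.
* ``heterozygous`` -- two alleles mixed 1:1 within the tumour fraction, so
                      reads are mutant with probability ``mutant_fraction/2``.

No PCR duplicates, indel errors, or quality calibration are modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .locus import AlleleSpec, GenomicInterval, LocusModel, apply_allele
from .align import revcomp

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_BASES = np.frombuffer(b"ACGT", np.uint8)


@dataclass
class SimulationConfig:
    seed: int = 0
    read_len: int = 100
    coverage: float = 100.0
    fragment_mean: float = 300.0
    fragment_sd: float = 50.0
    error_rate: float = 0.005
    mutant_fraction: float = 0.0
    sample_state: str = "normal"  # normal | hemizygous | heterozygous

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutant_fraction <= 1.0:
            raise ValueError("mutant_fraction must be in [0, 1]")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.fragment_mean < self.read_len:
            raise ValueError("fragment_mean shorter than read length")
        if self.sample_state not in ("normal", "hemizygous", "heterozygous"):
            raise ValueError(f"unknown sample_state {self.sample_state!r}")

    @property
    def p_mutant(self) -> float:
        if self.sample_state == "normal":
            return 0.0
        if self.sample_state == "heterozygous":
            return self.mutant_fraction / 2.0
        return self.mutant_fraction


@dataclass
class TruthRecord:
    """Ground truth for one simulated sample."""

    allele: AlleleSpec
    labels: list[str]  # per-pair haplotype, "mut" or "wt"
    n_pairs: int

    @property
    def realized_mutant_fraction(self) -> float:
        if not self.labels:
            return 0.0
        return sum(lab == "mut" for lab in self.labels) / len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pair": [f"read{i:06d}" for i in range(self.n_pairs)],
                "haplotype": self.labels,
            }
        )


def make_reference(
    seed: int,
    *,
    n_residues: int = 260,
    utr3_len: int = 350,
    contig: str = "chrS",
    genomic_end: int = 1_000_000,
    name: str = "synthetic-locus",
) -> LocusModel:
    """Generate a random minus-strand single-exon terminal locus.

    The CDS is ``3*(n_residues+1)`` bases (random sense codons + TGA), so a
    locus emulating a full-length 1755-residue protein has 5268 coding
    bases.  Deterministic for a given seed.
    """
    if n_residues < 1:
        raise ValueError("locus needs at least one coding residue")
    rng = np.random.default_rng(seed)
    codons = [_SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n_residues)]
    cds = "".join(codons) + "TGA"
    utr3 = "".join("ACGT"[i] for i in rng.integers(0, 4, utr3_len))
    transcript = cds + utr3
    exon = GenomicInterval(contig, genomic_end - len(transcript) + 1, genomic_end)
    return LocusModel(
        contig=contig,
        strand="-",
        exons=[exon],
        transcript_seq=transcript,
        cds_start=1,
        cds_end=len(cds),
        name=name,
    )


def _mutate(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), np.uint8).copy()
    hits = np.nonzero(rng.random(arr.shape[0]) < error_rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def _draw_fragment(rng: np.random.Generator, cfg: SimulationConfig, hap_len: int) -> int:
    # truncated normal: resample while shorter than a read or off-haplotype
    for _ in range(1000):
        frag = int(round(rng.normal(cfg.fragment_mean, cfg.fragment_sd)))
        if cfg.read_len <= frag <= hap_len:
            return frag
    return min(hap_len, max(cfg.read_len, int(cfg.fragment_mean)))


def simulate_reads(
    model: LocusModel,
    allele: AlleleSpec,
    config: SimulationConfig,
) -> tuple[list[tuple[str, str, str]], TruthRecord]:
    """Simulate paired-end reads from the wild-type/mutant haplotype mix.

    Returns ``(pairs, truth)`` where each pair is ``(name, seq1, seq2)``
    (mate 1 leftmost/forward, mate 2 reverse-complemented) and the truth
    record carries per-pair haplotype labels.  The expected number of pairs
    is ``coverage * locus_length / (2 * read_len)``.
    """
    rng = np.random.default_rng(config.seed)
    wt = model.transcript_seq
    mut = apply_allele(model, allele)
    n_pairs = int(round(config.coverage * len(wt) / (2 * config.read_len)))
    p_mut = config.p_mutant
    pairs = []
    labels = []
    for i in range(n_pairs):
        is_mut = rng.random() < p_mut
        hap = mut if is_mut else wt
        frag = _draw_fragment(rng, config, len(hap))
        start = int(rng.integers(0, len(hap) - frag + 1))
        fragment = hap[start : start + frag]
        s1 = _mutate(fragment[: config.read_len], rng, config.error_rate)
        s2 = _mutate(revcomp(fragment[-config.read_len :]), rng, config.error_rate)
        pairs.append((f"read{i:06d}", s1, s2))
        labels.append("mut" if is_mut else "wt")
    return pairs, TruthRecord(allele=allele, labels=labels, n_pairs=n_pairs)


def write_fastq(pairs, path1: str | Path, path2: str | Path) -> None:
    """Write mate FASTQ files (4-line records, /1 and /2 name suffixes)."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for name, s1, s2 in pairs:
            f1.write(f"@{name}/1\n{s1}\n+\n{'I' * len(s1)}\n")
            f2.write(f"@{name}/2\n{s2}\n+\n{'I' * len(s2)}\n")


def read_fastq_pairs(path1: str | Path, path2: str | Path):
    """Read mate FASTQ files back into (name, seq1, seq2) tuples."""
    from Bio import SeqIO

    out = []
    for r1, r2 in zip(SeqIO.parse(str(path1), "fastq"), SeqIO.parse(str(path2), "fastq")):
        n1 = r1.id.removesuffix("/1")
        n2 = r2.id.removesuffix("/2")
        if n1 != n2:
            raise ValueError(f"mismatched mates {r1.id} / {r2.id}")
        out.append((n1, str(r1.seq), str(r2.seq)))
    return out


# -- variant tables for the somatic filter ---------------------------------


def write_variant_table(
    truth: TruthRecord,
    model: LocusModel,
    *,
    tumour_depth: int = 100,
    normal_depth: int = 100,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Variant records for the ITD site consistent with simulation truth.

    The tumour row carries alt/total depths whose ratio equals the realized
    mutant read fraction; the matched normal has alt depth 0 (the ITD is
    somatic by construction).  Deterministic given the truth record.
    """
    if truth.allele.dup is None:
        rows = []
    else:
        g = model.cdna_interval_to_genomic(truth.allele.dup)
        alt_depth = int(round(truth.realized_mutant_fraction * tumour_depth))
        rows = [
            {
                "contig": g.contig,
                "pos": g.start,
                "ref": model.transcript_seq[
                    model.cdna_to_transcript(truth.allele.dup.start_c) - 1
                ],
                "alt": "<DUP:TANDEM>",
                "tumour_depth": tumour_depth,
                "tumour_alt": alt_depth,
                "normal_depth": normal_depth,
                "normal_alt": 0,
                "ratio": alt_depth / tumour_depth,
            }
        ]
    df = pd.DataFrame(
        rows,
        columns=[
            "contig", "pos", "ref", "alt", "tumour_depth", "tumour_alt",
            "normal_depth", "normal_alt", "ratio",
        ],
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def random_variant_records(seed: int, n: int) -> pd.DataFrame:
    """Random tumour/normal variant records spanning the filter boundaries.

    Depth/alt draws deliberately straddle the somatic-filter thresholds so
    that a filtered subset is a non-trivial fraction of the table.
    """
    rng = np.random.default_rng(seed)
    total = rng.integers(10, 200, n)
    alt = np.minimum(rng.integers(0, 40, n), total)
    normal_alt = rng.integers(0, 8, n)
    # sprinkle exact boundary cases
    k = min(n, 40)
    idx = rng.choice(n, k, replace=False)
    total[idx[: k // 4]] = 51
    alt[idx[k // 4 : k // 2]] = 7
    normal_alt[idx[k // 2 : 3 * k // 4]] = 4
    ratio_idx = idx[3 * k // 4 :]
    total[ratio_idx] = 100
    alt[ratio_idx] = 5  # ratio exactly 0.05
    return pd.DataFrame(
        {
            "contig": ["chrS"] * n,
            "pos": rng.integers(1, 10_000, n),
            "ref": rng.choice(list("ACGT"), n),
            "alt": rng.choice(list("ACGT"), n),
            "tumour_depth": total,
            "tumour_alt": alt,
            "normal_depth": rng.integers(30, 200, n),
            "normal_alt": normal_alt,
            "ratio": alt / total,
        }
    )


# -- reads for transcript-abundance recovery -------------------------------


def simulate_quant_reads(
    sequences: list[str],
    abundances: list[float],
    n_reads: int,
    *,
    read_len: int = 100,
    error_rate: float = 0.005,
    seed: int = 0,
) -> tuple[list[str], list[int]]:
    """Single-end reads from competing transcripts under the RSEM model.

    Transcript ``r`` generates a read with probability proportional to
    ``abundance_r * effective_length_r`` (effective length = number of
    admissible start positions, ``L - read_len + 1``); the start is uniform.
    This is the generative model the EM quantifier inverts, so abundance
    recovery is unbiased up to sampling error.  Returns reads and true
    source indices.
    """
    rng = np.random.default_rng(seed)
    eff = np.array([max(len(s) - read_len + 1, 1) for s in sequences], float)
    w = np.asarray(abundances, float) * eff
    if w.sum() <= 0:
        raise ValueError("no transcript with positive abundance")
    w = w / w.sum()
    reads, sources = [], []
    for _ in range(n_reads):
        r = int(rng.choice(len(sequences), p=w))
        start = int(rng.integers(0, int(eff[r])))
        seq = sequences[r][start : start + read_len]
        reads.append(_mutate(seq, rng, error_rate))
        sources.append(r)
    return reads, sources


# -- planted expression matrices -------------------------------------------


def simulate_fpkm_matrix(
    seed: int,
    *,
    n_genes: int = 200,
    group_sizes: tuple[int, int] = (6, 6),
    n_effect_genes: int = 40,
    log2_effect: float = 2.0,
    noise_sd: float = 0.5,
) -> tuple[pd.DataFrame, pd.Series]:
    """FPKM-like matrix with a planted two-group structure.

    Baseline expression is log-normal; ``n_effect_genes`` genes are shifted
    by ``log2_effect`` (in log2 units) in group B.  Returns (genes x samples
    DataFrame, sample phenotype labels).
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    samples = [f"A{i}" for i in range(group_sizes[0])] + [
        f"B{i}" for i in range(group_sizes[1])
    ]
    labels = pd.Series(
        ["A"] * group_sizes[0] + ["B"] * group_sizes[1], index=samples, name="phenotype"
    )
    base = rng.normal(3.0, 1.5, n_genes)[:, None]
    logx = base + rng.normal(0.0, noise_sd, (n_genes, len(samples)))
    logx[:n_effect_genes, group_sizes[0] :] += log2_effect
    fpkm = np.power(2.0, logx)
    return pd.DataFrame(fpkm, index=genes, columns=samples), labels
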