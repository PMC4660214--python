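# Methods

## Locus model and coordinates

A locus is a single transcript: exon intervals in transcript order
(1-based inclusive genomic coordinates), the spliced coding-strand
sequence, and the CDS span. On the minus strand genomic coordinates
decrease along the transcript, and within one exon the genomic↔cDNA map is
affine, `c = A − (g − g₀)` for any exonic anchor pair `(g₀, A)`. c.1 is
the first base of the start codon and the stop codon occupies the last
three coding positions, so a protein of `N` residues has `3(N+1)` coding
bases. Residue index is `⌈c/3⌉` with codon phase `((c−1) mod 3) + 1`.
All coordinates are 1-based inclusive throughout; half-open forms appear
only inside serialization code. Multi-exon loci are supported, but all
packaged fixtures keep the ITD region within one exon, matching the
biology this models (every recurrent *BCOR* ITD lies inside terminal
exon 15).

## The synthetic BCOR-like fixture

The package does not redistribute the real *BCOR* sequence. Instead
`bcoritd.fixtures.bcor_like_locus()` builds a **synthetic** locus with the
published geometry (1,755-residue protein, 5,268-base CDS ending in TGA,
chrX minus-strand coordinates anchored at c.5171 ↔ chrX:39,911,459) whose
codons are *pinned* at the thirteen positions that the eleven recurrent
tumour alleles name or constrain. The pins are the solution of the
junction equations the five ITD types impose — e.g. codon 1724 must be
TTA so that the type-I breakpoint at the second base of the stop codon
(T|GA) recreates a leucine; codon 1742 must begin GA so the type-III/IV
junctions restore the downstream residue; codon 1753 must not begin with
G or the type-II duplication would not be at its 3′-most position. All
other codons are seeded random draws from the 61 sense codons. On this
sequence every published allele reproduces its full genomic, cDNA *and*
protein annotation verbatim, which is what the annotation test suite
asserts. Conclusions about annotation *letters* (not coordinates)
therefore rest on the pinned positions only; coordinate arithmetic is
sequence-independent.

## Read simulation

`simulate_reads` draws read pairs from a wild-type/mutant haplotype mix:

* paired-end, 2×100 bp by default; fragment length truncated-normal
  (mean 300, sd 50 — defaults chosen as typical Illumina values since no
  empirical distribution was available), resampled while shorter than a
  read;
* independent per-base substitution errors (default 0.005), constant
  quality strings, no indel errors, no PCR duplicates;
* expected pairs = `coverage · locus_length / (2 · read_length)`;
* sample states: `normal` (wild type only), `hemizygous` (single allele;
  `mutant_fraction` acts as tumour purity), `heterozygous` (two alleles
  mixed 1:1 within the tumour fraction, so reads are mutant with
  probability `mutant_fraction/2`).

Everything is deterministic given the seed. What the generator does *not*
emulate — alignment artifacts of a genome-wide aligner, indels, quality
miscalibration, GC/coverage bias, chimeric fragments — bounds what a green
test shows about real data: the suite validates the *logic* of detection
and quantification under the stated error model, not robustness to every
sequencing pathology.

## Aligner

A semi-global affine-gap aligner with free terminal clipping: match +1,
mismatch −2, gaps −4 for the first base and −1 thereafter; unaligned read
ends become CIGAR soft clips at no cost. Reads scoring below
`0.6 · read_length` are reported unmapped — which deliberately turns
evenly split junction reads into the unmapped-mate (discordant) class the
detector mines. Both orientations are tried (forward preferred on ties);
among equal-scoring placements the earliest end cell in row-major order
wins, which selects the leftmost reference position for equal-length
placements. Exact full-length substring matches shortcut the dynamic
program (they attain the maximal score). The implementation is validated
cell-for-cell against an independent score-only Gotoh oracle in the test
suite. The detector does not depend on aligner-specific clip lengths
beyond the configurable `min_clip_len`.

## ITD detection

Defaults: `min_clip_len` 10, minimum clip-read support 3, clip-match
identity 90%, search radius 500 bp, seed length 8. None of these were
published; they are chosen so 100× simulations are saturated while clips
carrying one sequencing error still match. Clip realignment is
seed-and-extend: exact 8-mers seed candidate diagonals, each evaluated
ungapped; non-templated junction bases may be trimmed from the junction
side of the clip (up to 20 bp) but the remaining segment must *begin*
with a clean 5-base match run, so an insertion is never silently absorbed
as junction mismatches.

Candidates `(s, e, insertion)` from both junction sides are
**canonicalized** before voting: among all decompositions producing the
identical mutant sequence, the canonical one has the shortest insertion
(templated bases belong to the duplication — the HGVS preference for dup
over ins) and, at that length, the transcript-3′-most interval. The
search is closed-form: with `P`/`S` the longest common prefix/suffix of
mutant and reference and `n` the total inserted length, the minimal
insertion length is `max(0, n − (P + S − L))` and the canonical interval
always ends at `P`. When the two junction sides saturate on different
candidates (typically because the aligner absorbed an insertion base into
one anchor for a net score gain), the candidate whose exact junction
string appears verbatim in more reads wins; a genuine tie raises an
ambiguous-call error listing both.

**VAF** is allele-counting: each mutant haplotype copy exposes one novel
junction adjacency but both haplotypes expose two reference adjacencies
(`s−1|s` and `e|e+1`), so `VAF = 2·J/R` (clamped to [0,1]) where `J`
counts reads spanning the novel adjacency by ≥ `min_clip_len` bases on
each side and `R` counts reference-adjacency spans. This is unbiased for
mixtures (pure mutant → 1, 1:1 heterozygous → 0.5) but inherits Poisson
noise from the ~80-position junction window: at 100× its standard error
is roughly 0.1, which is why the hemizygous saturation test asserts the
median over a seed ladder rather than a single draw.

The discordant corroboration realigns unmapped mates of mapped reads
permissively (threshold 0.4·read length) and thresholds the resulting
depth profile at background median + 3·MAD, floored at an absolute depth
of 3 so isolated stray reads in ITD-free samples cannot surface as peaks.

## Protein annotation

In-frame alleles are annotated by translating the mutant CDS — through
into the modeled 3′-UTR when the duplication disrupts the stop codon —
then trimming the longest common prefix and, from the remainder, the
longest common suffix against the reference protein. The inserted peptide
is decomposed as: longest suffix matching the reference segment ending at
the trim point → the `dup` part; any residual prefix is reported first,
as an insertion (`p.X_YinsZ`) when the allele carries a non-templated
nucleotide insertion, or as a single-residue missense (`p.XnY`) when a
split codon re-reads the boundary residue differently. This residual-first
order reproduces all three published annotation patterns with one rule.
Frameshift alleles are refused at the protein level with a frameshift
status. Frame is checked as `(dup + insertion) mod 3 == 0`.

## EM quantification

The competing references are the transcript from the start of the sixth
exon from the end through the stop codon plus the first 304 bases of
3′-UTR, with and without the ITD bases. Per-read likelihood against each
reference is the product of per-base match/error probabilities at the
best substitution-only placement (seeded, consistent with the simulator's
error model; default error rate 0.005); reads with no seed hit or > 15%
mismatches are incompatible. The EM assigns read `i` to reference `r`
proportionally to `θ_r · lik_ir / ℓ̃_r` with effective length
`ℓ̃ = L − mean_fragment + 1` floored at 1; `θ` (the read-origin fractions)
updates as expected counts over reads, converging when the largest change
drops below 1e-6 (at most 1000 iterations). Reported **abundance
fractions are `θ_r/ℓ̃_r` renormalized** — without this correction the raw
count ratio over-represents the longer (mutant) reference; the test suite
checks both the bias and its removal. Junction reads are compatible only
with the mutant reference, so a pure hemizygous mutant quantifies at
≈ 1.0 even with sequencing errors. The quantification read generator
draws reads `∝ abundance × effective length` (the generative model the
EM inverts), so "true mutant fraction" in recovery tests means transcript
abundance fraction, not read fraction.

## Somatic filter

Retained iff ratio > 0.05 AND tumour depth > 50 AND tumour alt > 6 AND
normal alt < 4. The inequalities are read as strict, so boundary equality
rejects (all four thresholds are configurable). "Variant ratio" is the
tumour VAF; the normal-side threshold counts reads, matching the units of
the other coverage filters. The filter is monotone in every threshold and
order/duplicate stable; rows with missing depth fields are rejected with
a per-row reason rather than failing the table.

## Expression recipe

Gene filtering keeps mean > 1.5 FPKM and CV > 0.3 (strict), with CV using
the *sample* standard deviation (ddof 1; the population/sample choice was
unstated, sample sd documented here). An optional identifier-prefix
filter drops RPL/RPS ribosomal genes. Clustering is UPGMA (SciPy average
linkage) on `1 − Spearman` with average ranks for ties; a zero-variance
sample is an error naming the sample. Equal-distance merges follow
SciPy's deterministic first-minimum ordering, which serves the
determinism the tie rule exists for. The signal-to-noise score is
`(μ_A − μ_B)/(σ_A + σ_B)` with each σ floored at `0.2·|μ|` (0.2 when
μ = 0), the conventional default; the floor fraction is configurable. The
score is antisymmetric under label swap and invariant under positive
per-gene rescaling.

## Problem sizes and numerical choices

The validation suites run on a ~1.1 kb synthetic locus at 100× (≈ 566
pairs per sample; 50 allele round-trips + 20 null samples), 20,000 reads
per EM recovery point, 1,000-record filter tables, 200 aligner-oracle
pairs, and 100 seeded clustering runs — sizes chosen so the whole suite
completes in about a minute while keeping binomial tolerances meaningful
(±0.03 at 20,000 reads ≈ 3 standard errors). Tolerances: EM fraction sum
1e-9; log-likelihood monotonicity slack 1e-8 (floating-point
accumulation); canonicalization and coordinate arithmetic are exact
integer checks.

## Known limitations

* One ITD per locus: the detector reports the single best-supported call;
  multi-clonal mixtures of different ITDs are out of scope.
* The stop-loss mimicry that first flagged the type-I allele in clinical
  variant calling is covered as an annotation behaviour (translation
  through the 3′-UTR), not re-created in a SNV caller.
* Substitution-only error model end to end; indel sequencing errors would
  perturb both the aligner fast path and the clip matcher.
* The fixture locus is synthetic: protein-letter assertions hold by
  construction at pinned positions; running against the real reference
  requires supplying a locus config with the real sequence.
* VAF carries ~0.1 sampling noise at 100× (see above); it is a read-count
  estimator, not a confidence-calibrated genotype.
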