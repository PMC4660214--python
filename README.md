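# bcoritd

Detection, annotation and quantification of **internal tandem duplications
(ITDs)** at a single gene locus, built around the recurrent in-frame
duplications that cluster in the terminal exon of *BCOR* (Xp11.4, minus
strand) in pediatric clear cell sarcoma of the kidney.

ITDs are easy to miss: mapping algorithms soft-clip or discard the reads
that cross the duplication junction, so a 90-bp event can masquerade as a
stop-loss SNV or vanish entirely. This package reimplements, at desk scale
and as a tested library, the computational recipe that finds them:

1. **Soft-clip detection** — reads crossing the junction align their
   reference-colinear part and carry a terminal soft clip (CIGAR `S`);
   clipped subsequences are harvested and locally realigned to the locus.
   A right-clip whose clip re-matches *inside and upstream of* its own
   aligned span is the tandem-duplication signature.
2. **Reconstruction** — the duplicated interval `[s, e]` and any
   non-templated junctional insertion are voted from both junction sides
   and canonicalized (shortest insertion, then the HGVS transcript-3′-most
   interval).
3. **Discordant mate-pair corroboration** — mates that fail to map are
   permissively realigned to the transcript, where an ITD produces a focal
   coverage peak over the duplicated segment.
4. **Annotation** — minus-strand genomic/cDNA/protein descriptions. Within
   one exon the map is affine, `c = A − (g − g₀)` for an anchor pair
   `(g₀, A)`; residue `= ⌈c/3⌉`, phase `= ((c−1) mod 3) + 1`. Protein
   consequences are obtained by translating the mutant CDS (through the
   3′-UTR when the duplication disrupts the stop codon) and trimming
   against the reference protein, yielding the three observed patterns:
   `p.X_Ydup`, `p.X_YinsZ+p.A_Bdup`, and `p.XnY+p.A_Bdup`.
5. **Somatic filtering** — tumour/normal depth filters (ratio > 0.05,
   tumour depth > 50, tumour alt > 6, normal alt < 4; strict).
6. **EM quantification** — mutant vs wild-type transcript fractions from
   reads aligned to two competing references (terminal exons + 304-bp
   3′-UTR prefix, with and without the ITD bases), with RSEM-style
   effective-length correction: reads are assigned fractionally
   `∝ θ_r · P(read|r) / ℓ̃_r`, and abundances are `θ_r/ℓ̃_r` renormalized.
7. **Expression profiling** — FPKM filtering (mean > 1.5, CV > 0.3), UPGMA
   clustering on (1 − Spearman) distance, and signal-to-noise gene ranking
   `(μ_A − μ_B)/(σ_A + σ_B)` with the conventional 0.2·|μ| floor on σ.

Everything runs on seeded synthetic data produced by the package's own
generators (paired-end 2×100-bp reads, configurable coverage, error rate,
mutant fraction, hemizygous/heterozygous states), with ground truth
recorded for every read.

## Worked example

```python
from bcoritd import (make_reference, simulate_reads, SimulationConfig,
                     AlleleSpec, CdnaInterval, align_pairs, reconstruct_itd)
from bcoritd.detect import calls_to_frame
from bcoritd.quant import build_competing_refs, quantify
from bcoritd.simulate import simulate_quant_reads

model = make_reference(seed=42)  # ~1.1 kb minus-strand single-exon locus
allele = AlleleSpec(dup=CdnaInterval(450, 536), insertion_seq="TGT")
cfg = SimulationConfig(seed=9, coverage=100, mutant_fraction=1.0,
                       sample_state="hemizygous")
pairs, truth = simulate_reads(model, allele, cfg)
records = [r for pair in align_pairs(pairs, model.transcript_seq) for r in pair]
call = reconstruct_itd(records, model)
print(calls_to_frame([call], model, sample="tumour1").T.to_string())
```

```
sample                                     tumour1
gdna                       chrS:g.999465_999551dup
cdna                                  c.450_536dup
insertion                                      TGT
itd_length                                      87
clip_support                                    55
discordant_support                              30
vaf                                         0.8077
in_frame                                      True
protein             p.C179_L180insV+p.S151_C179dup
```

The detector recovered the simulated 87-bp duplication exactly, including
the 3-bp `TGT` junctional insertion (87 + 3 ≡ 0 mod 3: in frame), from 55
clipped reads and 30 discordant mates. The protein consequence shows the
insertion-plus-duplication pattern. Quantifying a pure-mutant read set
against the two competing references:

```python
refs = build_competing_refs(model, call.allele)
reads, _ = simulate_quant_reads(refs.sequences, [1.0, 0.0], 10000,
                                seed=9, error_rate=0.005)
print(quantify(reads, refs).summary())
```

```
Mutant/wild-type transcript quantification (EM)
-----------------------------------------------
reads used          10000
reads incompatible  0
iterations          498
log-likelihood      -107318.510
mutant fraction     0.9999
wild-type fraction  0.0001
expected counts     mutant 9999.4, wild-type 0.6
```

i.e. essentially all expression is contributed by the mutant transcript,
as expected for a hemizygous locus whose single allele carries the ITD.

A `bcoritd` console script exposes the same steps
(`simulate`, `align`, `detect`, `annotate`, `filter-somatic`, `quantify`,
`profile`); see `bcoritd --help`.

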