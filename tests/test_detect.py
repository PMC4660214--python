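"""Soft-clip harvest, clip realignment, ITD reconstruction, discordant peak."""

import numpy as np
import pytest

from bcoritd.align import align_pairs
from bcoritd.annotate import normalize_itd
from bcoritd.detect import (
    calls_to_frame,
    calls_to_vcf,
    discordant_peak,
    harvest_softclips,
    match_clip,
    reconstruct_itd,
)
from bcoritd.locus import AlleleSpec, CdnaInterval, apply_allele
from bcoritd.simulate import SimulationConfig, simulate_reads


class TestHarvestSoftclips:
    def test_clips_cluster_at_two_junction_anchors(self, type1_sample, small_locus):
        allele, records, _ = type1_sample
        clips = harvest_softclips(records, min_clip_len=10)
        s = small_locus.cdna_to_transcript(allele.dup.start_c)
        e = small_locus.cdna_to_transcript(allele.dup.end_c)
        anchors = {}
        for seg in clips:
            anchors[seg.anchor] = anchors.get(seg.anchor, 0) + 1
        top2 = sorted(anchors, key=anchors.get, reverse=True)[:2]
        # junction microhomology lets the aligner extend a few bases past
        # the breakpoints, so each modal anchor sits at its junction side
        # up to a short homology offset
        lo_anchor, hi_anchor = sorted(top2)
        assert s - 6 <= lo_anchor <= s
        assert e <= hi_anchor <= e + 6
        assert anchors[lo_anchor] + anchors[hi_anchor] >= 0.8 * len(clips)

    def test_itd_free_sample_has_no_clips(self, itd_free_sample):
        assert harvest_softclips(itd_free_sample, min_clip_len=10) == []

    def test_min_clip_longer_than_read_yields_nothing(self, type1_sample):
        _, records, _ = type1_sample
        assert harvest_softclips(records, min_clip_len=101) == []


class TestMatchClip:
    def test_verbatim_substring_hits_perfectly(self, small_locus):
        ref = small_locus.transcript_seq
        clip = ref[700:730]
        hit = match_clip(clip, ref, anchor=740, side="right")
        assert hit is not None
        assert (hit.ref_start, hit.ref_end) == (701, 730)
        assert hit.identity == 1.0 and hit.unmatched == ""

    def test_tandem_signature_hit_inside_aligned_span(self, small_locus):
        # a right clip from a junction read re-matches upstream of its anchor
        model = small_locus
        allele = AlleleSpec(dup=CdnaInterval(500, 595))
        mutant = apply_allele(model, allele)
        read = mutant[525:625]  # 70 aligned bases, 30 clipped
        clip = read[70:]
        hit = match_clip(clip, model.transcript_seq, anchor=595, side="right")
        assert hit is not None
        assert hit.ref_start == 500  # back to the duplication start
        assert hit.ref_start <= 595

    def test_random_clip_has_no_hit(self, small_locus):
        rng = np.random.default_rng(1)
        clip = "".join("ACGT"[i] for i in rng.integers(0, 4, 30))
        assert match_clip(clip, small_locus.transcript_seq, anchor=500) is None


class TestReconstruction:
    def test_clean_dup_recovered_exactly(self, type1_sample, small_locus):
        allele, records, _ = type1_sample
        call = reconstruct_itd(records, small_locus)
        assert call is not None
        truth = normalize_itd(
            small_locus.transcript_seq,
            small_locus.cdna_to_transcript(allele.dup.start_c),
            small_locus.cdna_to_transcript(allele.dup.end_c),
            "",
        )
        assert call.dup_transcript == truth[:2]
        assert call.insertion_seq == truth[2]
        assert call.dup_length == 96
        assert call.in_frame
        assert call.clip_support >= 3

    def test_junctional_insertion_recovered(self, small_locus):
        allele = AlleleSpec(dup=CdnaInterval(450, 536), insertion_seq="TGT")
        cfg = SimulationConfig(seed=9, coverage=100, mutant_fraction=1.0,
                               sample_state="hemizygous")
        pairs, _ = simulate_reads(small_locus, allele, cfg)
        records = [r for pr in align_pairs(pairs, small_locus.transcript_seq)
                   for r in pr]
        call = reconstruct_itd(records, small_locus)
        assert call.insertion_seq == "TGT"
        assert call.dup_length == 87
        assert (call.dup_length + len(call.insertion_seq)) % 3 == 0
        assert call.in_frame

    def test_itd_free_sample_yields_no_call(self, itd_free_sample, small_locus):
        assert reconstruct_itd(itd_free_sample, small_locus) is None

    def test_hemizygous_pure_mutant_vaf_saturates(self, small_locus):
        # the wild-type allele is essentially undetectable in pure
        # hemizygous mutants; junction-read sampling noise at 100x makes
        # single runs fluctuate, so the median over a seed ladder is used
        allele = AlleleSpec(dup=CdnaInterval(500, 595))
        vafs = []
        for seed in (1, 2, 3, 4, 5):
            cfg = SimulationConfig(seed=seed, coverage=100, mutant_fraction=1.0,
                                   sample_state="hemizygous")
            pairs, _ = simulate_reads(small_locus, allele, cfg)
            records = [r for pr in align_pairs(pairs, small_locus.transcript_seq)
                       for r in pr]
            vafs.append(reconstruct_itd(records, small_locus).vaf)
        assert float(np.median(vafs)) >= 0.95
        assert all(0.0 <= v <= 1.0 for v in vafs)

    def test_in_frame_flag_matches_arithmetic(self, small_locus):
        for dup, ins in [((500, 595), ""), ((450, 536), "TGT"), ((400, 450), "")]:
            allele = AlleleSpec(dup=CdnaInterval(*dup), insertion_seq=ins)
            cfg = SimulationConfig(seed=13, coverage=100, mutant_fraction=1.0,
                                   sample_state="hemizygous")
            pairs, _ = simulate_reads(small_locus, allele, cfg)
            records = [r for pr in align_pairs(pairs, small_locus.transcript_seq)
                       for r in pr]
            call = reconstruct_itd(records, small_locus)
            assert call.in_frame == (
                (call.dup_length + len(call.insertion_seq)) % 3 == 0
            )


class TestDiscordantPeak:
    def test_itd_free_sample_has_no_peak(self, itd_free_sample, small_locus):
        assert discordant_peak(itd_free_sample, small_locus).peak is None

    def test_peak_overlaps_duplicated_segment(self, type1_sample, small_locus):
        allele, records, _ = type1_sample
        prof = discordant_peak(records, small_locus)
        assert prof.peak is not None
        s = small_locus.cdna_to_transcript(allele.dup.start_c)
        e = small_locus.cdna_to_transcript(allele.dup.end_c)
        lo, hi = prof.peak
        assert lo <= e and hi >= s  # overlap with the duplicated interval
        assert (prof.depth >= 0).all()

    def test_peak_height_monotone_in_mutant_fraction(self, small_locus):
        allele = AlleleSpec(dup=CdnaInterval(500, 595))
        heights = []
        for frac in (0.2, 0.5, 1.0):
            cfg = SimulationConfig(seed=21, coverage=100, mutant_fraction=frac,
                                   sample_state="hemizygous")
            pairs, _ = simulate_reads(small_locus, allele, cfg)
            records = [r for pr in align_pairs(pairs, small_locus.transcript_seq)
                       for r in pr]
            heights.append(discordant_peak(records, small_locus).depth.max())
        assert heights[0] < heights[1] < heights[2]


class TestCallOutput:
    def test_tsv_frame_fields(self, type1_sample, small_locus):
        _, records, _ = type1_sample
        call = reconstruct_itd(records, small_locus)
        frame = calls_to_frame([call], small_locus, sample="s1")
        row = frame.iloc[0]
        assert row["sample"] == "s1"
        assert row["itd_length"] == 96
        assert row["cdna"].startswith("c.") and row["cdna"].endswith("dup")
        assert 0 <= row["vaf"] <= 1

    def test_vcf_output_parses(self, tmp_path, type1_sample, small_locus):
        import pysam

        _, records, _ = type1_sample
        call = reconstruct_itd(records, small_locus)
        path = tmp_path / "calls.vcf"
        calls_to_vcf([call], small_locus, path, sample="s1")
        with pysam.VariantFile(str(path)) as vcf:
            recs = list(vcf)
        assert len(recs) == 1
        rec = recs[0]
        assert rec.info["SVTYPE"] == "DUP:TANDEM"
        assert rec.info["SVLEN"] == 96
        assert 0.0 <= rec.info["VAF"] <= 1.0
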