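"""Somatic telomere-insertion calling: clustering, refinement, annotation."""

import pandas as pd
import pytest

from conftest import brute_force_microhomology, random_dna
from tmmkit.insertion_detection import (
    CandidateRegion,
    DiscordantTelomerePair,
    SplitRead,
    TelomereInsertion,
    annotate_cn_change,
    annotate_nearby_sv,
    call_candidate_regions,
    call_insertions,
    classify_sidedness,
    detect_microhomology,
    filter_control_panel,
    refine_junction,
    scan_alignment,
)
from tmmkit.synthetic_data import PlantedInsertion, SimulationConfig, generate_sample_pair

TEL = "TTAGGG" * 20


def dpair(chrom="chr1", start=10_000, qname="q"):
    return DiscordantTelomerePair(
        chrom=chrom, anchor_start=start, anchor_end=start + 100,
        anchor_strand="+", mate_sequence=TEL[:100], qname=qname,
    )


def split(pos, side="right", seq="TTAGGG" * 8, chrom="chr1", mapq=60):
    return SplitRead(chrom=chrom, clip_pos=pos, side=side, clipped_seq=seq, mapping_quality=mapq)


def ins(chrom="chr1", pos=10_000, orient="telomere-right", strand="G", **kw):
    return TelomereInsertion(
        chrom=chrom, position=pos, orientation=orient, repeat_strand=strand,
        n_discordant=5, n_split=3, **kw,
    )


class TestDiscordantPairCollection:
    def test_anchor_mapq_boundary_and_both_telomeric(self, tmp_path, patterns):
        """Anchors must be uniquely mapped (MAPQ > 30); pairs with two
        telomeric mates are not discordant telomere pairs."""
        import pysam

        header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 100_000}]}
        path = tmp_path / "t.sam"
        with pysam.AlignmentFile(str(path), "w", header=header) as fh:
            def rec(name, seq, mapq, unmapped, read1):
                a = pysam.AlignedSegment(fh.header)
                a.query_name = name
                a.query_sequence = seq
                a.query_qualities = [30] * len(seq)
                a.is_paired = True
                a.is_read1 = read1
                a.is_read2 = not read1
                if unmapped:
                    a.is_unmapped = True
                else:
                    a.reference_name = "chr1"
                    a.reference_start = 5_000
                    a.mapping_quality = mapq
                    a.cigarstring = f"{len(seq)}M"
                return a

            bg = random_dna(__import__("numpy").random.default_rng(0), 100)
            # good pair: anchor MAPQ 60 + unmapped telomeric mate
            fh.write(rec("good", bg, 60, False, True))
            fh.write(rec("good", TEL[:100], 0, True, False))
            # low-quality anchor (MAPQ 20): excluded
            fh.write(rec("lowq", bg, 20, False, True))
            fh.write(rec("lowq", TEL[:100], 0, True, False))
            # both mates telomeric: not discordant
            fh.write(rec("both", TEL[:100], 0, True, True))
            fh.write(rec("both", TEL[6:106], 0, True, False))
        pairs, _, qc = scan_alignment(path, patterns)
        assert [p.qname for p in pairs] == ["good"]


class TestCandidateRegions:
    def test_three_anchors_within_gap_is_candidate(self):
        tumor = [dpair(start=10_000 + i * 300, qname=f"q{i}") for i in range(3)]
        regions = call_candidate_regions(tumor, [])
        assert len(regions) == 1
        assert regions[0].n_tumor == 3

    def test_two_anchors_below_threshold(self):
        tumor = [dpair(start=10_000 + i * 300, qname=f"q{i}") for i in range(2)]
        assert call_candidate_regions(tumor, []) == []

    def test_control_overlap_rejects_cluster(self):
        tumor = [dpair(start=10_000 + i * 200, qname=f"q{i}") for i in range(5)]
        control = [dpair(start=10_400, qname="c0")]
        assert call_candidate_regions(tumor, control) == []

    def test_distant_control_pair_is_irrelevant(self):
        tumor = [dpair(start=10_000 + i * 200, qname=f"q{i}") for i in range(5)]
        control = [dpair(start=50_000, qname="c0")]
        assert len(call_candidate_regions(tumor, control)) == 1

    def test_gap_over_1kb_splits_clusters(self):
        tumor = [dpair(start=s, qname=f"q{s}") for s in (10_000, 10_500, 12_000, 12_400, 12_800)]
        regions = call_candidate_regions(tumor, [])
        assert [r.n_tumor for r in regions] == [3]  # first cluster has only 2


class TestRefineJunction:
    region = CandidateRegion("chr1", 9_500, 10_500, [dpair(qname=f"q{i}") for i in range(3)])

    def test_three_split_reads_define_junction(self):
        splits = [split(10_050) for _ in range(3)]
        out = refine_junction(self.region, splits)
        assert out is not None
        assert out.position == 10_050
        assert out.orientation == "telomere-right"
        assert out.repeat_strand == "G"

    def test_clips_without_ttaggg_rejected(self):
        splits = [split(10_050, seq="ACGTAC" * 8) for _ in range(5)]
        assert refine_junction(self.region, splits) is None

    def test_c_strand_clip_normalized(self):
        splits = [split(10_050, side="left", seq="CCCTAA" * 8) for _ in range(3)]
        out = refine_junction(self.region, splits)
        assert out.orientation == "telomere-left"
        assert out.repeat_strand == "C"

    def test_two_split_reads_insufficient(self):
        splits = [split(10_050) for _ in range(2)]
        assert refine_junction(self.region, splits) is None

    def test_tie_break_smallest_coordinate(self):
        splits = [split(10_060) for _ in range(3)] + [split(10_040) for _ in range(3)]
        out = refine_junction(self.region, splits)
        assert out.position == 10_040

    def test_short_clip_rejected(self):
        splits = [split(10_050, seq="TTAGGG") for _ in range(4)]  # 6 bp < 12 bp minimum
        assert refine_junction(self.region, splits) is None

    def test_impure_clip_rejected(self):
        impure = "TTAGGG" + "ACGTACGTACGTACGTAC"  # one repeat, purity 0.25
        splits = [split(10_050, seq=impure) for _ in range(4)]
        assert refine_junction(self.region, splits) is None


class TestControlPanel:
    def make_panel(self, n_hit, n_total=20, chrom="chr1", span=(9_600, 10_600)):
        panel = [{} for _ in range(n_total)]
        for i in range(n_hit):
            panel[i][chrom] = [span]
        return panel

    def test_recurrent_in_15_controls_excluded(self):
        out = filter_control_panel([ins(pos=10_000)], self.make_panel(15))
        assert out == []

    def test_recurrent_in_14_controls_retained(self):
        out = filter_control_panel([ins(pos=10_000)], self.make_panel(14))
        assert len(out) == 1

    def test_empty_panel_passes_through_with_warning(self):
        with pytest.warns(UserWarning):
            out = filter_control_panel([ins()], [])
        assert len(out) == 1


class TestSidedness:
    def test_partners_9kb_apart_two_sided(self):
        a = ins(pos=10_000, orient="telomere-right", strand="G")
        b = ins(pos=19_000, orient="telomere-left", strand="G")
        out = classify_sidedness([a, b])
        assert a.sidedness == b.sidedness == "two_sided"
        assert out[a.partner] is b and out[b.partner] is a  # symmetric

    def test_partners_11kb_apart_one_sided(self):
        a = ins(pos=10_000, orient="telomere-right")
        b = ins(pos=21_000, orient="telomere-left")
        classify_sidedness([a, b])
        assert a.sidedness == b.sidedness == "one_sided"

    def test_same_orientation_not_paired(self):
        a = ins(pos=10_000, orient="telomere-right")
        b = ins(pos=15_000, orient="telomere-right")
        classify_sidedness([a, b])
        assert a.sidedness == "one_sided"

    def test_different_forward_strand_repeat_not_paired(self):
        a = ins(pos=10_000, orient="telomere-right", strand="G")
        b = ins(pos=15_000, orient="telomere-left", strand="C")
        classify_sidedness([a, b])
        assert a.sidedness == "one_sided"

    def test_different_chromosomes_not_paired(self):
        a = ins(chrom="chr1", pos=10_000, orient="telomere-right")
        b = ins(chrom="chr2", pos=15_000, orient="telomere-left")
        classify_sidedness([a, b])
        assert a.sidedness == "one_sided"


def cn_frame(*segs):
    return pd.DataFrame(segs, columns=["chrom", "start", "end", "copy_number"])


class TestCnChange:
    def test_loss_across_nearby_breakpoint(self):
        # boundary at 120,000 (20 kb from the junction), CN 3 -> 2 distal
        segs = cn_frame(("chr1", 0, 120_000, 3), ("chr1", 120_000, 300_000, 2))
        assert annotate_cn_change(ins(pos=100_000), segs) == "loss"

    def test_gain(self):
        segs = cn_frame(("chr1", 0, 120_000, 2), ("chr1", 120_000, 300_000, 4))
        assert annotate_cn_change(ins(pos=100_000), segs) == "gain"

    def test_no_breakpoint_within_50kb_neutral(self):
        segs = cn_frame(("chr1", 0, 200_000, 3), ("chr1", 200_000, 300_000, 2))
        assert annotate_cn_change(ins(pos=100_000), segs) == "neutral"

    def test_equal_flanks_neutral(self):
        segs = cn_frame(("chr1", 0, 120_000, 2), ("chr1", 120_000, 300_000, 2))
        assert annotate_cn_change(ins(pos=100_000), segs) == "neutral"

    def test_complex_over_four_copies(self):
        segs = cn_frame(("chr1", 0, 120_000, 7), ("chr1", 120_000, 300_000, 2))
        assert annotate_cn_change(ins(pos=100_000), segs) == "complex"

    def test_exactly_four_copy_step_not_complex(self):
        segs = cn_frame(("chr1", 0, 120_000, 6), ("chr1", 120_000, 300_000, 2))
        assert annotate_cn_change(ins(pos=100_000), segs) == "loss"

    def test_orientation_flips_direction(self):
        """The loss/gain direction tracks the broken distal fragment: for a
        telomere-left junction the distal side is the lower-coordinate one."""
        segs = cn_frame(("chr1", 0, 120_000, 3), ("chr1", 120_000, 300_000, 2))
        assert annotate_cn_change(ins(pos=100_000, orient="telomere-left"), segs) == "gain"

    def test_segments_under_10kb_ignored(self):
        segs = cn_frame(
            ("chr1", 0, 120_000, 2),
            ("chr1", 120_000, 125_000, 9),  # sub-resolution sliver
            ("chr1", 125_000, 300_000, 2),
        )
        assert annotate_cn_change(ins(pos=100_000), segs) == "neutral"

    def test_unsegmented_region_neutral(self):
        assert annotate_cn_change(ins(chrom="chr9"), cn_frame(("chr1", 0, 50_000, 2))) == "neutral"


class TestNearbySv:
    def sv_at(self, pos):
        return pd.DataFrame(
            [{"chrom1": "chr1", "pos1": pos, "strand1": "+",
              "chrom2": "chr5", "pos2": 1, "strand2": "+"}]
        )

    def test_sv_8kb_away_flagged(self):
        i = ins(pos=100_000)
        annotate_nearby_sv(i, self.sv_at(108_000))
        assert i.nearby_sv is True

    def test_sv_12kb_away_not_flagged(self):
        i = ins(pos=100_000)
        annotate_nearby_sv(i, self.sv_at(112_000))
        assert i.nearby_sv is False

    def test_other_insertion_counts_as_breakpoint(self):
        i = ins(pos=100_000)
        other = ins(pos=106_000)
        annotate_nearby_sv(i, None, other_insertions=[i, other])
        assert i.nearby_sv is True

    def test_chromothripsis_overlap(self):
        i = ins(pos=100_000)
        regions = pd.DataFrame([{"chrom": "chr1", "start": 50_000, "end": 150_000}])
        annotate_nearby_sv(i, None, chromothripsis=regions)
        assert i.in_chromothripsis is True


class TestMicrohomology:
    def test_no_shared_bases(self):
        # flank ends in T where the repeat phase demands G: no slide possible
        length, _ = detect_microhomology("ACGTACCATT", "TTAGGG" * 3)
        assert length == 0

    def test_in_phase_flank_extension(self):
        # flank ends TTA, insert begins at the GGG phase: junction can slide 3
        length, _ = detect_microhomology("ACGTACT" + "TTA", "GGG" + "TTAGGG" * 3)
        assert length == 3

    def test_full_hexamer_overlap(self):
        length, _ = detect_microhomology("ACGTACT" + "GGTTAG", "GG" + "TTAGGG" * 3)
        assert length == 6

    def test_interstitial_repeat_flagged_ambiguous(self):
        _, ambiguous = detect_microhomology("TTAGGG" * 3, "TTAGGG" * 3)
        assert ambiguous is True

    def test_matches_brute_force_oracle(self, rng):
        """Implementation equals the exhaustive junction-sliding oracle on
        random flanks grafted with partial repeat tails."""
        stream = "TTAGGG" * 10
        for _ in range(300):
            phi = int(rng.integers(0, 6))
            graft = int(rng.integers(0, 10))
            # flank: random prefix + graft bases of repeat ending at phase phi
            idx = 30 + phi
            flank = random_dna(rng, 12) + (stream[idx - graft : idx] if graft else "")
            inserted = stream[idx : idx + 24]
            expected = brute_force_microhomology(flank, inserted)
            got, _ = detect_microhomology(flank, inserted)
            assert got == expected, (flank, inserted)


class TestPlantedTruthPipeline:
    def test_threshold_grid_recovery(self, tmp_path):
        """Only planted events meeting every printed rule are called; junction
        positions are exact."""
        insertions = [
            PlantedInsertion("chr1", 40_000, "telomere-right", "G", 5, 3),   # called
            PlantedInsertion("chr1", 80_000, "telomere-left", "C", 3, 4),    # called
            PlantedInsertion("chr1", 120_000, "telomere-right", "G", 2, 4),  # too few pairs
            PlantedInsertion("chr1", 160_000, "telomere-right", "G", 5, 2),  # too few splits
            PlantedInsertion("chr1", 200_000, "telomere-right", "G", 5, 3, n_control_discordant=1),
            PlantedInsertion("chr2", 40_000, "telomere-right", "G", 4, 3, panel_recurrence=15),
            PlantedInsertion("chr2", 80_000, "telomere-right", "G", 4, 3, panel_recurrence=14),  # called
        ]
        cfg = SimulationConfig(seed=17, n_background_reads=500, planted_insertions=insertions)
        pair = generate_sample_pair(cfg, tmp_path)
        from tmmkit.synthetic_data import build_control_panel

        panel = build_control_panel(cfg)
        calls = call_insertions(pair.tumor_sam, pair.control_sam, panel=panel)
        called = {(c.chrom, c.position) for c in calls}
        expected = {
            (r["chrom"], r["position"])
            for _, r in pair.truth.iterrows()
            if r["expected_called"]
        }
        assert called == expected

    def test_two_sided_pair_recovered(self, tmp_path):
        insertions = [
            PlantedInsertion("chr1", 50_000, "telomere-right", "G", 4, 3, partner=1),
            PlantedInsertion("chr1", 58_000, "telomere-left", "G", 4, 3, partner=0),
        ]
        cfg = SimulationConfig(seed=23, n_background_reads=200, planted_insertions=insertions)
        pair = generate_sample_pair(cfg, tmp_path)
        calls = call_insertions(pair.tumor_sam, pair.control_sam)
        assert len(calls) == 2
        assert all(c.sidedness == "two_sided" for c in calls)

    def test_somatic_contract(self, tmp_path):
        """No call is ever emitted at a region with control support."""
        cfg = SimulationConfig(
            seed=29, n_background_reads=200,
            planted_insertions=[
                PlantedInsertion("chr1", 50_000, n_discordant_pairs=8, n_split_reads=5,
                                 n_control_discordant=1)
            ],
        )
        pair = generate_sample_pair(cfg, tmp_path)
        assert call_insertions(pair.tumor_sam, pair.control_sam) == []
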