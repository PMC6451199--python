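"""Breakpoint classification between consecutive alignment blocks."""

import pytest

from asmqc.misassembly import (
    AlignmentBlock,
    BreakpointClass,
    MisassemblyConfig,
    classify_assembly,
    classify_breakpoint,
    read_coords,
    write_coords,
)
from asmqc.simulate import BreakpointRequest, FixtureSpecError, plant_breakpoints

CFG = MisassemblyConfig()


def pair(chrom2="chr1", strand2="+", ref_gap=100, contig_gap=100):
    """Two adjacent blocks of one contig with the given geometry."""
    left = AlignmentBlock("ctg", 0, 10_000, "chr1", 50_000, 60_000, "+", 99.9)
    right = AlignmentBlock("ctg", 10_000 + contig_gap, 20_000 + contig_gap,
                           chrom2, 60_000 + ref_gap, 70_000 + ref_gap,
                           strand2, 99.9)
    return left, right


class TestClassifyBreakpoint:
    def test_different_chromosomes_translocation(self):
        assert classify_breakpoint(*pair(chrom2="chr2")) is BreakpointClass.TRANSLOCATION

    def test_opposite_strands_inversion(self):
        assert classify_breakpoint(*pair(strand2="-")) is BreakpointClass.INVERSION

    def test_large_gap_relocation(self):
        # reference gap exceeds contig gap by 20 kb
        l, r = pair(ref_gap=20_100)
        assert classify_breakpoint(l, r) is BreakpointClass.RELOCATION

    def test_medium_gap_local(self):
        l, r = pair(ref_gap=1_100)  # discordance 1,000 bp
        assert classify_breakpoint(l, r) is BreakpointClass.LOCAL

    def test_small_gap_consistent(self):
        l, r = pair(ref_gap=150)  # discordance 50 bp
        assert classify_breakpoint(l, r) is BreakpointClass.CONSISTENT

    def test_overlap_counts_like_gap(self):
        # blocks 1 kb closer on the reference than the contig implies
        l, r = pair(ref_gap=-900)
        assert classify_breakpoint(l, r) is BreakpointClass.LOCAL

    @pytest.mark.parametrize("discordance,expected", [
        (85, BreakpointClass.CONSISTENT),    # bound is strict ">85 bp"
        (86, BreakpointClass.LOCAL),
        (12_000, BreakpointClass.LOCAL),     # inclusive upper bound
        (12_001, BreakpointClass.RELOCATION),
    ])
    def test_threshold_boundaries(self, discordance, expected):
        l, r = pair(ref_gap=100 + discordance)
        assert classify_breakpoint(l, r) is expected

    def test_different_contigs_rejected(self):
        l, _ = pair()
        other = AlignmentBlock("other", 0, 100, "chr1", 0, 100, "+")
        with pytest.raises(ValueError, match="different contigs"):
            classify_breakpoint(l, other)

    def test_threshold_monotonicity(self):
        """Raising extensive_mis_size never increases the relocation count."""
        l, r = pair(ref_gap=15_100)  # discordance 15 kb
        small = classify_breakpoint(l, r, MisassemblyConfig(extensive_mis_size=12_000))
        big = classify_breakpoint(l, r, MisassemblyConfig(extensive_mis_size=20_000))
        assert small is BreakpointClass.RELOCATION and big is BreakpointClass.LOCAL


def reverse_contig(blocks):
    """Globally reverse a contig: mirror contig coordinates, flip strands."""
    clen = max(b.c_end for b in blocks)
    return [
        AlignmentBlock(b.contig, clen - b.c_end, clen - b.c_start, b.chrom,
                       b.r_start, b.r_end, "+" if b.strand == "-" else "-",
                       b.identity)
        for b in blocks
    ]


class TestClassifyAssembly:
    def test_single_block_contigs_no_breakpoints(self):
        blocks = [AlignmentBlock(f"c{i}", 0, 1_000, "chr1", i * 2_000,
                                 i * 2_000 + 1_000, "+", 99.9) for i in range(5)]
        counts, labelled = classify_assembly(blocks)
        assert sum(counts.values()) == 0 and labelled == []

    def test_collinear_chain_consistent(self):
        blocks = [AlignmentBlock("c", i * 1_010, i * 1_010 + 1_000, "chr1",
                                 i * 1_010, i * 1_010 + 1_000, "+", 99.9)
                  for i in range(4)]
        counts, _ = classify_assembly(blocks)
        assert counts["consistent"] == 3
        assert sum(counts.values()) == len(blocks) - 1

    def test_planted_breakpoints_recovered(self):
        requests = [BreakpointRequest("translocation"),
                    BreakpointRequest("translocation"),
                    BreakpointRequest("inversion")]
        blocks, truth = plant_breakpoints(requests, {"chrA": 500_000,
                                                     "chrB": 500_000})
        counts, _ = classify_assembly(blocks)
        assert counts["translocation"] == 2
        assert counts["inversion"] == 1
        assert sum(counts.values()) == len(truth)

    def test_low_identity_blocks_dropped(self):
        l, r = pair(chrom2="chr2")
        bad = AlignmentBlock("ctg", 25_000, 30_000, "chr3", 0, 5_000, "+", 95.0)
        counts, _ = classify_assembly([l, r, bad])
        assert counts["translocation"] == 1
        assert sum(counts.values()) == 1  # the 95% block never forms a junction

    @pytest.mark.parametrize("kind,ref_gap", [
        ("relocation", 20_100), ("local", 1_100),
        ("inversion", 100), ("consistent", 110),
    ])
    def test_invariant_under_contig_reversal(self, kind, ref_gap):
        strand2 = "-" if kind == "inversion" else "+"
        blocks = list(pair(strand2=strand2, ref_gap=ref_gap))
        fwd, _ = classify_assembly(blocks)
        rev, _ = classify_assembly(reverse_contig(blocks))
        assert fwd == rev
        assert fwd[kind] == 1


class TestPlanting:
    def test_boundary_requests(self):
        blocks, _ = plant_breakpoints(
            [BreakpointRequest("local", 12_000),
             BreakpointRequest("relocation", 12_001),
             BreakpointRequest("consistent", 85),
             BreakpointRequest("local", 86)],
            {"chr1": 500_000, "chr2": 500_000})
        counts, _ = classify_assembly(blocks)
        assert counts == {"translocation": 0, "relocation": 1, "inversion": 0,
                          "local": 2, "consistent": 1}

    def test_infeasible_distance_rejected(self):
        with pytest.raises(FixtureSpecError):
            plant_breakpoints([BreakpointRequest("relocation", 12_000)],
                              {"chr1": 500_000})
        with pytest.raises(FixtureSpecError):
            plant_breakpoints([BreakpointRequest("local", 85)], {"chr1": 500_000})

    def test_coords_roundtrip(self, tmp_path):
        blocks, _ = plant_breakpoints([BreakpointRequest("local", 1_000)],
                                      {"chr1": 500_000})
        path = tmp_path / "blocks.tsv"
        write_coords(blocks, path)
        assert read_coords(path) == blocks
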