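"""Region classification and codon-level effect annotation."""

import pytest
from Bio.Seq import Seq

from asmqc.discrepancies import Discrepancy, DiscrepancyType
from asmqc.effects import (
    Effect,
    Region,
    annotate_all,
    annotate_effect,
    classify_region,
    summarize_effects,
)
from asmqc.genomes import (
    BoundsError,
    ReferenceGenome,
    TranscriptModel,
    build_region_partition,
    reverse_complement,
)

#              0123456789           22
PLUS_SEQ = "ACGTACGTAC" + "ATGGCTAAATAA" + "ACGTACGTAC"
PLUS_GENE = TranscriptModel("t_plus", "chr1", "+", [(10, 22)])


@pytest.fixture()
def plus_genome():
    return ReferenceGenome({"chr1": PLUS_SEQ})


@pytest.fixture()
def plus_partition(plus_genome):
    return build_region_partition(plus_genome, [PLUS_GENE])


def mismatch(pos, ref, alt, chrom="chr1"):
    return Discrepancy(chrom, pos, ref, alt, DiscrepancyType.MISMATCH)


def deletion(pos, ref, chrom="chr1"):
    return Discrepancy(chrom, pos, ref, "", DiscrepancyType.DELETION)


def insertion(pos, alt, chrom="chr1"):
    return Discrepancy(chrom, pos, "", alt, DiscrepancyType.INSERTION)


class TestClassifyRegion:
    def test_mismatch_inside_cds(self, plus_partition):
        assert classify_region(mismatch(15, "C", "T"), plus_partition) is Region.CODING

    def test_mismatch_outside_cds(self, plus_partition):
        assert classify_region(mismatch(5, "A", "T"), plus_partition) is Region.NON_CODING

    def test_deletion_straddling_cds_boundary_any_base_rule(self, plus_partition):
        # bases 2..11 (1-based), only base 11 (first CDS base) is coding
        d = deletion(2, PLUS_SEQ[1:11])
        assert d.indel_len == 10
        assert classify_region(d, plus_partition) is Region.CODING
        # per-base oracle: shifting one base left leaves no coding overlap
        d2 = deletion(1, PLUS_SEQ[0:10])
        assert classify_region(d2, plus_partition) is Region.NON_CODING

    def test_insertion_anchor_rule(self, plus_partition):
        # anchor one base left of the CDS start is non-coding ...
        assert classify_region(insertion(10, "GGG"), plus_partition) is Region.NON_CODING
        # ... the CDS start base itself is coding
        assert classify_region(insertion(11, "GGG"), plus_partition) is Region.CODING

    def test_out_of_bounds(self, plus_partition):
        with pytest.raises(BoundsError):
            classify_region(mismatch(999, "A", "T"), plus_partition)
        with pytest.raises(BoundsError):
            classify_region(mismatch(5, "A", "T", chrom="nope"), plus_partition)


class TestAnnotateEffect:
    def test_synonymous_third_position(self, plus_genome):
        # GCT -> GCC, Ala -> Ala
        assert annotate_effect(mismatch(16, "T", "C"), PLUS_GENE,
                               plus_genome) is Effect.SYNONYMOUS

    def test_non_synonymous_first_position(self, plus_genome):
        # AAA -> GAA, Lys -> Glu
        assert annotate_effect(mismatch(17, "A", "G"), PLUS_GENE,
                               plus_genome) is Effect.NON_SYNONYMOUS

    def test_inframe_and_frameshift_deletions(self, plus_genome):
        assert annotate_effect(deletion(14, PLUS_SEQ[13:16]), PLUS_GENE,
                               plus_genome) is Effect.INFRAME_INDEL
        assert annotate_effect(deletion(14, PLUS_SEQ[13:15]), PLUS_GENE,
                               plus_genome) is Effect.FRAMESHIFT_INDEL

    def test_edge_overlapping_indel_is_frameshift(self, plus_genome):
        # 3 bp deletion with only its last base inside the CDS: coding by the
        # any-base rule but not fully inside, so conservatively frameshift
        d = deletion(9, PLUS_SEQ[8:11])
        assert annotate_effect(d, PLUS_GENE, plus_genome) is Effect.FRAMESHIFT_INDEL

    def test_non_overlapping_returns_non_coding(self, plus_genome):
        assert annotate_effect(mismatch(3, "G", "C"), PLUS_GENE,
                               plus_genome) is Effect.NON_CODING

    def test_short_cds_unresolvable_codon(self):
        genome = ReferenceGenome({"chr1": "ACGTACGTAC"})
        stub = TranscriptModel("stub", "chr1", "+", [(2, 4)])  # spliced length 2
        assert annotate_effect(mismatch(3, "G", "A"), stub, genome) is Effect.UNRESOLVED

    def test_minus_strand_matches_revcomp_oracle(self):
        """Effect on a minus-strand gene equals the call obtained by
        translating the explicitly reverse-complemented CDS."""
        orf = "ATGGCTAAGTAA"  # M A K *
        seq = "GGGGGGGGGG" + reverse_complement(orf) + "GGGGGGGGGG"
        genome = ReferenceGenome({"chr1": seq})
        gene = TranscriptModel("t_minus", "chr1", "-", [(10, 22)])
        assert gene.spliced_cds(genome) == orf

        for gpos in range(10, 22):
            ref = seq[gpos]
            for alt in "ACGT":
                if alt == ref:
                    continue
                got = annotate_effect(mismatch(gpos + 1, ref, alt), gene, genome)
                # oracle: substitute on the genome, re-extract, translate both
                mutated = seq[:gpos] + alt + seq[gpos + 1:]
                alt_orf = reverse_complement(mutated[10:22])
                same = (str(Seq(orf).translate(table=1))
                        == str(Seq(alt_orf).translate(table=1)))
                expected = Effect.SYNONYMOUS if same else Effect.NON_SYNONYMOUS
                assert got is expected, f"pos {gpos} {ref}->{alt}"


class TestSummarize:
    def test_synonymous_only_does_not_alter_protein(self, plus_genome, plus_partition):
        anns = annotate_all([mismatch(16, "T", "C")], [PLUS_GENE],
                            plus_genome, plus_partition)
        s = summarize_effects(anns)
        assert (s.affected_mrnas, s.altered_proteins) == (1, 0)
        assert (s.n_syn, s.n_nonsyn) == (1, 0)

    def test_empty_input_all_zero(self, plus_genome, plus_partition):
        s = summarize_effects([])
        assert all(v == 0 for v in s.as_dict().values())

    def test_multi_transcript_overlap_counts_once(self, plus_genome):
        other = TranscriptModel("t_other", "chr1", "+", [(10, 22)])
        partition = build_region_partition(plus_genome, [PLUS_GENE, other])
        anns = annotate_all([mismatch(17, "A", "G")], [PLUS_GENE, other],
                            plus_genome, partition)
        s = summarize_effects(anns)
        assert s.n_mismatch_cds == 1                      # counted once
        assert len(anns[0].transcript_effects) == 2       # listed per transcript
        assert s.affected_mrnas == s.altered_proteins == 2

    def test_count_partition_and_monotonicity(self, default_fixture):
        """Region counts partition the totals, and adding discrepancies never
        decreases the number of affected mRNAs."""
        from asmqc.simulate import as_models

        genome, transcripts, partition, ds = as_models(default_fixture)
        anns = annotate_all(ds, transcripts, genome, partition)
        s = summarize_effects(anns)
        n_mism = sum(not d.is_indel for d in ds)
        n_indel = sum(d.is_indel for d in ds)
        assert s.n_mismatch_cds + s.n_mismatch_nc == n_mism
        assert s.n_indel_cds + s.n_indel_nc == n_indel
        prev = summarize_effects(anns[:100]).affected_mrnas
        for cut in (200, 400, len(anns)):
            cur = summarize_effects(anns[:cut]).affected_mrnas
            assert cur >= prev
            prev = cur
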