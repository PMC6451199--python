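"""The synthetic fixture generator: determinism, validity, ground truth."""

import hashlib

import numpy as np
import pytest
from Bio.Seq import Seq

from asmqc.genomes import read_fasta, read_gff3
from asmqc.simulate import (
    FixtureSpec,
    FixtureSpecError,
    generate_fixture,
)

SMALL = FixtureSpec(seed=7, n_chromosomes=1, chrom_length=120_000, n_genes=30)


def sha(path):
    return hashlib.sha256(path.read_bytes()).hexdigest()


class TestDeterminism:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        a = generate_fixture(SMALL, tmp_path / "a")
        b = generate_fixture(SMALL, tmp_path / "b")
        for name in a.paths:
            assert sha(a.paths[name]) == sha(b.paths[name]), name

    def test_different_seed_differs(self, tmp_path):
        a = generate_fixture(SMALL, tmp_path / "a")
        c = generate_fixture(FixtureSpec(seed=8, n_chromosomes=1,
                                         chrom_length=120_000, n_genes=30),
                             tmp_path / "c")
        assert sha(a.paths["fasta"]) != sha(c.paths["fasta"])


class TestGenomeComposition:
    def test_background_gc_within_sampling_bound(self):
        """GC 0.20 over 100 kb of gene-free background lands within +-2
        percentage points (binomial sd at n=100,000 is ~0.13 points)."""
        spec = FixtureSpec(seed=3, n_chromosomes=1, chrom_length=100_000,
                           n_genes=0, repeat_fraction=0.0, gc_fraction=0.20,
                           mismatch_rate_cds=0, mismatch_rate_nc=0,
                           indel_rate_cds=0, indel_rate_nc=0)
        fx = generate_fixture(spec)
        seq = fx.sequences["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.20) < 0.02

    def test_genes_are_valid_orfs(self, default_fixture):
        """Planted ORFs start with ATG, end with a stop, have length a
        multiple of 3 and no internal stop on the coding strand."""
        for gene in default_fixture.genes:
            orf = gene.orf
            assert len(orf) % 3 == 0
            assert orf.startswith("ATG")
            protein = str(Seq(orf).translate(table=1))
            assert protein.endswith("*")
            assert "*" not in protein[:-1]

    def test_orf_matches_emitted_sequence(self, default_fixture):
        """The spliced, strand-corrected genomic CDS equals the planted ORF."""
        genome = read_fasta(default_fixture.paths["fasta"])
        models = {m.transcript_id: m for m in read_gff3(default_fixture.paths["gff3"])}
        for gene in default_fixture.genes[::23]:
            assert models[gene.tid].spliced_cds(genome) == gene.orf

    def test_repeats_disjoint_from_cds(self, default_fixture):
        for chrom, ivs in default_fixture.repeat_intervals.items():
            cds = [seg for g in default_fixture.genes if g.chrom == chrom
                   for seg in g.segments]
            for rs, re_ in ivs:
                assert not any(s < re_ and rs < e for s, e in cds)

    def test_infeasible_spec_rejected(self):
        with pytest.raises(FixtureSpecError):
            generate_fixture(FixtureSpec(seed=1, n_chromosomes=1,
                                         chrom_length=20_000, n_genes=30))


class TestPlantedVariants:
    def test_counts_roughly_match_rates(self, default_fixture):
        # Poisson expectation sanity: within 5 sd of the planted rates
        fx = default_fixture
        spec = fx.spec
        l_cds = sum(e - s for g in fx.genes for s, e in g.segments)
        l_nc = sum(len(s) for s in fx.sequences.values()) - l_cds
        n_nc_indel = sum(1 for v in fx.truth.variants
                         if v.dtype != "mismatch" and v.region == "non_coding")
        lam = spec.indel_rate_nc * l_nc
        assert abs(n_nc_indel - lam) < 5 * np.sqrt(lam)

    def test_min_two_bp_separation(self, default_fixture):
        spans = {}
        for v in default_fixture.truth.variants:
            start = v.pos - 1
            end = start + (len(v.ref) if v.dtype == "deletion" else 1)
            spans.setdefault(v.chrom, []).append((start, end))
        for chrom, ivs in spans.items():
            ivs.sort()
            for (s0, e0), (s1, e1) in zip(ivs, ivs[1:]):
                assert s1 - e0 >= 2, (chrom, s0, s1)

    def test_ref_alleles_match_reference(self, default_fixture):
        for v in default_fixture.truth.variants:
            seq = default_fixture.sequences[v.chrom]
            if v.dtype == "mismatch":
                assert seq[v.pos - 1] == v.ref != v.alt
            elif v.dtype == "deletion":
                assert seq[v.pos - 1:v.pos - 1 + len(v.ref)] == v.ref

    def test_every_variant_has_one_label(self, default_fixture):
        for v in default_fixture.truth.variants:
            assert v.region in ("coding", "non_coding")
            assert v.effect in ("synonymous", "non_synonymous", "inframe_indel",
                                "frameshift_indel", "non_coding")
            assert (v.region == "coding") == (v.effect != "non_coding")

    def test_fold_ratio_recovered_within_poisson_bound(self):
        """A single fixture at low coding indel rate recovers the planted
        20x ratio within a 3-sigma delta-method Poisson interval (on the
        log scale, sd ~ sqrt(1/lambda_cds + 1/lambda_nc))."""
        from asmqc.effects import annotate_all, summarize_effects
        from asmqc.simulate import as_models
        from asmqc.stats import RegionCounts, fold_likelihood

        spec = FixtureSpec(seed=11, mismatch_rate_cds=0, mismatch_rate_nc=0,
                           indel_rate_cds=1e-5, indel_rate_nc=2e-4)
        fx = generate_fixture(spec)
        genome, transcripts, partition, ds = as_models(fx)
        s = summarize_effects(annotate_all(ds, transcripts, genome, partition))
        fold = fold_likelihood(RegionCounts(s.n_indel_cds, s.n_indel_nc,
                                            partition.l_cds, partition.l_nc))
        lam_cds = spec.indel_rate_cds * partition.l_cds
        lam_nc = spec.indel_rate_nc * partition.l_nc
        sigma = np.sqrt(1 / lam_cds + 1 / lam_nc)
        assert abs(np.log(fold / spec.rho_star)) < 3 * sigma


class TestFormatValidity:
    def test_outputs_parse_with_own_readers(self, default_fixture):
        """Round trip: every emitted file parses cleanly."""
        from asmqc.discrepancies import read_vcf_discrepancies
        from asmqc.genomes import read_bed_intervals
        from asmqc.misassembly import read_coords
        from asmqc.windows import read_bedgraph

        p = default_fixture.paths
        genome = read_fasta(p["fasta"])
        assert genome.total_length == sum(
            len(s) for s in default_fixture.sequences.values())
        assert len(read_gff3(p["gff3"], genome)) == len(default_fixture.genes)
        assert len(read_vcf_discrepancies(p["vcf"], genome)) == \
            len(default_fixture.truth.variants)
        assert read_bed_intervals(p["repeats"]) == {
            c: ivs for c, ivs in default_fixture.repeat_intervals.items() if ivs}
        cov = read_bedgraph(p["bedgraph"], genome.lengths)
        for chrom, depth in default_fixture.coverage.items():
            assert np.array_equal(cov[chrom], depth)
        assert read_coords(p["coords"]) == default_fixture.blocks
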