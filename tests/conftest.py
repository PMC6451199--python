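import pytest

from asmqc.simulate import FixtureSpec, generate_fixture


@pytest.fixture(scope="session")
def default_fixture(tmp_path_factory):
    """The default 1 Mb fixture (two 500 kb chromosomes, ~50% coding,
    planted indel density ratio 20), written to disk once per session."""
    outdir = tmp_path_factory.mktemp("fixture_seed1")
    return generate_fixture(FixtureSpec(seed=1), outdir=outdir)


@pytest.fixture()
def tiny_gff3(tmp_path):
    """Writer for small hand-built GFF3 files: rows of (chrom, type, start,
    end, strand, phase, attrs) in 1-based inclusive coordinates."""

    def write(rows):
        path = tmp_path / "models.gff3"
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for chrom, ftype, start, end, strand, phase, attrs in rows:
                fh.write(f"{chrom}\tt\t{ftype}\t{start}\t{end}\t.\t{strand}\t"
                         f"{phase}\t{attrs}\n")
        return path

    return write


@pytest.fixture()
def tiny_vcf(tmp_path):
    """Writer for small hand-built VCF files: records of (chrom, pos, ref, alt)."""

    def write(records, contigs=(("chr1", 100000),)):
        path = tmp_path / "vars.vcf"
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for name, length in contigs:
                fh.write(f"##contig=<ID={name},length={length}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for chrom, pos, ref, alt in records:
                fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")
        return path

    return write
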