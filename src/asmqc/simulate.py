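"""Seeded synthetic fixtures: genomes, gene models, repeats, coverage,
discrepancies with ground-truth labels, and alignment blocks with planted
breakpoints.

The generator emulates the statistical structure of a polished long-read
assembly evaluated against a small eukaryotic reference: an AT-rich genome
whose coding regions are GC-richer than the non-coding background (the
*P. falciparum*-like regime where AT-rich non-coding sequence accumulates
far more indels than coding sequence), valid ORF gene models (start codon,
stop codon, spliced length a multiple of 3, no internal stops), tandem
low-complexity repeats in intergenic space, short-read coverage with
zero-depth gaps, and mismatches/indels injected at different rates in
coding vs non-coding space.  Every injected event carries a ground-truth
region and effect label computed from the construction itself, so the
annotation machinery can be tested against planted truth rather than
against its own output.

All randomness flows through one ``numpy.random.Generator`` seeded from a
single integer: the same seed yields byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Seq import Seq

from .genomes import reverse_complement
from .misassembly import AlignmentBlock, MisassemblyConfig, write_coords

BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_COMPLEMENT_BASE = {"A": "T", "C": "G", "G": "C", "T": "A"}


class FixtureSpecError(ValueError):
    """The requested fixture is infeasible or self-contradictory."""


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic fixture.

    Defaults describe a desk-scale caricature of an AT-rich haploid genome:
    1 Mb over two chromosomes, ~50% coding, non-coding GC 0.15 vs coding
    GC ~0.25, 10% repeats, and indel rates 20x higher in non-coding than
    coding space (the planted density ratio rho* = indel_rate_nc /
    indel_rate_cds = 20).  Rates are events per bp.
    """

    seed: int = 1
    n_chromosomes: int = 2
    chrom_length: int = 500_000
    gc_fraction: float = 0.15          # non-coding background GC
    gc_coding: float = 0.25            # target GC of coding sequence
    n_genes: int = 300
    cds_length_range: tuple[int, int] = (900, 2400)   # multiples of 3
    two_exon_fraction: float = 0.3
    repeat_fraction: float = 0.10
    mismatch_rate_cds: float = 3e-4
    mismatch_rate_nc: float = 5e-4
    indel_rate_cds: float = 2e-5
    indel_rate_nc: float = 4e-4
    indel_len_max: int = 85
    indel_len_power: float = 3.0       # P(len) ~ len**-power over 1..indel_len_max
    coverage_mean: int = 50
    n_coverage_gaps: int = 4           # zero-depth intervals per chromosome
    min_intergenic: int = 200

    def __post_init__(self) -> None:
        for name in ("mismatch_rate_cds", "mismatch_rate_nc",
                     "indel_rate_cds", "indel_rate_nc"):
            if getattr(self, name) < 0:
                raise FixtureSpecError(f"{name} must be >= 0")
        if not (0 < self.gc_fraction < 1 and 0 < self.gc_coding < 1):
            raise FixtureSpecError("GC fractions must be in (0, 1)")
        if not (0 <= self.repeat_fraction < 1):
            raise FixtureSpecError("repeat_fraction must be in [0, 1)")
        lo, hi = self.cds_length_range
        if lo % 3 or hi % 3 or not (9 <= lo <= hi):
            raise FixtureSpecError("cds_length_range must be multiples of 3, >= 9")

    @property
    def rho_star(self) -> float:
        """Planted non-coding vs coding indel density ratio."""
        if self.indel_rate_cds == 0:
            return float("inf")
        return self.indel_rate_nc / self.indel_rate_cds


@dataclass
class PlantedVariant:
    """One injected discrepancy with its ground-truth labels."""

    chrom: str
    pos: int                # 1-based: mismatch base / insertion anchor / first deleted
    dtype: str              # mismatch | insertion | deletion
    ref: str                # normalized (empty for insertion)
    alt: str                # normalized (empty for deletion)
    region: str             # coding | non_coding
    effect: str             # synonymous | non_synonymous | inframe_indel |
                            # frameshift_indel | non_coding
    transcript: str = ""    # owning transcript for coding events


@dataclass
class PlantedGene:
    tid: str
    chrom: str
    strand: str
    segments: list[tuple[int, int]]  # 0-based half-open, genomic order
    orf: str                         # spliced CDS in translation order


@dataclass
class GroundTruth:
    """Planted variants, breakpoints, and the expected density ratio."""

    variants: list[PlantedVariant]
    breakpoint_classes: list[dict]
    rho_star: float

    def summary(self) -> dict[str, int]:
        """Expected annotation-summary counts implied by the planted labels."""
        s = {
            "mismatches_in_cds": 0, "mismatches_outside_cds": 0,
            "indels_in_cds": 0, "indels_outside_cds": 0,
            "non_synonymous_mutations": 0, "synonymous_mutations": 0,
            "unresolved_coding_mismatches": 0, "inframe_indels": 0,
        }
        affected, altered = set(), set()
        for v in self.variants:
            coding = v.region == "coding"
            if v.dtype == "mismatch":
                s["mismatches_in_cds" if coding else "mismatches_outside_cds"] += 1
            else:
                s["indels_in_cds" if coding else "indels_outside_cds"] += 1
            if v.effect == "non_synonymous":
                s["non_synonymous_mutations"] += 1
            elif v.effect == "synonymous":
                s["synonymous_mutations"] += 1
            elif v.effect == "inframe_indel":
                s["inframe_indels"] += 1
            if coding and v.transcript:
                affected.add(v.transcript)
                if v.effect in ("non_synonymous", "inframe_indel", "frameshift_indel"):
                    altered.add(v.transcript)
        s["affected_mrnas"] = len(affected)
        s["altered_proteins"] = len(altered)
        return s

    def to_json(self, path) -> None:
        payload = {
            "rho_star": self.rho_star,
            "summary": self.summary(),
            "variants": [asdict(v) for v in self.variants],
            "breakpoints": self.breakpoint_classes,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


@dataclass
class Fixture:
    """In-memory fixture plus (optionally) the paths it was written to."""

    spec: FixtureSpec
    sequences: dict[str, str]
    genes: list[PlantedGene]
    repeat_intervals: dict[str, list[tuple[int, int]]]
    coverage: dict[str, np.ndarray]
    truth: GroundTruth
    blocks: list[AlignmentBlock]
    paths: dict[str, Path] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Sequence and gene construction
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p)


def _random_orf(rng: np.random.Generator, length: int, gc: float) -> str:
    """Random valid ORF: ATG + non-stop codons + one stop codon."""
    n_mid = length // 3 - 2
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codons = []
    while len(codons) < n_mid:
        draw = BASES[rng.choice(4, size=(n_mid - len(codons) + 8, 3), p=p)]
        for row in draw:
            codon = "".join(row)
            if codon not in _STOPS:
                codons.append(codon)
                if len(codons) == n_mid:
                    break
    stop = ["TAA", "TAG", "TGA"][rng.integers(3)]
    return "ATG" + "".join(codons) + stop


def _plan_gene_layout(
    rng: np.random.Generator, spec: FixtureSpec, n_genes: int
) -> list[tuple[int, int, int]]:
    """Plan (start, orf_len, intron_len) footprints along one chromosome."""
    plans = []
    for _ in range(n_genes):
        lo, hi = spec.cds_length_range
        orf_len = 3 * int(rng.integers(lo // 3, hi // 3 + 1))
        intron = int(rng.integers(60, 200)) if rng.random() < spec.two_exon_fraction else 0
        plans.append((orf_len, intron))
    footprint = sum(o + i for o, i in plans)
    slack = spec.chrom_length - footprint - spec.min_intergenic * (n_genes + 1)
    if slack < 0:
        raise FixtureSpecError(
            f"genes do not fit: need {footprint} bp + gaps on a "
            f"{spec.chrom_length} bp chromosome"
        )
    # distribute the slack over the n_genes + 1 gaps
    cuts = np.sort(rng.integers(0, slack + 1, size=n_genes))
    gaps = np.diff(np.concatenate(([0], cuts, [slack]))) + spec.min_intergenic
    out, cursor = [], 0
    for (orf_len, intron), gap in zip(plans, gaps[:-1]):
        cursor += int(gap)
        out.append((cursor, orf_len, intron))
        cursor += orf_len + intron
    return out


def _build_chromosome(
    rng: np.random.Generator, spec: FixtureSpec, chrom: str, n_genes: int,
    gene_counter: int,
) -> tuple[str, list[PlantedGene], list[tuple[int, int]]]:
    """One chromosome: AT-rich background, planted ORFs, tandem repeats."""
    codes = _random_sequence(rng, spec.chrom_length, spec.gc_fraction)
    seq = BASES[codes]

    genes: list[PlantedGene] = []
    for start, orf_len, intron_len in _plan_gene_layout(rng, spec, n_genes):
        tid = f"mrna{gene_counter + len(genes):05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        orf = _random_orf(rng, orf_len, spec.gc_coding)
        genomic_cds = orf if strand == "+" else reverse_complement(orf)
        if intron_len:
            k = 3 * int(rng.integers(1, orf_len // 3))  # split between codons
            seg_seqs = [genomic_cds[:k], genomic_cds[k:]]
            intron = "".join(BASES[_random_sequence(rng, intron_len, spec.gc_fraction)])
            pieces, segments, cursor = [], [], start
            for i, part in enumerate(seg_seqs):
                pieces.append(part)
                segments.append((cursor, cursor + len(part)))
                cursor += len(part)
                if i == 0:
                    pieces.append(intron)
                    cursor += intron_len
            gene_seq = "".join(pieces)
        else:
            segments = [(start, start + orf_len)]
            gene_seq = genomic_cds
        seq[start:start + len(gene_seq)] = list(gene_seq)
        genes.append(PlantedGene(tid, chrom, strand, segments, orf))

    # tandem low-complexity repeats in intergenic space
    repeat_ivs: list[tuple[int, int]] = []
    target = int(spec.repeat_fraction * spec.chrom_length)
    gene_spans = [(g.segments[0][0], g.segments[-1][1]) for g in genes]
    occupied = sorted(gene_spans)
    gaps = []
    prev = 0
    for s, e in occupied:
        if s - prev >= 400:
            gaps.append((prev, s))
        prev = e
    if spec.chrom_length - prev >= 400:
        gaps.append((prev, spec.chrom_length))
    placed = 0
    order = rng.permutation(len(gaps))
    for gi in order:
        if placed >= target:
            break
        gs, ge = gaps[gi]
        room = ge - gs - 100
        if room < 100:
            continue
        rlen = int(min(room, rng.integers(100, 400), target - placed + 100))
        rstart = gs + 50 + int(rng.integers(0, room - rlen + 1))
        unit = "".join(BASES[_random_sequence(rng, int(rng.integers(3, 8)),
                                              spec.gc_fraction)])
        repeat = (unit * (rlen // len(unit) + 1))[:rlen]
        seq[rstart:rstart + rlen] = list(repeat)
        repeat_ivs.append((rstart, rstart + rlen))
        placed += rlen
    repeat_ivs.sort()
    return "".join(seq), genes, repeat_ivs


# ---------------------------------------------------------------------------
# Discrepancy injection with truth labels
# ---------------------------------------------------------------------------

def _orf_index(gene: PlantedGene, pos: int) -> int:
    """Map a genomic position inside the gene's CDS to its ORF index."""
    offset = 0
    for s, e in gene.segments:
        if s <= pos < e:
            gidx = offset + (pos - s)
            if gene.strand == "-":
                return len(gene.orf) - 1 - gidx
            return gidx
        offset += e - s
    raise ValueError(f"{gene.tid}: position {pos} not in CDS")


def _mismatch_effect(gene: PlantedGene, pos: int, alt_base: str) -> str:
    """Synonymous/non-synonymous call computed directly from the planted ORF."""
    idx = _orf_index(gene, pos)
    alt = alt_base if gene.strand == "+" else _COMPLEMENT_BASE[alt_base]
    k = idx // 3
    ref_codon = gene.orf[3 * k:3 * k + 3]
    alt_codon = ref_codon[:idx % 3] + alt + ref_codon[idx % 3 + 1:]
    same = str(Seq(ref_codon).translate(table=1)) == str(Seq(alt_codon).translate(table=1))
    return "synonymous" if same else "non_synonymous"


class _Blocker:
    """Tracks planted spans per chromosome, enforcing >= 2 bp separation."""

    def __init__(self, lengths: dict[str, int]) -> None:
        self.blocked = {c: np.zeros(n, dtype=bool) for c, n in lengths.items()}

    def try_claim(self, chrom: str, start: int, end: int) -> bool:
        lo, hi = max(0, start - 2), min(len(self.blocked[chrom]), end + 2)
        if self.blocked[chrom][lo:hi].any():
            return False
        self.blocked[chrom][lo:hi] = True
        return True


def _sample_indel_len(rng: np.random.Generator, spec: FixtureSpec) -> int:
    lens = np.arange(1, spec.indel_len_max + 1)
    w = lens.astype(float) ** -spec.indel_len_power
    return int(rng.choice(lens, p=w / w.sum()))


def _inject_variants(
    rng: np.random.Generator,
    spec: FixtureSpec,
    sequences: dict[str, str],
    genes: list[PlantedGene],
) -> list[PlantedVariant]:
    lengths = {c: len(s) for c, s in sequences.items()}
    blocker = _Blocker(lengths)
    variants: list[PlantedVariant] = []

    genes_by_chrom: dict[str, list[PlantedGene]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)

    for chrom, seq in sequences.items():
        length = lengths[chrom]
        coding = np.zeros(length, dtype=bool)
        owner = np.full(length, -1, dtype=np.int64)
        chrom_genes = genes_by_chrom.get(chrom, [])
        for i, g in enumerate(chrom_genes):
            for s, e in g.segments:
                coding[s:e] = True
                owner[s:e] = i
        coding_pos = np.flatnonzero(coding)
        # keep 1-based anchors valid and noncoding events clear of CDS edges
        nc = ~coding
        nc[0] = False
        noncoding_pos = np.flatnonzero(nc)
        l_cds, l_nc = len(coding_pos), length - len(coding_pos)

        def plant_mismatches(n: int, pool: np.ndarray, is_coding: bool) -> None:
            attempts = 0
            planted = 0
            while planted < n and attempts < 20 * n + 100:
                attempts += 1
                p = int(pool[rng.integers(len(pool))])
                if not blocker.try_claim(chrom, p, p + 1):
                    continue
                ref = seq[p]
                if ref == "N":
                    continue
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                if is_coding:
                    g = chrom_genes[owner[p]]
                    effect = _mismatch_effect(g, p, alt)
                    variants.append(PlantedVariant(
                        chrom, p + 1, "mismatch", ref, alt, "coding", effect, g.tid))
                else:
                    variants.append(PlantedVariant(
                        chrom, p + 1, "mismatch", ref, alt, "non_coding", "non_coding"))
                planted += 1

        def plant_indels(n: int, is_coding: bool) -> None:
            attempts = 0
            planted = 0
            while planted < n and attempts < 50 * n + 200:
                attempts += 1
                ilen = _sample_indel_len(rng, spec)
                deletion = rng.random() < 0.5
                if is_coding:
                    g = chrom_genes[rng.integers(len(chrom_genes))]
                    s, e = g.segments[rng.integers(len(g.segments))]
                    if deletion:
                        if e - s < ilen + 2:
                            continue
                        p = int(rng.integers(s + 1, e - ilen + 1))
                        span = (p, p + ilen)
                    else:
                        p = int(rng.integers(s + 1, e))
                        span = (p, p + 1)
                else:
                    p = int(noncoding_pos[rng.integers(len(noncoding_pos))])
                    if deletion:
                        span = (p, p + ilen)
                        if span[1] > length or coding[span[0]:span[1]].any():
                            continue
                    else:
                        span = (p, p + 1)
                if not blocker.try_claim(chrom, *span):
                    continue
                if deletion:
                    ref, alt, dtype = seq[p:p + ilen], "", "deletion"
                else:
                    ins = "".join(BASES[_random_sequence(
                        rng, ilen, spec.gc_coding if is_coding else spec.gc_fraction)])
                    ref, alt, dtype = "", ins, "insertion"
                if is_coding:
                    effect = "inframe_indel" if ilen % 3 == 0 else "frameshift_indel"
                    variants.append(PlantedVariant(
                        chrom, p + 1, dtype, ref, alt, "coding", effect, g.tid))
                else:
                    variants.append(PlantedVariant(
                        chrom, p + 1, dtype, ref, alt, "non_coding", "non_coding"))
                planted += 1

        if l_cds:
            plant_mismatches(rng.poisson(spec.mismatch_rate_cds * l_cds),
                             coding_pos, True)
            plant_indels(rng.poisson(spec.indel_rate_cds * l_cds), True)
        if l_nc:
            plant_mismatches(rng.poisson(spec.mismatch_rate_nc * l_nc),
                             noncoding_pos, False)
            plant_indels(rng.poisson(spec.indel_rate_nc * l_nc), False)

    variants.sort(key=lambda v: (v.chrom, v.pos))
    return variants


# ---------------------------------------------------------------------------
# Breakpoint planting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BreakpointRequest:
    """One engineered contig junction of the given class; ``distance`` is
    the reference discordance in bp for relocation/local/consistent."""

    cls: str
    distance: int | None = None


DEFAULT_BREAKPOINTS = (
    BreakpointRequest("translocation"),
    BreakpointRequest("relocation", 20_000),
    BreakpointRequest("inversion"),
    BreakpointRequest("local", 1_000),
    BreakpointRequest("local", 5_000),
    BreakpointRequest("consistent", 10),
)


def plant_breakpoints(
    requests: Sequence[BreakpointRequest],
    chrom_lengths: dict[str, int],
    cfg: MisassemblyConfig = MisassemblyConfig(),
    rng: np.random.Generator | None = None,
) -> tuple[list[AlignmentBlock], list[dict]]:
    """Emit two-block contigs whose junctions classify exactly as requested.

    A requested distance that violates the class thresholds (e.g. a
    relocation at 12,000 bp, which is local by the inclusive upper bound)
    raises :class:`FixtureSpecError`.
    """
    rng = rng or np.random.default_rng(0)
    chroms = list(chrom_lengths)
    block_len = 20_000
    contig_gap = 100
    blocks: list[AlignmentBlock] = []
    truth: list[dict] = []
    for i, req in enumerate(requests):
        contig = f"ctg{i:03d}"
        d = req.distance
        if req.cls == "relocation":
            if d is None:
                d = cfg.extensive_mis_size + 8_000
            if d <= cfg.extensive_mis_size:
                raise FixtureSpecError(
                    f"relocation needs distance > {cfg.extensive_mis_size}, got {d}")
        elif req.cls == "local":
            if d is None:
                d = (cfg.local_min + cfg.extensive_mis_size) // 2
            if not (cfg.local_min < d <= cfg.extensive_mis_size):
                raise FixtureSpecError(
                    f"local needs {cfg.local_min} < distance <= "
                    f"{cfg.extensive_mis_size}, got {d}")
        elif req.cls == "consistent":
            if d is None:
                d = 0
            if d > cfg.local_min:
                raise FixtureSpecError(
                    f"consistent needs distance <= {cfg.local_min}, got {d}")
        elif req.cls == "translocation":
            if len(chroms) < 2:
                raise FixtureSpecError("translocation needs >= 2 chromosomes")
        elif req.cls != "inversion":
            raise FixtureSpecError(f"unknown breakpoint class {req.cls!r}")

        chrom = chroms[i % len(chroms)]
        span_needed = 2 * block_len + (d or 0) + contig_gap + 30_000
        if chrom_lengths[chrom] < span_needed and req.cls != "translocation":
            raise FixtureSpecError(
                f"chromosome {chrom} too short for a {req.cls} fixture contig")
        r1 = int(rng.integers(0, max(1, chrom_lengths[chrom] - span_needed + 1)))

        left = AlignmentBlock(contig, 0, block_len, chrom,
                              r1, r1 + block_len, "+", 99.9)
        c2 = block_len + contig_gap
        if req.cls == "translocation":
            other = chroms[(i + 1) % len(chroms)]
            r2 = int(rng.integers(0, chrom_lengths[other] - block_len))
            right = AlignmentBlock(contig, c2, c2 + block_len, other,
                                   r2, r2 + block_len, "+", 99.9)
        elif req.cls == "inversion":
            r2 = r1 + block_len + contig_gap + 2_000
            right = AlignmentBlock(contig, c2, c2 + block_len, chrom,
                                   r2, r2 + block_len, "-", 99.9)
        else:
            # same chromosome/strand, reference gap = contig gap + distance
            r2 = r1 + block_len + contig_gap + d
            right = AlignmentBlock(contig, c2, c2 + block_len, chrom,
                                   r2, r2 + block_len, "+", 99.9)
        blocks.extend([left, right])
        truth.append({"contig": contig, "class": req.cls, "distance": d})
    return blocks, truth


# ---------------------------------------------------------------------------
# File writers (fixture exporters)
# ---------------------------------------------------------------------------

def _write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _segment_phases(gene: PlantedGene) -> list[int]:
    """GFF3 phase column per CDS segment, in genomic order."""
    order = gene.segments if gene.strand == "+" else gene.segments[::-1]
    phases, consumed = [], 0
    for s, e in order:
        phases.append((3 - consumed % 3) % 3)
        consumed += e - s
    return phases if gene.strand == "+" else phases[::-1]


def _write_gff3(genes: Sequence[PlantedGene], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            gid = g.tid.replace("mrna", "gene")
            start = g.segments[0][0] + 1
            end = g.segments[-1][1]
            fh.write(f"{g.chrom}\tasmqc_sim\tgene\t{start}\t{end}\t.\t{g.strand}\t.\t"
                     f"ID={gid}\n")
            fh.write(f"{g.chrom}\tasmqc_sim\tmRNA\t{start}\t{end}\t.\t{g.strand}\t.\t"
                     f"ID={g.tid};Parent={gid}\n")
            for (s, e), phase in zip(g.segments, _segment_phases(g)):
                fh.write(f"{g.chrom}\tasmqc_sim\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t"
                         f"{phase}\tID=cds-{g.tid};Parent={g.tid}\n")


def _write_vcf(variants: Sequence[PlantedVariant], sequences: dict[str, str],
               path) -> None:
    """Anchored VCF 4.2 representation of the planted discrepancies."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=asmqc-simulate\n")
        for name, seq in sequences.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            seq = sequences[v.chrom]
            if v.dtype == "mismatch":
                pos, ref, alt = v.pos, v.ref, v.alt
            elif v.dtype == "insertion":
                anchor = seq[v.pos - 1]
                pos, ref, alt = v.pos, anchor, anchor + v.alt
            else:  # deletion: anchor base left of the first deleted base
                anchor = seq[v.pos - 2]
                pos, ref, alt = v.pos - 1, anchor + v.ref, anchor
            fh.write(f"{v.chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")


def _simulate_coverage(
    rng: np.random.Generator, spec: FixtureSpec, sequences: dict[str, str]
) -> dict[str, np.ndarray]:
    """Piecewise-constant depth with a few planted zero-coverage gaps."""
    coverage: dict[str, np.ndarray] = {}
    for chrom, seq in sequences.items():
        length = len(seq)
        depth = np.zeros(length, dtype=np.int64)
        for start in range(0, length, 1_000):
            depth[start:start + 1_000] = rng.poisson(spec.coverage_mean)
        for _ in range(spec.n_coverage_gaps):
            glen = int(rng.integers(500, 3_000))
            gstart = int(rng.integers(0, max(1, length - glen)))
            depth[gstart:gstart + glen] = 0
        coverage[chrom] = depth
    return coverage


def _write_bedgraph(coverage: dict[str, np.ndarray], path) -> None:
    with open(path, "w") as fh:
        for chrom, depth in coverage.items():
            boundaries = np.flatnonzero(np.diff(depth)) + 1
            edges = np.concatenate(([0], boundaries, [len(depth)]))
            for s, e in zip(edges[:-1], edges[1:]):
                fh.write(f"{chrom}\t{s}\t{e}\t{int(depth[s])}\n")


def _write_repeats_bed(repeats: dict[str, list[tuple[int, int]]], path) -> None:
    with open(path, "w") as fh:
        for chrom, ivs in repeats.items():
            for s, e in ivs:
                fh.write(f"{chrom}\t{s}\t{e}\trepeat\n")


def as_models(fixture: "Fixture"):
    """Convert an in-memory fixture to analysis-layer objects without file
    round-trips: (genome, transcripts, partition, discrepancies)."""
    from .discrepancies import Discrepancy, DiscrepancyType
    from .genomes import ReferenceGenome, TranscriptModel, build_region_partition

    genome = ReferenceGenome(dict(fixture.sequences))
    transcripts = [
        TranscriptModel(g.tid, g.chrom, g.strand, list(g.segments), phase=0)
        for g in fixture.genes
    ]
    partition = build_region_partition(genome, transcripts)
    discrepancies = [
        Discrepancy(v.chrom, v.pos, v.ref, v.alt, DiscrepancyType(v.dtype))
        for v in fixture.truth.variants
    ]
    return genome, transcripts, partition, discrepancies


# ---------------------------------------------------------------------------
# Top-level generator
# ---------------------------------------------------------------------------

def generate_fixture(
    spec: FixtureSpec = FixtureSpec(),
    outdir: str | Path | None = None,
    breakpoint_requests: Sequence[BreakpointRequest] = DEFAULT_BREAKPOINTS,
) -> Fixture:
    """Generate a complete fixture; optionally write it to ``outdir``.

    Writes (when ``outdir`` is given): ref.fa, genes.gff3, repeats.bed,
    coverage.bedgraph, variants.vcf, blocks.tsv, truth.json.  The same seed
    produces byte-identical files.
    """
    rng = np.random.default_rng(spec.seed)
    sequences: dict[str, str] = {}
    genes: list[PlantedGene] = []
    repeats: dict[str, list[tuple[int, int]]] = {}

    per_chrom = [spec.n_genes // spec.n_chromosomes] * spec.n_chromosomes
    for i in range(spec.n_genes % spec.n_chromosomes):
        per_chrom[i] += 1
    for ci in range(spec.n_chromosomes):
        chrom = f"chr{ci + 1}"
        seq, chrom_genes, repeat_ivs = _build_chromosome(
            rng, spec, chrom, per_chrom[ci], gene_counter=len(genes))
        sequences[chrom] = seq
        genes.extend(chrom_genes)
        repeats[chrom] = repeat_ivs

    variants = _inject_variants(rng, spec, sequences, genes)
    coverage = _simulate_coverage(rng, spec, sequences)
    chrom_lengths = {c: len(s) for c, s in sequences.items()}
    requests = list(breakpoint_requests)
    if breakpoint_requests is DEFAULT_BREAKPOINTS and spec.n_chromosomes < 2:
        # a translocation fixture needs two chromosomes; explicit requests
        # on a one-chromosome genome still raise
        requests = [r for r in requests if r.cls != "translocation"]
    blocks, bp_truth = plant_breakpoints(requests, chrom_lengths, rng=rng)
    truth = GroundTruth(variants, bp_truth, spec.rho_star)

    fixture = Fixture(spec, sequences, genes, repeats, coverage, truth, blocks)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "ref.fa",
            "gff3": outdir / "genes.gff3",
            "repeats": outdir / "repeats.bed",
            "bedgraph": outdir / "coverage.bedgraph",
            "vcf": outdir / "variants.vcf",
            "coords": outdir / "blocks.tsv",
            "truth": outdir / "truth.json",
        }
        _write_fasta(sequences, paths["fasta"])
        _write_gff3(genes, paths["gff3"])
        _write_repeats_bed(repeats, paths["repeats"])
        _write_bedgraph(coverage, paths["bedgraph"])
        _write_vcf(variants, sequences, paths["vcf"])
        write_coords(blocks, paths["coords"])
        truth.to_json(paths["truth"])
        fixture.paths = paths
    return fixture
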