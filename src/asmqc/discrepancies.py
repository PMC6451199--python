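"""Assembly-vs-reference discrepancy lists: parsing, normalization, size classes.

A *discrepancy* is one difference between a polished assembly and the
reference it is evaluated against: a single-base mismatch, an insertion, or
a deletion.  Upstream aligners report these either as VCF records (anchored
representation, shared leading base) or as Quast-style SNP rows.  Both are
normalized here to a common form:

* mismatch — one ref base, one different alt base;
* insertion — empty ref allele, ``ref_pos`` is the 1-based *anchor* base
  immediately left of the inserted sequence;
* deletion — empty alt allele, ``ref_pos`` is the first deleted base.

Size classes follow the Quast convention adopted for assembly evaluation:
small indels are <=5 bp, large indels >5 and <=85 bp, and anything longer
is tracked as structural (excluded from the small/large tallies but still
usable for track building).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import pysam

from .genomes import FormatError, ReferenceGenome

logger = logging.getLogger("asmqc")


class DiscrepancyType(str, Enum):
    MISMATCH = "mismatch"
    INSERTION = "insertion"
    DELETION = "deletion"


class SizeClass(str, Enum):
    SMALL = "small"
    LARGE = "large"
    STRUCTURAL = "structural"
    NOT_APPLICABLE = "not_applicable"


class ConsistencyError(ValueError):
    """Input alleles contradict the reference sequence."""


@dataclass(frozen=True)
class Discrepancy:
    """One normalized assembly-vs-reference difference.

    ``ref_pos`` is 1-based: the mismatched base, the anchor base of an
    insertion, or the first deleted base.
    """

    chrom: str
    ref_pos: int
    ref_allele: str
    alt_allele: str
    dtype: DiscrepancyType

    def __post_init__(self) -> None:
        if self.dtype is DiscrepancyType.MISMATCH:
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValueError("mismatch requires single-base alleles")
            if self.ref_allele == self.alt_allele:
                raise ValueError("mismatch alleles must differ")
        elif self.dtype is DiscrepancyType.INSERTION:
            if self.ref_allele or not self.alt_allele:
                raise ValueError("insertion requires empty ref, non-empty alt")
        elif self.dtype is DiscrepancyType.DELETION:
            if self.alt_allele or not self.ref_allele:
                raise ValueError("deletion requires non-empty ref, empty alt")

    @property
    def indel_len(self) -> int:
        return abs(len(self.ref_allele) - len(self.alt_allele))

    @property
    def is_indel(self) -> bool:
        return self.dtype is not DiscrepancyType.MISMATCH

    def affected_span(self) -> tuple[int, int]:
        """0-based half-open span of affected reference bases.

        For an insertion this is the single anchor base; for a deletion the
        deleted bases; for a mismatch the substituted base.
        """
        start = self.ref_pos - 1
        if self.dtype is DiscrepancyType.DELETION:
            return start, start + len(self.ref_allele)
        return start, start + 1


@dataclass(frozen=True)
class IndelSizeConfig:
    """Size-class boundaries in bp: small <= small_max < large <= large_max."""

    small_max: int = 5
    large_max: int = 85

    def __post_init__(self) -> None:
        if not (0 < self.small_max < self.large_max):
            raise ValueError("require 0 < small_max < large_max")


def size_class(d: Discrepancy, cfg: IndelSizeConfig = IndelSizeConfig()) -> SizeClass:
    """Assign an indel to {small, large, structural}; mismatches are N/A."""
    if not d.is_indel:
        return SizeClass.NOT_APPLICABLE
    n = d.indel_len
    if n <= cfg.small_max:
        return SizeClass.SMALL
    if n <= cfg.large_max:
        return SizeClass.LARGE
    return SizeClass.STRUCTURAL


# ---------------------------------------------------------------------------
# Allele normalization
# ---------------------------------------------------------------------------

def _normalize_alleles(chrom: str, pos: int, ref: str, alt: str) -> list[Discrepancy]:
    """Turn one (possibly anchored, possibly multi-base) REF/ALT pair into
    normalized discrepancies.

    Shared leading bases are stripped (the VCF anchor convention); equal-
    length multi-base substitutions are decomposed into per-base mismatches,
    since mismatches are counted as base events.  No further left-alignment
    is attempted: input coordinates are trusted.
    """
    ref, alt = ref.upper(), alt.upper()
    # strip shared prefix, advancing the position
    while ref and alt and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1
    if not ref and not alt:
        return []
    if ref and alt and len(ref) == len(alt):
        return [
            Discrepancy(chrom, pos + i, r, a, DiscrepancyType.MISMATCH)
            for i, (r, a) in enumerate(zip(ref, alt))
            if r != a
        ]
    if ref and alt:
        # length-changing substitution: strip shared suffix, then emit the
        # remainder as mismatches over the overlap plus one indel
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        k = min(len(ref), len(alt))
        out = [
            Discrepancy(chrom, pos + i, r, a, DiscrepancyType.MISMATCH)
            for i, (r, a) in enumerate(zip(ref[:k], alt[:k]))
            if r != a
        ]
        if len(ref) > len(alt):
            out.append(
                Discrepancy(chrom, pos + k, ref[k:], "", DiscrepancyType.DELETION)
            )
        else:
            out.append(
                Discrepancy(chrom, pos + k - 1, "", alt[k:], DiscrepancyType.INSERTION)
            )
        return out
    if alt:  # pure insertion: anchor is the base left of the inserted sequence
        return [Discrepancy(chrom, pos - 1, "", alt, DiscrepancyType.INSERTION)]
    return [Discrepancy(chrom, pos, ref, "", DiscrepancyType.DELETION)]


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_vcf_discrepancies(
    path, genome: ReferenceGenome | None = None
) -> list[Discrepancy]:
    """Read a VCF 4.x file into normalized discrepancies.

    Multi-allelic records are split, one discrepancy list entry per ALT.
    When a genome is supplied, each record's REF is checked against the
    reference sequence and a :class:`ConsistencyError` is raised on
    disagreement.
    """
    out: list[Discrepancy] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if genome is not None:
                expected = genome.sequence(
                    rec.chrom, rec.pos - 1, rec.pos - 1 + len(rec.ref)
                )
                if expected != rec.ref.upper():
                    raise ConsistencyError(
                        f"{rec.chrom}:{rec.pos}: VCF REF {rec.ref!r} disagrees "
                        f"with reference sequence {expected!r}"
                    )
            for alt in rec.alts or ():
                if set(alt) - set("ACGTNacgtn"):
                    logger.warning(
                        "%s:%d: skipping symbolic/breakend ALT %r",
                        rec.chrom, rec.pos, alt,
                    )
                    continue
                out.extend(_normalize_alleles(rec.chrom, rec.pos, rec.ref, alt))
    return out


def read_quast_snps(path) -> list[Discrepancy]:
    """Read a Quast-style SNP/indel TSV into normalized discrepancies.

    Expected columns: chromosome, reference position (1-based), reference
    allele or ``.``, contig id, contig position, assembly allele or ``.``.
    ``.`` marks the absent side of an indel; a row with ``.`` on both sides
    is a format error.  For insertion rows the reference position is taken
    as the anchor base (the base left of the inserted sequence).
    """
    out: list[Discrepancy] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
            chrom, pos_s, ref, _contig, _cpos, alt = parts[:6]
            try:
                pos = int(pos_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer position {pos_s!r}")
            ref = "" if ref == "." else ref.upper()
            alt = "" if alt == "." else alt.upper()
            if not ref and not alt:
                raise FormatError(f"{path}:{lineno}: both alleles are '.'")
            if not ref:
                out.append(Discrepancy(chrom, pos, "", alt, DiscrepancyType.INSERTION))
            elif not alt:
                out.append(Discrepancy(chrom, pos, ref, "", DiscrepancyType.DELETION))
            else:
                out.extend(_normalize_alleles(chrom, pos, ref, alt))
    return out


def write_discrepancy_tsv(
    discrepancies: Iterable[Discrepancy],
    path,
    cfg: IndelSizeConfig = IndelSizeConfig(),
) -> None:
    """Export normalized discrepancies with size classes as TSV."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\ttype\tref\talt\tindel_len\tsize_class\n")
        for d in discrepancies:
            fh.write(
                f"{d.chrom}\t{d.ref_pos}\t{d.dtype.value}\t"
                f"{d.ref_allele or '.'}\t{d.alt_allele or '.'}\t"
                f"{d.indel_len}\t{size_class(d, cfg).value}\n"
            )


def count_size_classes(
    discrepancies: Sequence[Discrepancy], cfg: IndelSizeConfig = IndelSizeConfig()
) -> dict[str, int]:
    counts = {c.value: 0 for c in SizeClass}
    for d in discrepancies:
        counts[size_class(d, cfg).value] += 1
    return counts
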