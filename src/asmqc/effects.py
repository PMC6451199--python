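"""Coding/non-coding classification and mutation-effect annotation.

Each discrepancy is first placed into coding or non-coding space using the
CDS-union partition (mismatches and deletions are coding if *any* affected
reference base is coding; insertions if their anchor base is).  Coding
discrepancies are then annotated per overlapping transcript:

* mismatches — the containing codon is reconstructed from the spliced,
  strand-corrected CDS using the reading-frame phase, and the call is
  synonymous iff the standard genetic code (translation table 1) gives the
  same amino acid for the reference and alternate codons;
* indels fully inside a transcript's CDS — in-frame iff the length is a
  multiple of 3, frameshift otherwise;
* indels straddling a CDS edge — counted as coding (any-base rule) and
  conservatively labelled frameshift.

Region counts are per discrepancy (counted once even when several
transcripts overlap); effect lists are per transcript.  A transcript's
mRNA is "affected" by any coding discrepancy; its protein is "altered"
only by a non-synonymous mismatch or an indel — a purely synonymous hit
touches the mRNA but leaves the protein unchanged, which is why affected
mRNA counts are always >= altered protein counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from Bio.Data import CodonTable
from Bio.Seq import Seq

from .discrepancies import Discrepancy, DiscrepancyType
from .genomes import (
    RegionPartition,
    ReferenceGenome,
    TranscriptModel,
    reverse_complement,
)

logger = logging.getLogger("asmqc")

_COMPLEMENT_BASE = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class Region(str, Enum):
    CODING = "coding"
    NON_CODING = "non_coding"


class Effect(str, Enum):
    SYNONYMOUS = "synonymous"
    NON_SYNONYMOUS = "non_synonymous"
    INFRAME_INDEL = "inframe_indel"
    FRAMESHIFT_INDEL = "frameshift_indel"
    NON_CODING = "non_coding"
    UNRESOLVED = "unresolved"  # codon not reconstructable (phase/N/short CDS)

ALTERING_EFFECTS = {Effect.NON_SYNONYMOUS, Effect.INFRAME_INDEL,
                    Effect.FRAMESHIFT_INDEL}


@dataclass
class EffectAnnotation:
    """Region call plus per-transcript effects for one discrepancy."""

    discrepancy: Discrepancy
    region: Region
    transcript_effects: list[tuple[str, Effect]] = field(default_factory=list)

    @property
    def alters_protein(self) -> bool:
        return any(e in ALTERING_EFFECTS for _, e in self.transcript_effects)


@dataclass
class EffectSummary:
    """Aggregate counts mirroring a per-assembly evaluation table."""

    n_mismatch_cds: int = 0
    n_mismatch_nc: int = 0
    n_indel_cds: int = 0
    n_indel_nc: int = 0
    n_nonsyn: int = 0
    n_syn: int = 0
    n_unresolved_mismatch: int = 0
    n_inframe: int = 0
    affected_mrnas: int = 0
    altered_proteins: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "mismatches_in_cds": self.n_mismatch_cds,
            "mismatches_outside_cds": self.n_mismatch_nc,
            "indels_in_cds": self.n_indel_cds,
            "indels_outside_cds": self.n_indel_nc,
            "non_synonymous_mutations": self.n_nonsyn,
            "synonymous_mutations": self.n_syn,
            "unresolved_coding_mismatches": self.n_unresolved_mismatch,
            "inframe_indels": self.n_inframe,
            "affected_mrnas": self.affected_mrnas,
            "altered_proteins": self.altered_proteins,
        }


def classify_region(d: Discrepancy, partition: RegionPartition) -> Region:
    """Coding/non-coding call for one discrepancy (any-base / anchor rule)."""
    start, end = d.affected_span()
    if d.chrom not in partition.chrom_lengths:
        from .genomes import BoundsError

        raise BoundsError(f"unknown chromosome {d.chrom!r}")
    length = partition.chrom_lengths[d.chrom]
    if start < 0 or end > length:
        from .genomes import BoundsError

        raise BoundsError(f"{d.chrom}:{d.ref_pos} outside chromosome (length {length})")
    if partition.overlaps_coding(d.chrom, start, end):
        return Region.CODING
    return Region.NON_CODING


def _codon_call(
    d: Discrepancy, t: TranscriptModel, genome: ReferenceGenome
) -> Effect:
    """Synonymous/non-synonymous call for a mismatch inside ``t``'s CDS."""
    spliced = t.spliced_cds(genome)
    idx = t.spliced_index(d.ref_pos - 1)
    if idx is None:  # caller guarantees overlap; defensive
        return Effect.NON_CODING
    cds_idx = idx - t.phase
    if cds_idx < 0:
        return Effect.UNRESOLVED
    codon_start = t.phase + 3 * (cds_idx // 3)
    if codon_start + 3 > len(spliced):
        return Effect.UNRESOLVED
    ref_codon = spliced[codon_start:codon_start + 3]
    alt_base = d.alt_allele
    if t.strand == "-":
        alt_base = _COMPLEMENT_BASE.get(alt_base, "N")
    within = idx - codon_start
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1:]
    if "N" in ref_codon or "N" in alt_codon:
        return Effect.UNRESOLVED
    ref_aa = str(Seq(ref_codon).translate(table=1))
    alt_aa = str(Seq(alt_codon).translate(table=1))
    return Effect.SYNONYMOUS if ref_aa == alt_aa else Effect.NON_SYNONYMOUS


def annotate_effect(
    d: Discrepancy, t: TranscriptModel, genome: ReferenceGenome
) -> Effect:
    """Effect of one discrepancy on one transcript.

    Returns ``NON_CODING`` when the discrepancy does not touch the
    transcript's CDS (per the any-base/anchor rule applied to this single
    transcript).
    """
    start, end = d.affected_span()
    touched = any(
        t.contains(p) for p in range(start, end)
    )
    if not touched:
        return Effect.NON_CODING
    if d.dtype is DiscrepancyType.MISMATCH:
        return _codon_call(d, t, genome)
    # indel: in-frame/frameshift decided only when fully inside the CDS
    fully_inside = all(t.contains(p) for p in range(start, end))
    if fully_inside and d.indel_len % 3 == 0:
        return Effect.INFRAME_INDEL
    return Effect.FRAMESHIFT_INDEL


def annotate_all(
    discrepancies: Sequence[Discrepancy],
    transcripts: Sequence[TranscriptModel],
    genome: ReferenceGenome,
    partition: RegionPartition,
) -> list[EffectAnnotation]:
    """Region + per-transcript effect annotation for every discrepancy."""
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_chrom.setdefault(t.chrom, []).append(t)
    out: list[EffectAnnotation] = []
    for d in discrepancies:
        region = classify_region(d, partition)
        effects: list[tuple[str, Effect]] = []
        if region is Region.CODING:
            for t in by_chrom.get(d.chrom, ()):  # small genomes: linear scan is fine
                eff = annotate_effect(d, t, genome)
                if eff is not Effect.NON_CODING:
                    effects.append((t.transcript_id, eff))
        out.append(EffectAnnotation(d, region, effects))
    return out


def summarize_effects(annotations: Iterable[EffectAnnotation]) -> EffectSummary:
    """Aggregate per-discrepancy annotations into table-style counts.

    Mismatch syn/non-syn tallies are per discrepancy: a mismatch is counted
    non-synonymous if any overlapping transcript's call is non-synonymous,
    synonymous if all resolvable calls are synonymous.  An indel is counted
    in-frame only when every coding transcript effect is in-frame.
    """
    s = EffectSummary()
    affected: set[str] = set()
    altered: set[str] = set()
    for ann in annotations:
        d = ann.discrepancy
        coding = ann.region is Region.CODING
        if d.is_indel:
            if coding:
                s.n_indel_cds += 1
            else:
                s.n_indel_nc += 1
        else:
            if coding:
                s.n_mismatch_cds += 1
            else:
                s.n_mismatch_nc += 1
        effs = [e for _, e in ann.transcript_effects]
        if coding and not d.is_indel:
            resolvable = [e for e in effs
                          if e in (Effect.SYNONYMOUS, Effect.NON_SYNONYMOUS)]
            if Effect.NON_SYNONYMOUS in resolvable:
                s.n_nonsyn += 1
            elif resolvable:
                s.n_syn += 1
            else:
                s.n_unresolved_mismatch += 1
        if coding and d.is_indel and effs:
            if all(e is Effect.INFRAME_INDEL for e in effs):
                s.n_inframe += 1
        for tid, eff in ann.transcript_effects:
            affected.add(tid)
            if eff in ALTERING_EFFECTS:
                altered.add(tid)
    s.affected_mrnas = len(affected)
    s.altered_proteins = len(altered)
    return s


def write_annotation_tsv(annotations: Iterable[EffectAnnotation], path) -> None:
    """Per-discrepancy annotation export: one row per transcript effect
    (or a single row with transcript '.' for non-coding hits)."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\ttype\tregion\ttranscript\teffect\n")
        for ann in annotations:
            d = ann.discrepancy
            base = f"{d.chrom}\t{d.ref_pos}\t{d.dtype.value}\t{ann.region.value}"
            if ann.transcript_effects:
                for tid, eff in ann.transcript_effects:
                    fh.write(f"{base}\t{tid}\t{eff.value}\n")
            else:
                fh.write(f"{base}\t.\t{Effect.NON_CODING.value}\n")
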