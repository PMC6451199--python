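"""Reference genomes, gene models, and the coding/non-coding partition.

A polished long-read assembly is evaluated against a curated reference
genome.  Everything downstream (discrepancy classification, effect calls,
density statistics, feature tracks) lives in the coordinate frame of that
reference, so this module owns the three foundational objects:

``ReferenceGenome``
    chromosome id -> nucleotide sequence, the coordinate frame.
``TranscriptModel``
    strand-aware, ordered CDS intervals with the reading-frame phase of the
    first coding segment — the basis for codon reconstruction.
``RegionPartition``
    the per-base union of all CDS intervals, splitting the genome into
    coding and non-coding space (UTRs and introns count as non-coding).

All internal coordinates are 0-based half-open.  GFF3 (1-based inclusive),
VCF (1-based) and BED (0-based half-open) are converted at the parser
boundary and nowhere else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("asmqc")

#: IUPAC nucleotide codes accepted in reference sequences.
IUPAC_NT = set("ACGTUNRYSWKMBDHV")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class AnnotationError(ValueError):
    """Gene-model content is structurally invalid (e.g. CDS without parent)."""


class BoundsError(ValueError):
    """A coordinate falls outside its chromosome."""


@dataclass
class ReferenceGenome:
    """Chromosome sequences keyed by id, in file order."""

    chromosomes: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def sequence(self, chrom: str, start: int, end: int) -> str:
        """Sub-sequence in 0-based half-open coordinates, bounds-checked."""
        try:
            seq = self.chromosomes[chrom]
        except KeyError:
            raise BoundsError(f"unknown chromosome {chrom!r}") from None
        if not (0 <= start <= end <= len(seq)):
            raise BoundsError(
                f"{chrom}:{start}-{end} outside chromosome of length {len(seq)}"
            )
        return seq[start:end]


@dataclass
class TranscriptModel:
    """One transcript's CDS layout on the reference.

    ``cds_intervals`` are 0-based half-open, sorted in *genomic* order and
    non-overlapping within the transcript; for minus-strand transcripts the
    translation order is the reverse.  ``phase`` is the phase of the first
    CDS segment in translation order: the number of bases to skip before
    the first complete codon.
    """

    transcript_id: str
    chrom: str
    strand: str
    cds_intervals: list[tuple[int, int]]
    phase: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        ivs = sorted(self.cds_intervals)
        for (s0, e0), (s1, e1) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise AnnotationError(
                    f"{self.transcript_id}: overlapping CDS segments "
                    f"({s0},{e0}) and ({s1},{e1})"
                )
        for s, e in ivs:
            if s >= e:
                raise AnnotationError(
                    f"{self.transcript_id}: empty CDS interval ({s},{e})"
                )
        self.cds_intervals = ivs

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    def frame_remainder(self) -> int:
        """(spliced length - phase) mod 3; non-zero flags a malformed model."""
        return (self.spliced_length - self.phase) % 3

    def validate_against(self, genome: ReferenceGenome) -> None:
        length = genome.lengths.get(self.chrom)
        if length is None:
            raise BoundsError(
                f"{self.transcript_id}: chromosome {self.chrom!r} not in genome"
            )
        for s, e in self.cds_intervals:
            if s < 0 or e > length:
                raise BoundsError(
                    f"{self.transcript_id}: CDS ({s},{e}) outside {self.chrom} "
                    f"(length {length})"
                )

    def spliced_cds(self, genome: ReferenceGenome) -> str:
        """CDS sequence in translation order (reverse-complemented for '-')."""
        parts = [genome.sequence(self.chrom, s, e) for s, e in self.cds_intervals]
        seq = "".join(parts)
        if self.strand == "-":
            seq = reverse_complement(seq)
        return seq

    def spliced_index(self, pos: int) -> int | None:
        """Map a genomic position to its index in the spliced CDS.

        Returns None when ``pos`` is not inside any CDS segment.  The index
        follows translation order, i.e. it counts from the 3' genomic end
        for minus-strand transcripts.
        """
        offset = 0
        genomic_idx = None
        for s, e in self.cds_intervals:
            if s <= pos < e:
                genomic_idx = offset + (pos - s)
                break
            offset += e - s
        if genomic_idx is None:
            return None
        if self.strand == "-":
            return self.spliced_length - 1 - genomic_idx
        return genomic_idx

    def contains(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.cds_intervals)


_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
                            "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Parsers
# ---------------------------------------------------------------------------

def read_fasta(path) -> ReferenceGenome:
    """Read a (multi-)FASTA file into a :class:`ReferenceGenome`.

    Record ids are the header token up to the first whitespace; sequences
    are upper-cased.  Residues outside the IUPAC nucleotide alphabet raise
    :class:`FormatError` naming the offending record.
    """
    chromosomes: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        bad = set(seq) - IUPAC_NT
        if bad:
            raise FormatError(
                f"record {record.id!r}: non-nucleotide residues {sorted(bad)}"
            )
        if record.id in chromosomes:
            raise FormatError(f"duplicate chromosome id {record.id!r}")
        chromosomes[record.id] = seq
    if not chromosomes:
        raise FormatError(f"{path}: no FASTA records found")
    return ReferenceGenome(chromosomes)


def read_gff3(path, genome: ReferenceGenome | None = None) -> list[TranscriptModel]:
    """Read CDS features from GFF3 and group them into transcript models.

    CDS features are grouped by their ``Parent`` attribute (falling back to
    ``ID`` for parent-less single-feature dialects raises instead: a CDS
    without a parent is an annotation error).  GFF3 1-based inclusive
    coordinates become 0-based half-open.  The stored phase is the phase of
    the first CDS segment in translation order (last genomic segment for
    minus-strand transcripts).
    """
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    grouped: dict[str, list] = {}
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        parents = feat.attributes.get("Parent")
        if not parents:
            raise AnnotationError(
                f"CDS at {feat.seqid}:{feat.start}-{feat.end} has no Parent attribute"
            )
        for parent in parents:
            grouped.setdefault(parent, []).append(feat)

    models = []
    for tid, feats in grouped.items():
        feats = sorted(feats, key=lambda f: f.start)
        strand = feats[0].strand
        chrom = feats[0].seqid
        if any(f.strand != strand or f.seqid != chrom for f in feats):
            raise AnnotationError(f"{tid}: CDS segments disagree on chromosome/strand")
        first = feats[0] if strand == "+" else feats[-1]
        phase = int(first.frame) if first.frame not in (None, ".", "") else 0
        model = TranscriptModel(
            transcript_id=tid,
            chrom=chrom,
            strand=strand,
            cds_intervals=[(f.start - 1, f.end) for f in feats],
            phase=phase,
        )
        if genome is not None:
            model.validate_against(genome)
        if model.frame_remainder() != 0:
            logger.warning(
                "transcript %s: spliced CDS length %d (phase %d) is not a "
                "multiple of 3", tid, model.spliced_length, model.phase,
            )
        models.append(model)
    return models


# ---------------------------------------------------------------------------
# Interval arithmetic and the coding/non-coding partition
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[tuple[int, int]]) -> np.ndarray:
    """Union of half-open intervals as a sorted (N, 2) int array."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    if not ivs:
        return np.empty((0, 2), dtype=np.int64)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


class IntervalSet:
    """Disjoint sorted half-open intervals with O(log n) point/range queries."""

    def __init__(self, intervals: Iterable[tuple[int, int]] = ()) -> None:
        merged = merge_intervals(intervals)
        self.starts = merged[:, 0] if len(merged) else np.empty(0, dtype=np.int64)
        self.ends = merged[:, 1] if len(merged) else np.empty(0, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def total_bp(self) -> int:
        return int((self.ends - self.starts).sum())

    def contains(self, pos: int) -> bool:
        i = int(np.searchsorted(self.starts, pos, side="right")) - 1
        return i >= 0 and pos < self.ends[i]

    def overlaps(self, start: int, end: int) -> bool:
        """True if any base of [start, end) lies in the set."""
        if end <= start:
            return False
        i = int(np.searchsorted(self.ends, start, side="right"))
        return i < len(self.starts) and self.starts[i] < end

    def intervals(self) -> list[tuple[int, int]]:
        return [(int(s), int(e)) for s, e in zip(self.starts, self.ends)]

    def mask(self, length: int) -> np.ndarray:
        """Per-base boolean membership array of the given length."""
        out = np.zeros(length, dtype=bool)
        for s, e in zip(self.starts, self.ends):
            out[max(0, s):min(length, e)] = True
        return out


@dataclass
class RegionPartition:
    """Coding/non-coding split of a genome: per-chromosome CDS unions."""

    coding: dict[str, IntervalSet]
    chrom_lengths: dict[str, int]

    @property
    def l_cds(self) -> int:
        return sum(ivs.total_bp for ivs in self.coding.values())

    @property
    def l_nc(self) -> int:
        return sum(self.chrom_lengths.values()) - self.l_cds

    def l_cds_chrom(self, chrom: str) -> int:
        return self.coding[chrom].total_bp

    def is_coding(self, chrom: str, pos: int) -> bool:
        if chrom not in self.coding:
            raise BoundsError(f"unknown chromosome {chrom!r}")
        if not (0 <= pos < self.chrom_lengths[chrom]):
            raise BoundsError(
                f"{chrom}:{pos} outside chromosome of length {self.chrom_lengths[chrom]}"
            )
        return self.coding[chrom].contains(pos)

    def overlaps_coding(self, chrom: str, start: int, end: int) -> bool:
        if chrom not in self.coding:
            raise BoundsError(f"unknown chromosome {chrom!r}")
        return self.coding[chrom].overlaps(start, end)

    def coding_mask(self, chrom: str) -> np.ndarray:
        return self.coding[chrom].mask(self.chrom_lengths[chrom])

    def to_bed(self, path) -> None:
        """Write the coding intervals as BED (0-based half-open)."""
        with open(path, "w") as fh:
            for chrom, ivs in self.coding.items():
                for s, e in ivs.intervals():
                    fh.write(f"{chrom}\t{s}\t{e}\tCDS\n")

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for chrom, length in self.chrom_lengths.items():
            cds = self.coding[chrom].total_bp
            rows.append({"chromosome": chrom, "length": length,
                         "L_cds": cds, "L_nc": length - cds})
        return pd.DataFrame(rows)


def build_region_partition(
    genome: ReferenceGenome, transcripts: Sequence[TranscriptModel]
) -> RegionPartition:
    """Union all CDS intervals across transcripts into a coding partition.

    The non-coding length is the complement, so L_cds + L_nc equals the
    genome length exactly, per chromosome and globally.
    """
    per_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chromosomes}
    for t in transcripts:
        t.validate_against(genome)
        per_chrom[t.chrom].extend(t.cds_intervals)
    coding = {chrom: IntervalSet(ivs) for chrom, ivs in per_chrom.items()}
    return RegionPartition(coding=coding, chrom_lengths=genome.lengths)


def read_bed_intervals(path) -> dict[str, list[tuple[int, int]]]:
    """Read BED intervals (0-based half-open) grouped by chromosome."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has <3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer BED coordinates")
            out.setdefault(parts[0], []).append((start, end))
    return out
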