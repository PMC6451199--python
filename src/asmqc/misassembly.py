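"""Mis-assembly breakpoint classification from contig-to-reference alignments.

When a contig aligns to the reference in several blocks, each junction
between consecutive blocks (in contig order) is a potential mis-assembly
breakpoint.  The classes and thresholds follow the Quast convention used
for long-read assembly evaluation:

* translocation — the flanking blocks align to different chromosomes;
* inversion — same chromosome, opposite strands;
* relocation — same chromosome and strand, but the blocks are more than
  ``extensive_mis_size`` (default 12 kb, twice a 6 kb minimum read length)
  further apart — or overlapping by more — than the contig spacing implies;
* local — the same inconsistency, but between 85 bp and 12 kb;
* consistent — anything at or below 85 bp.

The gap/overlap magnitude is |observed reference distance − contig distance
between the blocks|, which folds "further apart" and "overlap by the same
length" into one number.  Blocks below the minimum percent identity
(default 99.5) are dropped before breakpoint analysis, mirroring the
identity filter the upstream aligner applies.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .genomes import FormatError

logger = logging.getLogger("asmqc")


class BreakpointClass(str, Enum):
    TRANSLOCATION = "translocation"
    RELOCATION = "relocation"
    INVERSION = "inversion"
    LOCAL = "local"
    CONSISTENT = "consistent"


@dataclass(frozen=True)
class AlignmentBlock:
    """One contig-to-reference alignment segment (all coordinates 0-based
    half-open, start < end in both frames regardless of strand)."""

    contig: str
    c_start: int
    c_end: int
    chrom: str
    r_start: int
    r_end: int
    strand: str
    identity: float = 100.0

    def __post_init__(self) -> None:
        if not (self.c_start < self.c_end and self.r_start < self.r_end):
            raise ValueError(f"{self.contig}: block start must precede end")
        if self.strand not in "+-":
            raise ValueError(f"{self.contig}: strand must be '+' or '-'")
        if not (0 <= self.identity <= 100):
            raise ValueError(f"{self.contig}: identity must be in [0, 100]")


@dataclass(frozen=True)
class MisassemblyConfig:
    """Breakpoint thresholds (bp / percent)."""

    extensive_mis_size: int = 12_000
    local_min: int = 85
    min_identity: float = 99.5

    def __post_init__(self) -> None:
        if not (0 < self.local_min < self.extensive_mis_size):
            raise ValueError("require 0 < local_min < extensive_mis_size")


def reference_discordance(left: AlignmentBlock, right: AlignmentBlock) -> int:
    """|observed reference distance − contig distance| for same-chromosome,
    same-strand flanking blocks."""
    contig_gap = right.c_start - left.c_end
    if left.strand == "+":
        ref_gap = right.r_start - left.r_end
    else:  # minus strand: reference coordinates run opposite to contig order
        ref_gap = left.r_start - right.r_end
    return abs(ref_gap - contig_gap)


def classify_breakpoint(
    left: AlignmentBlock,
    right: AlignmentBlock,
    cfg: MisassemblyConfig = MisassemblyConfig(),
) -> BreakpointClass:
    """Classify the junction between two consecutive blocks of one contig.

    Distances exactly equal to ``extensive_mis_size`` classify as local
    (inclusive upper bound), leaving no gap between the local and
    relocation classes; distances at or below ``local_min`` (85 bp) are
    consistent.
    """
    if left.contig != right.contig:
        raise ValueError(
            f"blocks from different contigs: {left.contig!r} vs {right.contig!r}"
        )
    if left.chrom != right.chrom:
        return BreakpointClass.TRANSLOCATION
    if left.strand != right.strand:
        return BreakpointClass.INVERSION
    d = reference_discordance(left, right)
    if d > cfg.extensive_mis_size:
        return BreakpointClass.RELOCATION
    if d > cfg.local_min:
        return BreakpointClass.LOCAL
    return BreakpointClass.CONSISTENT


def classify_assembly(
    blocks: Sequence[AlignmentBlock],
    cfg: MisassemblyConfig = MisassemblyConfig(),
) -> tuple[dict[str, int], list[tuple[AlignmentBlock, AlignmentBlock, BreakpointClass]]]:
    """Classify every adjacent block pair of every contig.

    Blocks failing ``min_identity`` are dropped (logged); blocks are sorted
    by contig coordinate within each contig (with a warning if the input was
    unsorted).  Returns (per-class counts, labelled breakpoints).  Every
    adjacent pair gets exactly one label, so the total number of labels is
    the sum over contigs of (blocks − 1).
    """
    kept = [b for b in blocks if b.identity >= cfg.min_identity]
    dropped = len(blocks) - len(kept)
    if dropped:
        logger.info("dropped %d blocks below %.2f%% identity", dropped, cfg.min_identity)

    by_contig: dict[str, list[AlignmentBlock]] = {}
    for b in kept:
        by_contig.setdefault(b.contig, []).append(b)

    counts = Counter({c.value: 0 for c in BreakpointClass})
    labelled: list[tuple[AlignmentBlock, AlignmentBlock, BreakpointClass]] = []
    for contig, cblocks in by_contig.items():
        ordered = sorted(cblocks, key=lambda b: (b.c_start, b.c_end))
        if ordered != cblocks:
            logger.warning("contig %s: blocks were not sorted; auto-sorted", contig)
        for left, right in zip(ordered, ordered[1:]):
            label = classify_breakpoint(left, right, cfg)
            counts[label.value] += 1
            labelled.append((left, right, label))
    return dict(counts), labelled


# ---------------------------------------------------------------------------
# Coords-style TSV I/O
# ---------------------------------------------------------------------------

_COORDS_COLUMNS = ("contig", "c_start", "c_end", "chrom", "r_start", "r_end",
                   "strand", "identity")


def read_coords(path) -> list[AlignmentBlock]:
    """Read alignment blocks from a coords-style TSV (one block per line:
    contig, c_start, c_end, chrom, r_start, r_end, strand, identity)."""
    out: list[AlignmentBlock] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise FormatError(f"{path}:{lineno}: expected 8 columns, got {len(parts)}")
            try:
                out.append(AlignmentBlock(
                    contig=parts[0], c_start=int(parts[1]), c_end=int(parts[2]),
                    chrom=parts[3], r_start=int(parts[4]), r_end=int(parts[5]),
                    strand=parts[6], identity=float(parts[7]),
                ))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_coords(blocks: Iterable[AlignmentBlock], path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_COORDS_COLUMNS) + "\n")
        for b in blocks:
            fh.write(
                f"{b.contig}\t{b.c_start}\t{b.c_end}\t{b.chrom}\t"
                f"{b.r_start}\t{b.r_end}\t{b.strand}\t{b.identity:g}\n"
            )


def write_breakpoint_tsv(
    labelled: Iterable[tuple[AlignmentBlock, AlignmentBlock, BreakpointClass]], path
) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tleft_end\tright_start\tleft_chrom\tright_chrom\tclass\n")
        for left, right, label in labelled:
            fh.write(
                f"{left.contig}\t{left.c_end}\t{right.c_start}\t"
                f"{left.chrom}\t{right.chrom}\t{label.value}\n"
            )
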