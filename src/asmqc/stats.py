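"""Headline evaluation statistics for a polished assembly.

These are the simple but load-bearing numbers of assembly evaluation:

* the fold-likelihood ratio of discrepancy densities between non-coding
  and coding space, (n_nc / L_nc) / (n_cds / L_cds) — e.g. how much more
  likely an indel is to land in AT-rich non-coding sequence;
* the combined accuracy of a region class,
  100 * (1 - (mismatches + indels) / L), an event-count definition;
* per-100-kbp rates, with the denominator (aligned length or region
  length) supplied explicitly by the caller;
* co-location of discrepancies between two assemblies against the same
  reference: shared means same chromosome, same position, same category
  (mismatch vs indel), each discrepancy matched at most once.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from .discrepancies import Discrepancy, DiscrepancyType


@dataclass(frozen=True)
class RegionCounts:
    """Counts of one discrepancy type split by region, with region lengths."""

    n_cds: int
    n_nc: int
    l_cds: int
    l_nc: int

    def __post_init__(self) -> None:
        if self.l_cds <= 0 or self.l_nc <= 0:
            raise ValueError("region lengths must be positive")
        if self.n_cds < 0 or self.n_nc < 0:
            raise ValueError("counts must be non-negative")


def fold_likelihood(rc: RegionCounts) -> float:
    """Non-coding vs coding density ratio: (n_nc/L_nc) / (n_cds/L_cds).

    Returns ``math.inf`` when the coding count is zero (an undefined ratio
    reported as an infinite density contrast rather than a number).  Use
    :func:`round` to one decimal for display; the unrounded value is what
    this function returns.
    """
    if rc.n_cds == 0:
        return math.inf
    return (rc.n_nc / rc.l_nc) / (rc.n_cds / rc.l_cds)


def combined_accuracy(n_mismatch: int, n_indel: int, length_bp: int) -> float:
    """Percent accuracy of a region: 100 * (1 - events / length)."""
    if length_bp <= 0:
        raise ValueError("region length must be positive")
    if n_mismatch < 0 or n_indel < 0:
        raise ValueError("counts must be non-negative")
    return 100.0 * (1.0 - (n_mismatch + n_indel) / length_bp)


def per_100kbp(n: int, denominator_bp: int) -> float:
    """Rate per 100 kbp over an explicit denominator (aligned or region bp)."""
    if denominator_bp <= 0:
        raise ValueError("denominator must be positive")
    return n / denominator_bp * 100_000


@dataclass
class ColocationResult:
    """Discrepancies shared by two assemblies at identical reference loci."""

    shared_indels: int
    shared_mismatches: int
    matched_pairs: list[tuple[Discrepancy, Discrepancy]] = field(default_factory=list)


def _category(d: Discrepancy) -> str:
    return "mismatch" if d.dtype is DiscrepancyType.MISMATCH else "indel"


def colocate(
    a: Sequence[Discrepancy],
    b: Sequence[Discrepancy],
    allele_strict: bool = False,
) -> ColocationResult:
    """Match discrepancies of two assemblies at the same reference locations.

    A pair is shared iff same chromosome, same position, and same type
    category (mismatch vs indel); with ``allele_strict`` the alleles must
    also agree.  Each discrepancy is matched at most once, so shared counts
    are bounded by the smaller multiset.
    """
    def key(d: Discrepancy):
        k = (d.chrom, d.ref_pos, _category(d))
        return k + (d.ref_allele, d.alt_allele) if allele_strict else k

    pool: dict[tuple, list[Discrepancy]] = {}
    for d in b:
        pool.setdefault(key(d), []).append(d)

    shared = Counter()
    pairs: list[tuple[Discrepancy, Discrepancy]] = []
    for d in a:
        bucket = pool.get(key(d))
        if bucket:
            other = bucket.pop()
            shared[_category(d)] += 1
            pairs.append((d, other))
    return ColocationResult(
        shared_indels=shared["indel"],
        shared_mismatches=shared["mismatch"],
        matched_pairs=pairs,
    )
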