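"""Per-base feature tracks, sliding-window counts, and blocked correlations.

This implements the windowed feature-correlation procedure used to relate
indel locations to genomic context along each chromosome:

1. per-base tracks are built for each feature — 0/1 indicators for indel
   anchors, mismatch positions, coding bases, repeat bases, non-coding
   non-repeat bases, G/C bases and zero-coverage bases, plus raw depth for
   coverage;
2. indicator/depth values are summed in sliding windows of ``w`` bp
   (100–1,000) advancing in steps of ``s`` bp (50–500), the trailing
   partial window dropped;
3. for each pair of features, a Pearson correlation is computed over every
   block of ``B`` consecutive window counts (default 200), the block
   advancing one window at a time — yielding a correlation vector along
   the chromosome.

Blocks where either series has zero variance are reported as undefined
(NaN plus an explicit mask) rather than silently zeroed, so feature
deserts such as telomeres do not fabricate correlation signal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .discrepancies import Discrepancy
from .genomes import FormatError, IntervalSet, ReferenceGenome, RegionPartition

logger = logging.getLogger("asmqc")

TRACK_NAMES = (
    "indels", "mismatches", "coding", "repeats", "noncoding_nonrepeat",
    "gc", "coverage", "coverage_gap",
)


@dataclass
class FeatureTrack:
    """Per-base values of one feature along one chromosome."""

    chrom: str
    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.name in TRACK_NAMES and self.name != "coverage":
            bad = set(np.unique(self.values)) - {0, 1}
            if bad:
                raise ValueError(f"indicator track {self.name!r} has values {bad}")


@dataclass(frozen=True)
class WindowSpec:
    """Window width, step, and correlation block size (in window counts).

    Defaults are the midpoints of the ranges the procedure is defined over
    (windows 100–1,000 bp, steps 50–500 bp) with 200-count blocks.
    """

    window: int = 500
    step: int = 250
    block: int = 200

    def __post_init__(self) -> None:
        if not (100 <= self.window <= 1000):
            raise ValueError("window must be in [100, 1000] bp")
        if not (50 <= self.step <= 500):
            raise ValueError("step must be in [50, 500] bp")
        if self.step > self.window:
            raise ValueError("step must not exceed window")
        if self.block < 3:
            raise ValueError("block must be >= 3 window counts")


@dataclass
class CorrelationVector:
    """Blocked Pearson correlations for one feature pair on one chromosome."""

    chrom: str
    feature_x: str
    feature_y: str
    positions: np.ndarray  # block centers, bp
    r: np.ndarray          # NaN where undefined
    defined: np.ndarray    # False where either series had zero variance


def build_tracks(
    genome: ReferenceGenome,
    partition: RegionPartition,
    discrepancies: Sequence[Discrepancy] = (),
    repeat_intervals: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    coverage: Mapping[str, np.ndarray] | None = None,
) -> list[FeatureTrack]:
    """Build per-base feature tracks for every chromosome.

    ``repeat_intervals`` are 0-based half-open per chromosome; ``coverage``
    maps chromosome to a per-base depth array (chromosomes missing from it
    get no coverage/coverage_gap track, with a warning).  Indel tracks mark
    the anchor base only, keeping them structurally comparable to the
    mismatch track.
    """
    repeat_intervals = repeat_intervals or {}
    tracks: list[FeatureTrack] = []
    for chrom, seq in genome.chromosomes.items():
        length = len(seq)
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        gc = ((arr == ord("G")) | (arr == ord("C"))).astype(np.int8)

        indel = np.zeros(length, dtype=np.int8)
        mism = np.zeros(length, dtype=np.int8)
        for d in discrepancies:
            if d.chrom != chrom:
                continue
            pos = d.ref_pos - 1
            if 0 <= pos < length:
                (indel if d.is_indel else mism)[pos] = 1

        coding = partition.coding_mask(chrom).astype(np.int8)
        repeats = IntervalSet(repeat_intervals.get(chrom, ())).mask(length).astype(np.int8)
        ncnr = ((coding == 0) & (repeats == 0)).astype(np.int8)

        tracks += [
            FeatureTrack(chrom, "indels", indel),
            FeatureTrack(chrom, "mismatches", mism),
            FeatureTrack(chrom, "coding", coding),
            FeatureTrack(chrom, "repeats", repeats),
            FeatureTrack(chrom, "noncoding_nonrepeat", ncnr),
            FeatureTrack(chrom, "gc", gc),
        ]
        if coverage is not None:
            if chrom in coverage:
                depth = np.asarray(coverage[chrom])
                if len(depth) != length:
                    raise ValueError(
                        f"{chrom}: coverage length {len(depth)} != chromosome {length}"
                    )
                tracks.append(FeatureTrack(chrom, "coverage", depth))
                tracks.append(
                    FeatureTrack(chrom, "coverage_gap", (depth == 0).astype(np.int8))
                )
            else:
                logger.warning("no coverage for chromosome %s; track omitted", chrom)
    return tracks


def window_counts(track: FeatureTrack, spec: WindowSpec = WindowSpec()) -> np.ndarray:
    """Sum track values in sliding windows [i*s, i*s + w); partial trailing
    window dropped.  Returns an empty array (with a warning) when the
    chromosome is shorter than one window."""
    values = track.values
    w, s = spec.window, spec.step
    if len(values) < w:
        logger.warning(
            "%s/%s: length %d < window %d; no windows",
            track.chrom, track.name, len(values), w,
        )
        return np.zeros(0, dtype=np.int64)
    n = (len(values) - w) // s + 1
    csum = np.concatenate(([0], np.cumsum(values, dtype=np.int64)))
    starts = np.arange(n) * s
    return csum[starts + w] - csum[starts]


def rolling_correlation(
    x: np.ndarray,
    y: np.ndarray,
    spec: WindowSpec = WindowSpec(),
    chrom: str = "",
    feature_x: str = "x",
    feature_y: str = "y",
    method: str = "pearson",
) -> CorrelationVector:
    """Blocked rolling correlation of two window-count series.

    For each block start j (advancing one window per step), r_j is the
    correlation of x[j:j+B] with y[j:j+B].  Pearson by default; Spearman
    (rank-transformed Pearson) behind the ``method`` flag.  Positions are
    the genomic centers of the base span each block covers.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("count series must have equal length")
    B = spec.block
    if len(x) < B:
        logger.warning("series length %d < block %d; empty correlation vector", len(x), B)
        empty = np.zeros(0)
        return CorrelationVector(chrom, feature_x, feature_y, empty, empty,
                                 empty.astype(bool))
    n = len(x) - B + 1
    r = np.full(n, np.nan)
    defined = np.zeros(n, dtype=bool)
    for j in range(n):
        xs, ys = x[j:j + B], y[j:j + B]
        if method == "spearman":
            xs = pd.Series(xs).rank().to_numpy()
            ys = pd.Series(ys).rank().to_numpy()
        sx, sy = xs.std(), ys.std()
        if sx == 0 or sy == 0:
            continue
        r[j] = float(np.corrcoef(xs, ys)[0, 1])
        defined[j] = True
    # block j covers bases [j*s, (j+B-1)*s + w)
    starts = np.arange(n) * spec.step
    positions = (starts + (starts + (B - 1) * spec.step + spec.window)) / 2.0
    return CorrelationVector(chrom, feature_x, feature_y, positions, r, defined)


def correlate_tracks(
    tracks: Sequence[FeatureTrack],
    pairs: Sequence[tuple[str, str]],
    spec: WindowSpec = WindowSpec(),
    method: str = "pearson",
) -> list[CorrelationVector]:
    """Window each track and compute blocked correlations for feature pairs,
    per chromosome."""
    by_key = {(t.chrom, t.name): t for t in tracks}
    chroms = sorted({t.chrom for t in tracks}, key=lambda c: list(
        dict.fromkeys(t.chrom for t in tracks)).index(c))
    out: list[CorrelationVector] = []
    for chrom in chroms:
        cache: dict[str, np.ndarray] = {}
        for fx, fy in pairs:
            tx, ty = by_key.get((chrom, fx)), by_key.get((chrom, fy))
            if tx is None or ty is None:
                logger.warning("%s: missing track for pair (%s, %s); skipped",
                               chrom, fx, fy)
                continue
            if fx not in cache:
                cache[fx] = window_counts(tx, spec)
            if fy not in cache:
                cache[fy] = window_counts(ty, spec)
            out.append(rolling_correlation(
                cache[fx], cache[fy], spec, chrom, fx, fy, method=method))
    return out


def write_correlation_tsv(vectors: Iterable[CorrelationVector], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tblock_center\tfeature_x\tfeature_y\tr\n")
        for v in vectors:
            for pos, r, ok in zip(v.positions, v.r, v.defined):
                fh.write(
                    f"{v.chrom}\t{pos:.1f}\t{v.feature_x}\t{v.feature_y}\t"
                    f"{r:.6f}\n" if ok else
                    f"{v.chrom}\t{pos:.1f}\t{v.feature_x}\t{v.feature_y}\tNA\n"
                )


def read_bedgraph(path, chrom_lengths: Mapping[str, int]) -> dict[str, np.ndarray]:
    """Read bedGraph coverage (chrom, start, end, depth; 0-based half-open)
    into per-base depth arrays; uncovered bases have depth 0."""
    depth = {c: np.zeros(n, dtype=np.int64) for c, n in chrom_lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: bedGraph line has <4 columns")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if chrom not in depth:
                logger.warning("%s:%d: unknown chromosome %s; skipped",
                               path, lineno, chrom)
                continue
            depth[chrom][start:end] = int(float(value))
    return depth


def plot_correlations(vectors: Sequence[CorrelationVector], path,
                      tracks: Sequence[FeatureTrack] = (),
                      spec: WindowSpec = WindowSpec()) -> None:
    """Optional per-chromosome panel plot: one row per feature pair, positive
    correlations up, negative down."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not vectors:
        return
    n = len(vectors)
    fig, axes = plt.subplots(n, 1, figsize=(10, 1.8 * n), sharex=True, squeeze=False)
    for ax, v in zip(axes[:, 0], vectors):
        pos = v.positions[v.defined] / 1e3
        r = v.r[v.defined]
        ax.bar(pos[r >= 0], r[r >= 0], width=spec.step / 1e3, color="firebrick")
        ax.bar(pos[r < 0], r[r < 0], width=spec.step / 1e3, color="steelblue")
        ax.set_ylim(-1.05, 1.05)
        ax.set_ylabel(f"{v.feature_x}\nvs {v.feature_y}", fontsize=7)
        ax.axhline(0.0, lw=0.5, color="black")
    axes[-1, 0].set_xlabel(f"{vectors[0].chrom} position (kb)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
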