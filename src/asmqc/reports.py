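"""Run configuration, report writers, and the composed evaluation run.

`run_annotate` drives the region/effect annotation for one discrepancy set
and writes a per-discrepancy TSV plus a summary JSON whose keys mirror the
rows of a standard assembly-evaluation table.  `run_full_report` composes
annotation, density/accuracy statistics, mis-assembly classification and
window correlations into one JSON report with a checksummed output
manifest.  Sections whose inputs were not supplied are listed as omitted;
partial-input runs still succeed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import metadata, resources
from pathlib import Path

from . import effects, genomes, misassembly, stats, windows
from .discrepancies import (
    IndelSizeConfig,
    count_size_classes,
    read_quast_snps,
    read_vcf_discrepancies,
    write_discrepancy_tsv,
)
from .misassembly import MisassemblyConfig
from .windows import WindowSpec

logger = logging.getLogger("asmqc")

DEFAULT_FEATURE_PAIRS = (
    ("indels", "mismatches"),
    ("indels", "coding"),
    ("indels", "repeats"),
    ("indels", "noncoding_nonrepeat"),
    ("indels", "gc"),
    ("indels", "coverage"),
    ("indels", "coverage_gap"),
)


@dataclass
class RunConfig:
    """Inputs, thresholds, and output location for one evaluation run."""

    fasta: Path
    gff3: Path
    outdir: Path
    vcf: Path | None = None
    quast_snps: Path | None = None
    repeats_bed: Path | None = None
    bedgraph: Path | None = None
    coords: Path | None = None
    indel_sizes: IndelSizeConfig = field(default_factory=IndelSizeConfig)
    misassembly_cfg: MisassemblyConfig = field(default_factory=MisassemblyConfig)
    window_spec: WindowSpec = field(default_factory=WindowSpec)
    allele_strict: bool = False
    seed: int | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("fasta", "gff3", "vcf", "quast_snps", "repeats_bed",
                     "bedgraph", "coords"):
            value = getattr(self, name)
            if value is not None:
                path = Path(value)
                setattr(self, name, path)
                if not path.exists():
                    raise FileNotFoundError(f"{name} input does not exist: {path}")
        self.outdir = Path(self.outdir)

    def echo(self) -> dict:
        """Config as a JSON-safe dict, echoed verbatim into output metadata."""
        out = {}
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if isinstance(value, Path):
                value = str(value)
            elif dataclasses.is_dataclass(value):
                value = dataclasses.asdict(value)
            out[f.name] = value
        return out


def _load_inputs(config: RunConfig):
    genome = genomes.read_fasta(config.fasta)
    transcripts = genomes.read_gff3(config.gff3, genome)
    partition = genomes.build_region_partition(genome, transcripts)
    if config.vcf is not None:
        discrepancies = read_vcf_discrepancies(config.vcf, genome)
    elif config.quast_snps is not None:
        discrepancies = read_quast_snps(config.quast_snps)
    else:
        discrepancies = []
    bad = sorted({d.chrom for d in discrepancies} - set(genome.chromosomes))
    if bad:
        raise genomes.BoundsError(
            f"discrepancy chromosomes not present in the genome: {bad}")
    return genome, transcripts, partition, discrepancies


def run_annotate(config: RunConfig):
    """Annotate all discrepancies; write annotation TSV + summary JSON.

    Returns (annotations, summary).  Outputs are deterministic for
    identical inputs.
    """
    genome, transcripts, partition, discrepancies = _load_inputs(config)
    annotations = effects.annotate_all(discrepancies, transcripts, genome, partition)
    summary = effects.summarize_effects(annotations)

    config.outdir.mkdir(parents=True, exist_ok=True)
    effects.write_annotation_tsv(annotations, config.outdir / "annotation.tsv")
    write_discrepancy_tsv(discrepancies, config.outdir / "discrepancies.tsv",
                          config.indel_sizes)
    payload = dict(summary.as_dict())
    payload["size_classes"] = count_size_classes(discrepancies, config.indel_sizes)
    with open(config.outdir / "summary.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return annotations, summary


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_full_report(config: RunConfig) -> dict:
    """Compose the full evaluation: annotation, statistics, mis-assembly
    classes, and window correlations; write ``report.json``."""
    genome, transcripts, partition, discrepancies = _load_inputs(config)
    annotations = effects.annotate_all(discrepancies, transcripts, genome, partition)
    summary = effects.summarize_effects(annotations)

    config.outdir.mkdir(parents=True, exist_ok=True)
    effects.write_annotation_tsv(annotations, config.outdir / "annotation.tsv")
    write_discrepancy_tsv(discrepancies, config.outdir / "discrepancies.tsv",
                          config.indel_sizes)

    omitted: list[str] = []
    report: dict = {"sections": {}}

    # --- effect summary -----------------------------------------------------
    report["sections"]["effects"] = dict(summary.as_dict())
    report["sections"]["effects"]["size_classes"] = count_size_classes(
        discrepancies, config.indel_sizes)

    # --- densities and accuracy --------------------------------------------
    l_cds, l_nc = partition.l_cds, partition.l_nc
    sec: dict = {"L_cds": l_cds, "L_nc": l_nc}
    if l_cds > 0 and l_nc > 0:
        indel_rc = stats.RegionCounts(summary.n_indel_cds, summary.n_indel_nc,
                                      l_cds, l_nc)
        mism_rc = stats.RegionCounts(summary.n_mismatch_cds, summary.n_mismatch_nc,
                                     l_cds, l_nc)
        fold_i = stats.fold_likelihood(indel_rc)
        fold_m = stats.fold_likelihood(mism_rc)
        sec["indel_fold_likelihood"] = None if fold_i == float("inf") else fold_i
        sec["indel_fold_likelihood_display"] = (
            "inf" if fold_i == float("inf") else f"{fold_i:.1f}")
        sec["mismatch_fold_likelihood"] = None if fold_m == float("inf") else fold_m
        sec["coding_accuracy_pct"] = stats.combined_accuracy(
            summary.n_mismatch_cds, summary.n_indel_cds, l_cds)
        sec["noncoding_accuracy_pct"] = stats.combined_accuracy(
            summary.n_mismatch_nc, summary.n_indel_nc, l_nc)
        sec["coding_indels_per_100kbp"] = stats.per_100kbp(summary.n_indel_cds, l_cds)
        sec["noncoding_indels_per_100kbp"] = stats.per_100kbp(summary.n_indel_nc, l_nc)
    report["sections"]["statistics"] = sec

    # --- mis-assembly classification ---------------------------------------
    if config.coords is not None:
        blocks = misassembly.read_coords(config.coords)
        counts, labelled = misassembly.classify_assembly(blocks, config.misassembly_cfg)
        misassembly.write_breakpoint_tsv(labelled, config.outdir / "breakpoints.tsv")
        report["sections"]["misassemblies"] = counts
    else:
        omitted.append("misassemblies")
        logger.info("no alignment blocks supplied; mis-assembly section skipped")

    # --- window correlations -----------------------------------------------
    repeat_ivs = (genomes.read_bed_intervals(config.repeats_bed)
                  if config.repeats_bed is not None else {})
    coverage = (windows.read_bedgraph(config.bedgraph, genome.lengths)
                if config.bedgraph is not None else None)
    tracks = windows.build_tracks(genome, partition, discrepancies,
                                  repeat_ivs, coverage)
    have = {t.name for t in tracks}
    pairs = [p for p in DEFAULT_FEATURE_PAIRS if p[0] in have and p[1] in have]
    skipped_pairs = [list(p) for p in DEFAULT_FEATURE_PAIRS if p not in pairs]
    vectors = windows.correlate_tracks(tracks, pairs, config.window_spec)
    corr_path = config.outdir / "correlations.tsv"
    windows.write_correlation_tsv(vectors, corr_path)
    report["sections"]["correlations"] = {
        "file": str(corr_path),
        "pairs": [list(p) for p in pairs],
        "omitted_pairs": skipped_pairs,
        "window": config.window_spec.window,
        "step": config.window_spec.step,
        "block": config.window_spec.block,
    }

    report["omitted_sections"] = omitted
    try:
        report["tool_version"] = metadata.version("asmqc")
    except metadata.PackageNotFoundError:  # pragma: no cover
        report["tool_version"] = "unknown"
    report["config"] = config.echo()

    manifest = {}
    for name in ("annotation.tsv", "discrepancies.tsv", "breakpoints.tsv",
                 "correlations.tsv"):
        path = config.outdir / name
        if path.exists():
            manifest[name] = _sha256(path)
    report["manifest"] = manifest

    with open(config.outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report


# ---------------------------------------------------------------------------
# Report schema (structural validation; no external schema library)
# ---------------------------------------------------------------------------

def load_report_schema() -> dict:
    with resources.files("asmqc").joinpath("report_schema.json").open() as fh:
        return json.load(fh)


def validate_report(report: dict, schema: dict | None = None) -> list[str]:
    """Check the report against the shipped schema; returns a list of
    violations (empty when valid)."""
    schema = schema or load_report_schema()
    problems: list[str] = []

    def check(obj, spec, path):
        expected = spec.get("type")
        types = {"object": dict, "array": list, "string": str,
                 "number": (int, float), "integer": int, "boolean": bool}
        if expected and not isinstance(obj, types[expected]):
            problems.append(f"{path}: expected {expected}, got {type(obj).__name__}")
            return
        if expected == "object":
            for key in spec.get("required", []):
                if key not in obj:
                    problems.append(f"{path}: missing required key {key!r}")
            for key, sub in spec.get("properties", {}).items():
                if key in obj:
                    check(obj[key], sub, f"{path}.{key}")

    check(report, schema, "report")
    return problems
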