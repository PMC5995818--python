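"""One-call reproduction of the full LD-characterization analysis.

Stages, in order: QC -> LD (adjacent and all within-chromosome pairs) ->
summary tables (per-chromosome means, distance-binned decay, LD
categories, metric correlation) -> inbreeding F and the VanRaden G
summary -> Ne trajectory -> Gabriel haplotype blocks and block statistics
-> marker-density recommendation and genome-coverage summary.  The run is
fully deterministic: identical config and input produce byte-identical
report tables, and a manifest records the configuration, package version
and input checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genotype_io import GenotypeMatrix, allele_stats, read_ped_map, read_vcf, write_tables
from .hap_blocks import BlockConfig, block_stats, gabriel_blocks, recommended_marker_count
from .ld_core import pairwise_ld
from .ld_summaries import bin_by_distance, categorize, correlate_metrics, summarize_by_chromosome
from .ne_estimation import NeConfig, d2_f_correlation, ne_trajectory
from .qc import QCConfig, run_qc
from .relatedness import inbreeding, relationship_summary, vanraden_grm

__all__ = [
    "RunConfig",
    "ReportBundle",
    "StageError",
    "OVINE_GENOME_MB",
    "run_full_analysis",
    "genome_coverage",
    "load_genotypes",
]

log = logging.getLogger(__name__)

#: Total ovine genome length used for coverage and density headlines (Mb).
OVINE_GENOME_MB = 2615.52


class StageError(RuntimeError):
    """An analysis stage failed; carries the stage name."""

    def __init__(self, stage, cause):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclasses.dataclass
class RunConfig:
    """Inputs and per-stage configuration for a full run."""

    ped_path: str = None
    map_path: str = None
    vcf_path: str = None
    qc: QCConfig = dataclasses.field(default_factory=QCConfig)
    ne: NeConfig = dataclasses.field(default_factory=NeConfig)
    blocks: BlockConfig = dataclasses.field(default_factory=BlockConfig)
    genome_length_mb: float = OVINE_GENOME_MB
    decay_bin_edges_mb: tuple = tuple(np.round(np.arange(0.0, 4.0 + 1e-9, 0.1), 10))
    out_dir: str = None


@dataclasses.dataclass
class ReportBundle:
    """Every table the analysis produces, cross-consistent by construction."""

    qc_report: object
    chromosome_summary_adjacent: pd.DataFrame
    chromosome_summary_all: pd.DataFrame
    decay: pd.DataFrame
    categories: pd.DataFrame
    metric_correlation_adjacent: float
    metric_correlation_all: float
    inbreeding: object
    grm_summary: dict
    ne: object
    blocks: list
    block_stats: object
    recommended_markers: int
    coverage_span_mb: float
    coverage_percent: int
    d2_f_correlation_adjacent: float
    manifest: dict


def load_genotypes(run_config: RunConfig) -> GenotypeMatrix:
    """Load genotypes from the configured .ped/.map or VCF path."""
    if run_config.vcf_path:
        if not Path(run_config.vcf_path).exists():
            raise FileNotFoundError(run_config.vcf_path)
        return read_vcf(run_config.vcf_path)
    if run_config.ped_path and run_config.map_path:
        for p in (run_config.ped_path, run_config.map_path):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        return read_ped_map(run_config.ped_path, run_config.map_path)
    raise ValueError("run config names neither a VCF nor a .ped/.map pair")


def genome_coverage(markermap: pd.DataFrame, genome_length_mb: float,
                    span_mb: float = None):
    """Panel span and its percentage of the genome.

    Span is the per-chromosome (max - min position) summed, in Mb; the
    headline percentage is rounded to the nearest integer.  A known span
    may be supplied to override the computed one.
    """
    if genome_length_mb <= 0:
        raise ValueError("genome length must be positive")
    if len(markermap) == 0:
        raise ValueError("empty marker map")
    if span_mb is None:
        span_mb = float(
            markermap.groupby("chrom", sort=False)["pos"]
            .agg(lambda p: p.max() - p.min())
            .sum()
        ) / 1e6
    percent = int(np.floor(100.0 * span_mb / genome_length_mb + 0.5))
    return span_mb, percent


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise StageError(name, exc) from exc
        return wrapped
    return deco


def run_full_analysis(run_config: RunConfig, genotypes: GenotypeMatrix = None) -> ReportBundle:
    """Execute every stage and return (and optionally write) the bundle.

    ``genotypes`` may be passed directly (e.g. simulator output); otherwise
    the configured input files are read.  Any stage failure propagates as
    :class:`StageError` carrying the stage name.
    """
    manifest = {"ldscape_version": __version__, "inputs": {}}
    if genotypes is None:
        genotypes = _stage("load")(load_genotypes)(run_config)
        for key in ("ped_path", "map_path", "vcf_path"):
            p = getattr(run_config, key)
            if p:
                manifest["inputs"][key] = {"path": str(p), "sha256": _checksum(p)}
    manifest["config"] = {
        "qc": dataclasses.asdict(run_config.qc),
        "ne": dataclasses.asdict(run_config.ne),
        "blocks": dataclasses.asdict(run_config.blocks),
        "genome_length_mb": run_config.genome_length_mb,
    }

    log.info("QC on %d samples x %d markers", genotypes.n_individuals, genotypes.n_markers)
    filtered, qc_report = _stage("qc")(run_qc)(genotypes, run_config.qc)

    log.info("LD: adjacent and all within-chromosome pairs")
    ld_adj = _stage("ld_adjacent")(pairwise_ld)(filtered, mode="adjacent")
    ld_all = _stage("ld_all")(pairwise_ld)(filtered, mode="all")

    summ_adj = _stage("summaries")(summarize_by_chromosome)(ld_adj)
    summ_all = _stage("summaries")(summarize_by_chromosome)(ld_all)
    decay = _stage("summaries")(bin_by_distance)(ld_all, run_config.decay_bin_edges_mb)
    cats = _stage("summaries")(categorize)(ld_all)
    corr_adj = _stage("summaries")(correlate_metrics)(ld_adj)
    corr_all = _stage("summaries")(correlate_metrics)(ld_all)

    inb = _stage("inbreeding")(inbreeding)(filtered)
    grm = _stage("grm")(vanraden_grm)(filtered)
    grm_summary = _stage("grm")(relationship_summary)(grm)

    ne = _stage("ne")(ne_trajectory)(ld_all, run_config.ne, filtered.n_individuals)

    blocks = _stage("blocks")(gabriel_blocks)(filtered, run_config.blocks)
    bstats = _stage("blocks")(block_stats)(blocks)
    if bstats.n_blocks and np.isfinite(bstats.mean_spacing_mb) and bstats.mean_spacing_mb > 0:
        rec = recommended_marker_count(run_config.genome_length_mb, bstats.mean_spacing_mb)
    else:
        rec = 0

    span_mb, percent = _stage("coverage")(genome_coverage)(
        filtered.markers, run_config.genome_length_mb
    )

    # per-chromosome F and mean allele frequency feed the D^2-F relation
    st = allele_stats(filtered)
    try:
        per_chrom_f = _per_chromosome_f(filtered)
        freq = st.groupby("chrom", sort=False)["freq_a"].mean()
        d2f = d2_f_correlation(ld_adj, per_chrom_f, freq)
    except (ValueError, KeyError):
        d2f = float("nan")

    bundle = ReportBundle(
        qc_report=qc_report,
        chromosome_summary_adjacent=summ_adj,
        chromosome_summary_all=summ_all,
        decay=decay,
        categories=cats,
        metric_correlation_adjacent=corr_adj,
        metric_correlation_all=corr_all,
        inbreeding=inb,
        grm_summary=grm_summary,
        ne=ne,
        blocks=blocks,
        block_stats=bstats,
        recommended_markers=rec,
        coverage_span_mb=span_mb,
        coverage_percent=percent,
        d2_f_correlation_adjacent=d2f,
        manifest=manifest,
    )
    if run_config.out_dir:
        write_report_tables(bundle, run_config.out_dir)
    return bundle


def _per_chromosome_f(genotypes: GenotypeMatrix) -> pd.Series:
    """Population-mean F computed chromosome by chromosome."""
    mk = genotypes.markers
    values = {}
    for chrom in genotypes.chromosomes():
        idx = np.flatnonzero((mk["chrom"] == chrom).to_numpy())
        values[chrom] = inbreeding(genotypes.subset(marker_idx=idx)).mean_f
    return pd.Series(values)


def write_report_tables(bundle: ReportBundle, outdir) -> list:
    """Write the bundle as TSV tables plus a JSON manifest and summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    blocks_df = pd.DataFrame(
        [
            {
                "chrom": b.chrom,
                "start_bp": b.start_bp,
                "end_bp": b.end_bp,
                "n_markers": b.n_markers,
                "span_bp": b.span_bp,
                "mean_spacing_bp": b.mean_spacing_bp,
            }
            for b in bundle.blocks
        ],
        columns=["chrom", "start_bp", "end_bp", "n_markers", "span_bp", "mean_spacing_bp"],
    )
    hist = bundle.block_stats.size_histogram.rename("n_blocks").reset_index()
    tables = {
        "qc_per_chromosome": bundle.qc_report.per_chromosome,
        "chromosome_summary_adjacent": bundle.chromosome_summary_adjacent,
        "chromosome_summary_all": bundle.chromosome_summary_all,
        "ld_decay": bundle.decay,
        "ld_categories": bundle.categories,
        "inbreeding": bundle.inbreeding.table,
        "ne_trajectory": bundle.ne.table,
        "ne_per_chromosome": bundle.ne.per_chromosome,
        "blocks": blocks_df,
        "block_size_histogram": hist,
    }
    paths = write_tables(tables, outdir)

    scalars = {
        "metric_correlation_adjacent": bundle.metric_correlation_adjacent,
        "metric_correlation_all": bundle.metric_correlation_all,
        "mean_f": bundle.inbreeding.mean_f,
        "grm_summary": bundle.grm_summary,
        "recent_ne": bundle.ne.recent_ne,
        "recent_t": bundle.ne.recent_t,
        "n_blocks": bundle.block_stats.n_blocks,
        "block_mean_spacing_mb": bundle.block_stats.mean_spacing_mb,
        "recommended_markers": bundle.recommended_markers,
        "coverage_span_mb": bundle.coverage_span_mb,
        "coverage_percent": bundle.coverage_percent,
        "d2_f_correlation_adjacent": bundle.d2_f_correlation_adjacent,
        "samples_removed": bundle.qc_report.samples_removed,
        "markers_removed": bundle.qc_report.markers_removed,
    }
    summary_path = outdir / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(scalars, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return [*paths, summary_path, manifest_path]
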