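"""End-to-end orchestration: simulate -> backtrace -> quantify -> DE -> intervals.

The pipeline runs the stages in dependency order on either simulated or
user-supplied inputs, logs the resolved configuration, and writes a manifest
with per-stage wall-clock times and SHA-256 checksums of every output so that
reruns with identical config and seeds are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import backtrace, core, diffexpr, intervals, quant, simulate
from .amplicon import CutSiteSpec, estimate_editing

logger = logging.getLogger("terv")


# ---------------------------------------------------------------------------
# Default synthetic scenario (the study conditions every stage is tested under)
# ---------------------------------------------------------------------------

N_INJECTED = 10
N_NULL_SUBFAMILIES = 200
INJECTED_LOG2FC = 4.0
INJECTED_CLUSTER = "ExcN"
CLUSTERS = ("ExcN", "InhN", "Glia")
SAMPLES = {"ctl1": "control", "ctl2": "control", "ko1": "KO", "ko2": "KO"}
LIBRARY_MULTIPLIERS = {"ctl1": 1.0, "ctl2": 1.2, "ko1": 0.9, "ko2": 1.1}
TE_BASELINE_MEAN = 60.0
N_GENES = 30
CELLS_PER_CLUSTER = 40
BARCODE_LENGTH = 12


def default_scenario(
    seed: int,
) -> tuple[simulate.SimulatedGenome, simulate.ExpressionProgram,
           simulate.CellPopulation]:
    """Two control + two KO single-cell samples over three clusters.

    10 TE subfamilies are injected at log2FC = 4 in the ExcN cluster of KO
    samples among 200 null subfamilies; half of all subfamilies have two
    homologous copies (NH = 2 multimapping), half are single-copy. Two
    full-length LTR-internal-LTR elements provide interval-calling substrate.
    """
    n_sub = N_INJECTED + N_NULL_SUBFAMILIES
    tes = []
    for i in range(n_sub):
        grouped = i % 2 == 0
        tes.append(
            simulate.TECopySpec(
                subfamily=f"TE{i:03d}", family=f"FAM{i % 20}", te_class="LTR",
                n_copies=2 if grouped else 1, copy_length=1000,
                homology_group=f"hg{i}" if grouped else None,
            )
        )
    for j in range(2):
        tes.append(
            simulate.TECopySpec(
                subfamily=f"FLERV{j}", family="ERVK", te_class="LTR",
                n_copies=2, copy_length=6000, full_length=True,
                homology_group=f"flhg{j}",
            )
        )
    genes = [simulate.GeneSpec(f"Gene{g:02d}", length=2000,
                               strand="+" if g % 2 == 0 else "-")
             for g in range(N_GENES)]
    model = simulate.GenomeModel(
        chromosomes=[(f"chr{c}", 700_000) for c in range(1, 5)], seed=seed
    )
    genome = simulate.build_genome(model, genes, tes)

    gene_means = {g.name: 80.0 + 4.0 * (i % 15) for i, g in enumerate(genes)}
    te_means = {f"TE{i:03d}": TE_BASELINE_MEAN for i in range(n_sub)}
    injected = {
        (INJECTED_CLUSTER, f"TE{i:03d}"): INJECTED_LOG2FC for i in range(N_INJECTED)
    }
    program = simulate.ExpressionProgram(
        gene_baseline={c: gene_means for c in CLUSTERS},
        te_baseline={c: te_means for c in CLUSTERS},
        injected_log2fc=injected,
        library_multiplier=LIBRARY_MULTIPLIERS,
    )

    rng = np.random.default_rng(seed + 1)
    cells = []
    for sample in sorted(SAMPLES):
        bcs = simulate.random_barcodes(
            CELLS_PER_CLUSTER * len(CLUSTERS), BARCODE_LENGTH, rng
        )
        for ci, cluster in enumerate(CLUSTERS):
            for b in bcs[ci * CELLS_PER_CLUSTER : (ci + 1) * CELLS_PER_CLUSTER]:
                cells.append((sample, b, cluster))
    population = simulate.CellPopulation(cells=cells, condition=dict(SAMPLES))
    return genome, program, population


# ---------------------------------------------------------------------------
# Configuration and manifest
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    outdir: str = "terv_out"
    seed: int = 0
    force: bool = False
    # stage toggles
    run_simulate: bool = True
    run_amplicon: bool = False
    run_backtrace: bool = True
    run_quantify: bool = True
    run_de: bool = True
    run_intervals: bool = True
    # thresholds (defaults follow the analysis conventions documented per field)
    significance_mode: str = "cluster-te"  # padj < 0.01, log2FC > 3
    qc_nmads: float = 3.0
    em_tol: float = 1e-6
    em_max_iter: int = 100
    min_fraction: float = 0.5  # full-length overlap threshold
    fl_denominator: str = "internal"
    windows: tuple[int, ...] = intervals.DEFAULT_WINDOWS
    strandedness: str = "forward"  # single-cell pseudobulk protocol
    min_total_count: float = 10.0
    n_bins: int = 10
    # amplicon stage parameters
    amplicon_length: int = 200
    amplicon_cut_site: int = 100
    amplicon_indel_freq: float = 0.985
    amplicon_frameshift_frac: float = 0.8
    amplicon_n_reads: int = 5000
    amplicon_window: int = 10
    # external inputs when run_simulate is off
    alignments: str | None = None
    gene_gtf: str | None = None
    te_bed: str | None = None
    predictions_bed: str | None = None
    barcode_map: str | None = None
    conditions: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "windows" in raw:
            raw["windows"] = tuple(raw["windows"])
        return cls(**raw)

    def validate(self) -> None:
        if self.run_backtrace and not self.run_simulate and self.barcode_map is None:
            raise ValueError(
                "cluster back-tracing requested without a barcode map: enable "
                "run_simulate or provide barcode_map"
            )
        if not self.run_simulate and self.run_quantify and (
            self.alignments is None or self.gene_gtf is None or self.te_bed is None
        ):
            raise ValueError(
                "quantification without simulation needs alignments, gene_gtf "
                "and te_bed paths"
            )
        if self.run_de and not self.run_quantify:
            raise ValueError("differential expression requires the quantify stage")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    stages: list[dict] = field(default_factory=list)

    def record(self, name: str, outputs: list[Path], seconds: float) -> None:
        self.stages.append(
            {
                "stage": name,
                "wall_clock_s": round(seconds, 3),
                "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
            }
        )

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.config, "stages": self.stages}, fh, indent=2,
                      default=str)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _fresh(path: Path, force: bool) -> Path:
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; rerun with force=True to overwrite")
    return path


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the enabled stages in dependency order and write a manifest.

    Fails before any stage runs on contradictory configuration; on a stage
    failure, prior outputs are preserved.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config))
    logger.info("resolved config: %s", asdict(config))

    records = truth = genome = None
    bc_map: dict | None = None
    conditions: Mapping[str, str] = dict(config.conditions)

    if config.run_simulate:
        t0 = time.perf_counter()
        genome, program, cells = default_scenario(config.seed)
        records, truth = simulate.simulate_alignments(
            genome, program, cells, seed=config.seed + 2,
            strand_protocol=config.strandedness,
        )
        conditions = dict(cells.condition)
        bc_map = {(s, b): c for s, b, c in cells.cells}
        outputs = []
        p = _fresh(outdir / "genome.fa", config.force)
        core.write_fasta(p, genome.sequences); outputs.append(p)
        p = _fresh(outdir / "genes.gtf", config.force)
        core.write_gtf(p, genome.gene_exons); outputs.append(p)
        p = _fresh(outdir / "te_fragments.bed", config.force)
        core.write_te_bed(p, genome.te_fragments); outputs.append(p)
        p = _fresh(outdir / "predictions.bed", config.force)
        core.write_te_bed(p, genome.predictions); outputs.append(p)
        p = _fresh(outdir / "alignments.sam", config.force)
        core.write_sam(p, records, genome.chrom_lengths); outputs.append(p)
        p = _fresh(outdir / "barcode_map.tsv", config.force)
        pd.DataFrame(
            [(s, b, c) for (s, b), c in sorted(bc_map.items())],
            columns=["sample", "barcode", "cluster"],
        ).to_csv(p, sep="\t", index=False); outputs.append(p)
        p = _fresh(outdir / "truth.tsv", config.force)
        truth.to_tsv(p); outputs.append(p)
        manifest.record("simulate", outputs, time.perf_counter() - t0)
        logger.info("simulate: %d records, %d truth reads", len(records),
                    len(truth.reads))

    if config.run_amplicon:
        t0 = time.perf_counter()
        amp_records, amp_truth = simulate.simulate_amplicons(
            config.amplicon_length, config.amplicon_cut_site,
            config.amplicon_indel_freq, config.amplicon_frameshift_frac,
            config.amplicon_n_reads, seed=config.seed + 3,
        )
        site = CutSiteSpec("amplicon", config.amplicon_cut_site,
                           config.amplicon_window)
        summary = estimate_editing(amp_records, site)
        p = _fresh(outdir / "amplicon_summary.tsv", config.force)
        summary.to_frame("amplicon").to_csv(p, sep="\t", index=False)
        manifest.record("amplicon", [p], time.perf_counter() - t0)

    if config.run_simulate:
        index = quant.FeatureIndex(genome.gene_exons, genome.te_fragments)
    elif config.run_quantify:
        gene_exons = core.read_gene_gtf(config.gene_gtf)
        te_frags = core.read_te_bed(config.te_bed)
        index = quant.FeatureIndex(gene_exons, te_frags)
        records = list(core.read_sam(config.alignments))
        bc_map = (core.read_barcode_map(config.barcode_map)
                  if config.barcode_map else bc_map)

    partition = None
    if config.run_backtrace:
        t0 = time.perf_counter()
        detected = backtrace.genes_detected_from_records(
            records, index, config.strandedness
        )
        retained, verdicts = backtrace.qc_filter_cells(detected, config.qc_nmads)
        partition = backtrace.assign_reads_to_clusters(records, bc_map, retained)
        p = _fresh(outdir / "qc_verdicts.tsv", config.force)
        verdicts.to_csv(p, sep="\t", index=False)
        p2 = _fresh(outdir / "drop_report.tsv", config.force)
        partition.drop_report().to_csv(p2, sep="\t", index=False)
        manifest.record("backtrace", [p, p2], time.perf_counter() - t0)
        logger.info("backtrace: %d buckets, drops=%s", len(partition.buckets),
                    partition.dropped)

    gene_counts = te_counts = None
    if config.run_quantify:
        t0 = time.perf_counter()
        if partition is not None:
            gene_counts, te_counts = backtrace.build_pseudobulk_counts(
                partition, index, config.strandedness, conditions,
                em_max_iter=config.em_max_iter, em_tol=config.em_tol,
            )
        else:
            gene_counts = quant.count_genes_unique(records, index,
                                                   config.strandedness)
            te_counts = quant.count_te_em(
                records, index, config.strandedness,
                max_iter=config.em_max_iter, tol=config.em_tol,
            )
        p = _fresh(outdir / "gene_counts.tsv", config.force)
        gene_counts.to_csv(p, sep="\t")
        p2 = _fresh(outdir / "te_counts.tsv", config.force)
        te_counts.to_csv(p2, sep="\t")
        manifest.record("quantify", [p, p2], time.perf_counter() - t0)

    if config.run_de:
        t0 = time.perf_counter()
        outputs = []
        if isinstance(te_counts.columns, pd.MultiIndex):
            results = per_cluster_te_de(
                gene_counts, te_counts, conditions,
                min_total=config.min_total_count,
            )
            for cluster, df in results.items():
                called = diffexpr.call_significant(df, config.significance_mode)
                p = _fresh(outdir / f"de_te_{cluster}.tsv", config.force)
                called.to_csv(p, sep="\t")
                outputs.append(p)
        else:
            factors = diffexpr.size_factors_median_ratio(gene_counts)
            df = diffexpr.run_de(te_counts, conditions, factors,
                                 reference="control",
                                 min_total=config.min_total_count)
            called = diffexpr.call_significant(df, "bulk")
            p = _fresh(outdir / "de_te_bulk.tsv", config.force)
            called.to_csv(p, sep="\t")
            outputs.append(p)
        manifest.record("de", outputs, time.perf_counter() - t0)

    if config.run_intervals and (config.run_simulate or config.predictions_bed):
        t0 = time.perf_counter()
        if config.run_simulate:
            preds = genome.predictions
            internals = [iv for iv in genome.te_fragments
                         if iv.subfamily and iv.subfamily.endswith("-int")]
            chrom_lengths = genome.chrom_lengths
        else:
            preds = core.read_te_bed(config.predictions_bed, kind="full_length")
            internals = [iv for iv in core.read_te_bed(config.te_bed)
                         if iv.subfamily and iv.subfamily.endswith("-int")]
            chrom_lengths = None
        calls = intervals.call_full_length(
            preds, internals, config.min_fraction, config.fl_denominator
        )
        p = _fresh(outdir / "full_length_calls.tsv", config.force)
        intervals.calls_to_frame(calls).to_csv(p, sep="\t", index=False)
        outputs = [p]
        if chrom_lengths is not None and records is not None:
            depth = intervals.depth_from_records(records, chrom_lengths)
            passing = intervals.passing_predictions(calls)
            fl_elements = [iv for iv in preds if iv.feature_id in passing]
            if fl_elements:
                mat = intervals.coverage_matrix(
                    depth, fl_elements, n_bins=config.n_bins,
                    library_size=len({r.name for r in records}),
                )
                p2 = _fresh(outdir / "coverage_matrix.tsv", config.force)
                mat.to_csv(p2, sep="\t")
                outputs.append(p2)
        manifest.record("intervals", outputs, time.perf_counter() - t0)

    manifest_path = outdir / "manifest.json"
    manifest.write(manifest_path)
    return manifest


def per_cluster_te_de(
    gene_counts: pd.DataFrame,
    te_counts: pd.DataFrame,
    conditions: Mapping[str, str],
    min_total: float = 10.0,
    reference: str = "control",
) -> dict[str, pd.DataFrame]:
    """NB Wald DE of TE subfamilies within each cluster.

    Size factors come from the *gene* pseudobulk counts of the same cluster
    columns; TE counts are tested with those gene-derived factors as offsets.
    """
    clusters = sorted({c for _, c in te_counts.columns})
    out: dict[str, pd.DataFrame] = {}
    for cluster in clusters:
        cols = [col for col in te_counts.columns if col[1] == cluster]
        genes_c = gene_counts[cols]
        tes_c = te_counts[cols]
        factors = diffexpr.size_factors_median_ratio(genes_c)
        cond_map = {col: conditions[col[0]] for col in cols}
        out[cluster] = diffexpr.run_de(
            tes_c, cond_map, factors, reference=reference, min_total=min_total
        )
    return out
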