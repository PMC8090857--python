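"""Cell QC and per-cluster pseudobulk back-tracing of barcoded alignments.

Clustering itself is an upstream input (a (sample, barcode) -> cluster table);
this module quality-filters cells on genes detected, then routes every
alignment record of a retained cell to its cluster's read bucket so each
bucket can be quantified like a bulk library. Multimapped records of one read
travel together (the EM counter needs the full multiplicity set).
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core import AlignmentRecord
from . import quant

# scale factor making the median absolute deviation consistent with the
# normal distribution's standard deviation
_MAD_SCALE = 1.4826022185056018


def qc_filter_cells(
    genes_detected: Mapping[tuple[str, str], int] | pd.Series,
    nmads: float = 3.0,
    log_scale: bool = True,
    lower: bool = True,
    upper: bool = True,
) -> tuple[set, pd.DataFrame]:
    """Retain cells whose genes-detected lies within median +/- nmads * MAD.

    The statistic is log2(genes detected + 1) by default, and the MAD is
    scaled for consistency with the normal distribution. When every cell is
    identical the MAD is 0 and zero deviation stays within the band, so all
    cells are retained. Raises if fewer than 3 cells are given or nothing
    survives.
    """
    if isinstance(genes_detected, pd.Series):
        keys = list(genes_detected.index)
        values = genes_detected.to_numpy(float)
    else:
        keys = list(genes_detected.keys())
        values = np.array([genes_detected[k] for k in keys], float)
    if len(keys) < 3:
        raise ValueError("QC needs at least 3 cells")
    x = np.log2(values + 1.0) if log_scale else values
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med))) * _MAD_SCALE
    dev = x - med
    keep = np.ones(len(x), bool)
    if lower:
        keep &= dev >= -nmads * mad
    if upper:
        keep &= dev <= nmads * mad
    retained = {k for k, ok in zip(keys, keep) if ok}
    if not retained:
        raise ValueError("QC removed every cell")
    verdicts = pd.DataFrame(
        {"cell": keys, "genes_detected": values, "statistic": x,
         "deviation": dev, "retained": keep}
    )
    return retained, verdicts


def genes_detected_from_records(
    records: Iterable[AlignmentRecord],
    index: quant.FeatureIndex,
    strandedness: str = "forward",
) -> pd.Series:
    """Genes detected per (sample, barcode) from unique unambiguous gene reads."""
    genes: dict[tuple[str, str], set[str]] = defaultdict(set)
    for rec in records:
        if not rec.mapped or rec.barcode is None or rec.nh != 1:
            continue
        hits = index.overlapping_genes(rec, strandedness)
        if len(hits) == 1:
            genes[(quant._sample_of(rec), rec.barcode)].add(next(iter(hits)))
    keys = sorted(genes)
    return pd.Series([len(genes[k]) for k in keys],
                     index=pd.MultiIndex.from_tuples(keys), dtype=int)


@dataclass
class PseudobulkPartition:
    """Per-(cluster, sample) read buckets plus drop accounting."""

    buckets: dict[tuple[str, str], list[AlignmentRecord]]  # (cluster, sample)
    dropped: dict[str, int] = field(
        default_factory=lambda: {
            "no_barcode": 0, "barcode_not_in_map": 0, "cell_failed_qc": 0,
            "unmapped": 0,
        }
    )

    @property
    def clusters(self) -> list[str]:
        return sorted({c for c, _ in self.buckets})

    @property
    def samples(self) -> list[str]:
        return sorted({s for _, s in self.buckets})

    def n_assigned_reads(self) -> int:
        return sum(len({r.name for r in recs}) for recs in self.buckets.values())

    def drop_report(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"reason": list(self.dropped), "reads": list(self.dropped.values())}
        )


def assign_reads_to_clusters(
    records: Iterable[AlignmentRecord],
    barcode_map: Mapping[tuple[str, str], str],
    retained_cells: set | None = None,
) -> PseudobulkPartition:
    """Partition reads into per-cluster buckets keyed by (cluster, sample).

    All records sharing a read name within a sample go to the same bucket.
    Reads lacking a barcode tag, carrying a barcode absent from the map, or
    belonging to a QC-failed cell are counted in the drop ledger instead.
    ``retained_cells=None`` skips the QC gate.
    """
    if not barcode_map:
        raise ValueError("barcode map is empty")
    by_read: dict[tuple[str, str], list[AlignmentRecord]] = defaultdict(list)
    partition = PseudobulkPartition(buckets=defaultdict(list))
    for rec in records:
        if not rec.mapped:
            partition.dropped["unmapped"] += 1
            continue
        by_read[(quant._sample_of(rec), rec.name)].append(rec)

    for (sample, _name), recs in by_read.items():
        barcode = next((r.barcode for r in recs if r.barcode is not None), None)
        if barcode is None:
            partition.dropped["no_barcode"] += 1
            continue
        key = (sample, barcode)
        if key not in barcode_map:
            partition.dropped["barcode_not_in_map"] += 1
            continue
        if retained_cells is not None and key not in retained_cells:
            partition.dropped["cell_failed_qc"] += 1
            continue
        partition.buckets[(barcode_map[key], sample)].extend(recs)
    partition.buckets = dict(partition.buckets)
    return partition


def build_pseudobulk_counts(
    partition: PseudobulkPartition,
    index: quant.FeatureIndex,
    strandedness: str = "forward",
    conditions: Mapping[str, str] | None = None,
    em_max_iter: int = 100,
    em_tol: float = 1e-6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify each (sample, cluster) bucket: unique gene counts + TE EM counts.

    Returns (gene matrix, TE subfamily matrix) with identical MultiIndex
    columns (sample, cluster); ``attrs['condition']`` maps samples to their
    condition when given. Empty buckets yield zero columns with a warning.
    """
    if not partition.buckets:
        raise ValueError("empty partition")
    columns = sorted((s, c) for c, s in partition.buckets)
    gene_cols, te_cols = {}, {}
    for sample, cluster in columns:
        recs = partition.buckets[(cluster, sample)]
        if not recs:
            warnings.warn(f"empty bucket ({sample}, {cluster})", RuntimeWarning)
            gene_cols[(sample, cluster)] = pd.Series(0, index=index.gene_ids)
            te_cols[(sample, cluster)] = pd.Series(0.0, index=index.subfamilies)
            continue
        g = quant.count_genes_unique(recs, index, strandedness)
        t = quant.count_te_em(recs, index, strandedness,
                              max_iter=em_max_iter, tol=em_tol)
        gene_cols[(sample, cluster)] = g.iloc[:, 0] if g.shape[1] else pd.Series(
            0, index=index.gene_ids)
        te_cols[(sample, cluster)] = t.iloc[:, 0] if t.shape[1] else pd.Series(
            0.0, index=index.subfamilies)
    midx = pd.MultiIndex.from_tuples(columns, names=["sample", "cluster"])
    genes = pd.DataFrame(
        {c: gene_cols[c] for c in columns},
        index=pd.Index(index.gene_ids, name="feature"),
    ).fillna(0).astype(np.int64)
    tes = pd.DataFrame(
        {c: te_cols[c] for c in columns},
        index=pd.Index(index.subfamilies, name="feature"),
    ).fillna(0.0)
    genes.columns = midx
    tes.columns = midx
    if conditions is not None:
        genes.attrs["condition"] = dict(conditions)
        tes.attrs["condition"] = dict(conditions)
    return genes, tes
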