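"""Full-length ERV calling, neighbor-gene windows, and binned coverage matrices.

All interval arithmetic is 0-based half-open. Full-length calling intersects
internal-region TE fragments with full-length ERV predictions and keeps
predictions where the overlap fraction reaches a threshold (default 0.5). The
denominator of the fraction is the internal fragment's length by default,
switchable to the prediction's length — both conventions are exposed because
overlap-fraction tools differ in which interval anchors the fraction.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import AlignmentRecord, AnnotationInterval, parse_cigar
from .diffexpr import wilcoxon_rank_sum


# ---------------------------------------------------------------------------
# Full-length calling
# ---------------------------------------------------------------------------

@dataclass
class FullLengthCall:
    """One prediction/internal-fragment overlap with its fraction and verdict."""

    prediction_id: str
    internal_id: str
    overlap_bp: int
    fraction: float
    passed: bool
    borderline: bool  # fraction exactly at the threshold


def call_full_length(
    predictions: Sequence[AnnotationInterval],
    internal_fragments: Sequence[AnnotationInterval],
    min_fraction: float = 0.5,
    denominator: str = "internal",
) -> list[FullLengthCall]:
    """Score every overlapping (prediction, internal fragment) pair.

    fraction = overlap_bp / len(internal) (default) or / len(prediction).
    A pair passes when fraction >= min_fraction; exact ties are flagged
    ``borderline``. A prediction is a full-length call when any of its pairs
    passes (see :func:`passing_predictions`).
    """
    if denominator not in ("internal", "prediction"):
        raise ValueError("denominator must be 'internal' or 'prediction'")
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for iv in internal_fragments:
        trees[iv.chrom].addi(iv.start, iv.end, iv)
    calls: list[FullLengthCall] = []
    for pred in predictions:
        for hit in sorted(trees[pred.chrom].overlap(pred.start, pred.end),
                          key=lambda h: (h.begin, h.end, h.data.feature_id)):
            frag = hit.data
            overlap = min(pred.end, frag.end) - max(pred.start, frag.start)
            denom = (frag.end - frag.start) if denominator == "internal" else (
                pred.end - pred.start)
            f = overlap / denom
            calls.append(
                FullLengthCall(
                    prediction_id=pred.feature_id,
                    internal_id=frag.feature_id,
                    overlap_bp=overlap,
                    fraction=f,
                    passed=f >= min_fraction,
                    borderline=f == min_fraction,
                )
            )
    return calls


def passing_predictions(calls: Iterable[FullLengthCall]) -> set[str]:
    return {c.prediction_id for c in calls if c.passed}


def calls_to_frame(calls: Iterable[FullLengthCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(prediction=c.prediction_id, internal=c.internal_id,
                 overlap_bp=c.overlap_bp, fraction=c.fraction, passed=c.passed,
                 borderline=c.borderline)
            for c in calls
        ],
        columns=["prediction", "internal", "overlap_bp", "fraction", "passed",
                 "borderline"],
    )


# ---------------------------------------------------------------------------
# Neighbor-gene windows
# ---------------------------------------------------------------------------

DEFAULT_WINDOWS = (10_000, 20_000, 50_000)


@dataclass
class WindowResult:
    """Genes near upregulated vs non-upregulated elements at one window width."""

    w: int
    genes_near_up: set[str]
    genes_near_other: set[str]
    lfc_near_up: np.ndarray
    lfc_near_other: np.ndarray
    ranksum_stat: float
    ranksum_p: float


def genes_in_window(
    element: AnnotationInterval,
    gene_tree: IntervalTree,
    w: int,
) -> set[str]:
    """Genes whose span overlaps [element_start - w, element_end + w).

    Strand is ignored; w = 0 reduces to direct overlap.
    """
    lo = max(0, element.start - w)
    hi = element.end + w
    return {hit.data for hit in gene_tree.overlap(lo, hi)}


def _gene_span_trees(
    genes: Iterable[AnnotationInterval],
) -> dict[str, IntervalTree]:
    spans: dict[str, tuple[str, int, int]] = {}
    for iv in genes:
        if iv.gene in spans:
            chrom, s, e = spans[iv.gene]
            spans[iv.gene] = (chrom, min(s, iv.start), max(e, iv.end))
        else:
            spans[iv.gene] = (iv.chrom, iv.start, iv.end)
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for gene, (chrom, s, e) in spans.items():
        trees[chrom].addi(s, e, gene)
    return trees


def neighbor_gene_windows(
    elements: Sequence[AnnotationInterval],
    upregulated_ids: set[str],
    genes: Sequence[AnnotationInterval],
    gene_log2fc: Mapping[str, float],
    windows: Sequence[int] = DEFAULT_WINDOWS,
) -> dict[int, WindowResult]:
    """Compare gene log2FC near upregulated vs non-upregulated elements.

    For each window half-width w, collects the genes overlapping
    [start - w, end + w) of each element, splits them by element status, and
    compares the two log2FC distributions with a two-sided rank-sum test.
    A gene near elements of both statuses contributes to both sets.
    """
    trees = _gene_span_trees(genes)
    out: dict[int, WindowResult] = {}
    for w in windows:
        near_up: set[str] = set()
        near_other: set[str] = set()
        for el in elements:
            target = near_up if el.feature_id in upregulated_ids else near_other
            target |= genes_in_window(el, trees[el.chrom], w)
        lfc_up = np.array([gene_log2fc[g] for g in sorted(near_up)
                           if g in gene_log2fc])
        lfc_other = np.array([gene_log2fc[g] for g in sorted(near_other)
                              if g in gene_log2fc])
        if len(lfc_up) and len(lfc_other):
            stat, p = wilcoxon_rank_sum(lfc_up, lfc_other)
        else:
            stat, p = np.nan, np.nan
        out[w] = WindowResult(w, near_up, near_other, lfc_up, lfc_other, stat, p)
    return out


# ---------------------------------------------------------------------------
# Coverage matrices
# ---------------------------------------------------------------------------

def depth_from_records(
    records: Iterable[AlignmentRecord],
    chrom_lengths: Sequence[tuple[str, int]],
) -> dict[str, np.ndarray]:
    """Per-base reference coverage from aligned (M/=/X) CIGAR footprints."""
    depth = {name: np.zeros(length) for name, length in chrom_lengths}
    for rec in records:
        if not rec.mapped or rec.chrom not in depth:
            continue
        pos = rec.start
        arr = depth[rec.chrom]
        for op, n in parse_cigar(rec.cigar):
            if op in "M=X":
                arr[pos : pos + n] += 1
                pos += n
            elif op in "DN":
                pos += n
    return depth


def coverage_matrix(
    depth: Mapping[str, np.ndarray],
    elements: Sequence[AnnotationInterval],
    n_bins: int = 10,
    library_size: float | None = None,
    flip_minus: bool = False,
) -> pd.DataFrame:
    """Scale each element to ``n_bins`` equal bins of mean per-base coverage.

    Bin boundaries may be fractional for short elements; the bin value is the
    exact average of the per-base depth over the (real-valued) bin interval.
    ``library_size`` rescales depth to per-million-mapped-reads so that jointly
    doubling depth and library size leaves the matrix unchanged.
    ``flip_minus`` reverses bin order for minus-strand elements.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    scale = 1.0 if library_size is None else 1e6 / library_size
    rows = np.zeros((len(elements), n_bins))
    prefix: dict[str, np.ndarray] = {}
    for chrom, arr in depth.items():
        prefix[chrom] = np.concatenate([[0.0], np.cumsum(arr)])

    def cum(chrom: str, x: float) -> float:
        p = prefix[chrom]
        arr = depth[chrom]
        i = int(np.floor(x))
        i = min(max(i, 0), len(arr))
        frac = x - i
        base = p[i]
        if 0 <= i < len(arr) and frac > 0:
            base += frac * arr[i]
        return float(base)

    for r, el in enumerate(elements):
        width = (el.end - el.start) / n_bins
        for b in range(n_bins):
            lo = el.start + b * width
            hi = el.start + (b + 1) * width
            rows[r, b] = (cum(el.chrom, hi) - cum(el.chrom, lo)) / width
        if flip_minus and el.strand == "-":
            rows[r] = rows[r, ::-1]
    rows *= scale
    return pd.DataFrame(
        rows,
        index=pd.Index([el.feature_id for el in elements], name="element"),
        columns=[f"bin{b}" for b in range(n_bins)],
    )


def sort_rows_by_group_max(
    matrices: Mapping[str, pd.DataFrame], group: Sequence[str]
) -> list[str]:
    """Row order (descending) by each element's maximum bin value over the
    named sample group — e.g. sort a coverage heatmap by KO-sample maxima."""
    if not group:
        raise ValueError("empty sample group")
    stacked = np.stack([matrices[s].to_numpy() for s in group])
    key = stacked.max(axis=(0, 2))
    index = matrices[group[0]].index
    order = np.argsort(-key, kind="stable")
    return [index[i] for i in order]
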