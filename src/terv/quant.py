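"""Read counting over genes, TE elements, and TE subfamilies.

Three regimes:

* ``count_genes_unique`` — uniquely mapped reads (NH=1) over gene exons, with
  strand-aware overlap and discard of reads ambiguous between genes.
* ``count_elements_unique`` — the same rule over individual TE element
  intervals (and full-length predictions when supplied).
* ``count_te_em`` — subfamily-level counting where multimapped reads are
  fractionally assigned by expectation-maximization: each read carries total
  mass 1, unique reads pin their subfamily, and ambiguous reads are split in
  proportion to the current subfamily abundance estimates until the counts
  stabilize.

A read's candidate subfamily set is the set of subfamilies of TE fragments any
of its alignments overlaps by >= 1 bp with compatible strand, deduplicated at
the subfamily level.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import AlignmentRecord, AnnotationInterval

STRANDEDNESS = ("forward", "reverse", "unstranded")


def _strand_compatible(read_strand: str, feature_strand: str, mode: str) -> bool:
    if mode == "unstranded":
        return True
    if mode == "forward":
        return read_strand == feature_strand
    if mode == "reverse":
        return read_strand != feature_strand
    raise ValueError(f"unknown strandedness {mode!r}; expected one of {STRANDEDNESS}")


class FeatureIndex:
    """Interval lookup over gene exons and TE fragments.

    Gene exons and TE fragments are indexed independently: a read overlapping
    both is countable in both regimes (the gene matrix and the TE matrix are
    separate).
    """

    def __init__(
        self,
        gene_exons: Iterable[AnnotationInterval] = (),
        te_fragments: Iterable[AnnotationInterval] = (),
        elements: Iterable[AnnotationInterval] | None = None,
    ):
        self._gene_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._te_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._element_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self.gene_ids: list[str] = []
        self.subfamilies: list[str] = []
        self.element_ids: list[str] = []
        self.hierarchy: dict[str, tuple[str | None, str | None]] = {}

        seen_genes: set[str] = set()
        for iv in gene_exons:
            self._gene_trees[iv.chrom].addi(iv.start, iv.end, iv)
            if iv.gene not in seen_genes:
                seen_genes.add(iv.gene)
                self.gene_ids.append(iv.gene)
        seen_sub: set[str] = set()
        te_fragments = list(te_fragments)
        for iv in te_fragments:
            if iv.subfamily is None:
                raise ValueError(f"TE fragment {iv.feature_id} lacks a subfamily")
            self._te_trees[iv.chrom].addi(iv.start, iv.end, iv)
            if iv.subfamily not in seen_sub:
                seen_sub.add(iv.subfamily)
                self.subfamilies.append(iv.subfamily)
            self.hierarchy[iv.subfamily] = (iv.family, iv.te_class)
        element_ivs = te_fragments if elements is None else list(elements)
        seen_el: set[str] = set()
        for iv in element_ivs:
            self._element_trees[iv.chrom].addi(iv.start, iv.end, iv)
            if iv.feature_id not in seen_el:
                seen_el.add(iv.feature_id)
                self.element_ids.append(iv.feature_id)

    def _query(
        self, trees, rec: AlignmentRecord, strandedness: str
    ) -> list[AnnotationInterval]:
        tree = trees.get(rec.chrom)
        if tree is None:
            return []
        hits = tree.overlap(rec.start, rec.end)
        return [
            h.data
            for h in hits
            if _strand_compatible(rec.strand, h.data.strand, strandedness)
        ]

    def overlapping_genes(self, rec: AlignmentRecord, strandedness: str) -> set[str]:
        return {iv.gene for iv in self._query(self._gene_trees, rec, strandedness)}

    def overlapping_subfamilies(
        self, rec: AlignmentRecord, strandedness: str
    ) -> set[str]:
        return {
            iv.subfamily for iv in self._query(self._te_trees, rec, strandedness)
        }

    def overlapping_elements(self, rec: AlignmentRecord, strandedness: str) -> set[str]:
        return {
            iv.feature_id
            for iv in self._query(self._element_trees, rec, strandedness)
        }


def _sample_of(rec: AlignmentRecord) -> str:
    return rec.sample if rec.sample is not None else "sample"


def _unique_feature_counts(
    records: Iterable[AlignmentRecord],
    lookup,
    feature_ids: Sequence[str],
    provenance: str,
) -> pd.DataFrame:
    counts: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    samples: list[str] = []
    seen_samples: set[str] = set()
    for rec in records:
        if not rec.mapped:
            continue
        sample = _sample_of(rec)
        if sample not in seen_samples:
            seen_samples.add(sample)
            samples.append(sample)
        if rec.nh != 1:
            continue
        hits = lookup(rec)
        if len(hits) == 1:
            counts[sample][next(iter(hits))] += 1
    df = pd.DataFrame(
        {s: [counts[s].get(f, 0) for f in feature_ids] for s in samples},
        index=pd.Index(feature_ids, name="feature"),
        dtype=np.int64,
    )
    df.attrs["provenance"] = provenance
    return df


def count_genes_unique(
    records: Iterable[AlignmentRecord],
    index: FeatureIndex,
    strandedness: str = "reverse",
) -> pd.DataFrame:
    """Integer gene counts from uniquely mapped reads.

    A record counts once for a gene when it overlaps any exon of that gene with
    compatible strand; records hitting exons of more than one gene are dropped
    as ambiguous. The bulk default is ``reverse`` (dUTP-stranded libraries);
    single-cell pseudobulk uses ``forward``.
    """
    return _unique_feature_counts(
        records,
        lambda rec: index.overlapping_genes(rec, strandedness),
        index.gene_ids,
        "unique-genes",
    )


def count_elements_unique(
    records: Iterable[AlignmentRecord],
    index: FeatureIndex,
    strandedness: str = "reverse",
) -> pd.DataFrame:
    """Integer counts over individual TE elements (unique reads only)."""
    return _unique_feature_counts(
        records,
        lambda rec: index.overlapping_elements(rec, strandedness),
        index.element_ids,
        "unique-elements",
    )


def count_te_em(
    records: Iterable[AlignmentRecord],
    index: FeatureIndex,
    strandedness: str = "reverse",
    max_iter: int = 100,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Subfamily counts with EM redistribution of multimapped reads.

    Every read contributes total mass 1 over its candidate subfamilies. Reads
    whose candidate set is a single subfamily contribute 1 there; ambiguous
    reads are split proportionally to the current abundance estimates,
    iterating until the largest per-subfamily count change is below ``tol``
    (or ``max_iter``, in which case a warning is issued and the result carries
    ``attrs['converged'][sample] = False``).
    """
    by_sample: dict[str, dict[str, set[str]]] = defaultdict(dict)
    samples: list[str] = []
    seen: set[str] = set()
    for rec in records:
        if not rec.mapped:
            continue
        sample = _sample_of(rec)
        if sample not in seen:
            seen.add(sample)
            samples.append(sample)
        cands = index.overlapping_subfamilies(rec, strandedness)
        if not cands:
            continue
        read_sets = by_sample[sample]
        if rec.name in read_sets:
            read_sets[rec.name] |= cands
        else:
            read_sets[rec.name] = set(cands)

    subfams = list(index.subfamilies)
    pos = {s: i for i, s in enumerate(subfams)}
    data = np.zeros((len(subfams), len(samples)))
    converged: dict[str, bool] = {}

    for j, sample in enumerate(samples):
        unique = np.zeros(len(subfams))
        ambiguous: dict[tuple[int, ...], int] = defaultdict(int)
        for cands in by_sample[sample].values():
            if len(cands) == 1:
                unique[pos[next(iter(cands))]] += 1
            else:
                ambiguous[tuple(sorted(pos[c] for c in cands))] += 1
        counts = unique.copy()
        for cs, n in ambiguous.items():  # uniform initial split
            counts[list(cs)] += n / len(cs)
        ok = True
        if ambiguous:
            ok = False
            for _ in range(max_iter):
                new = unique.copy()
                for cs, n in sorted(ambiguous.items()):
                    idx = list(cs)
                    tot = counts[idx].sum()
                    if tot <= 0:
                        new[idx] += n / len(cs)
                    else:
                        new[idx] += n * counts[idx] / tot
                delta = np.abs(new - counts).max()
                counts = new
                if delta < tol:
                    ok = True
                    break
        if not ok:
            warnings.warn(
                f"EM did not converge for sample {sample} within {max_iter} "
                "iterations", RuntimeWarning,
            )
        converged[sample] = ok
        data[:, j] = counts

    df = pd.DataFrame(
        data, index=pd.Index(subfams, name="feature"), columns=samples
    )
    df.attrs["provenance"] = "te-em"
    df.attrs["converged"] = converged
    return df
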