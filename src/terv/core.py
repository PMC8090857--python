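"""Shared domain types and on-disk format I/O.

Coordinate conventions
----------------------
All coordinates are 0-based half-open in memory. On disk, BED stays 0-based
half-open, GTF is shifted to 1-based closed, and SAM positions are handled by
pysam (which exposes 0-based starts in its API).

Alignments travel through the package as lightweight :class:`AlignmentRecord`
objects; pysam is used at the SAM boundary only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
import pyranges as pr
import pysam

# Tag conventions: NH is the SAM-standard hit count; CB is the droplet-pipeline
# corrected cell barcode. Both are overridable where they are consumed.
NH_TAG = "NH"
DEFAULT_BARCODE_TAG = "CB"
SAMPLE_TAG = "RG"

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

# CIGAR ops that consume reference / query bases
_REF_OPS = set("MDN=X")
_QUERY_OPS = set("MIS=X")


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    """Parse a CIGAR string into (op, length) pairs, validating coverage."""
    pairs = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar)]
    if "".join(f"{n}{op}" for op, n in pairs) != cigar:
        raise ValueError(f"malformed CIGAR: {cigar!r}")
    return pairs


def cigar_reference_length(cigar: str) -> int:
    """Number of reference bases consumed by a CIGAR string."""
    return sum(n for op, n in parse_cigar(cigar) if op in _REF_OPS)


@dataclass
class AlignmentRecord:
    """One mapped read segment.

    ``nh`` is the read's total alignment multiplicity (SAM NH); a read name
    with ``nh=k`` appears in exactly k records. ``barcode`` is the corrected
    cell barcode for single-cell data, ``None`` for bulk.
    """

    name: str
    chrom: str
    start: int  # 0-based
    cigar: str
    strand: str = "+"
    nh: int = 1
    barcode: str | None = None
    sample: str | None = None
    mapped: bool = True

    @property
    def end(self) -> int:
        return self.start + cigar_reference_length(self.cigar)


@dataclass
class AnnotationInterval:
    """A genomic feature: gene exon, TE fragment, or full-length ERV prediction.

    TE fragments carry the subfamily -> family -> class hierarchy; gene exons
    carry ``gene``. ``kind`` is one of ``gene``, ``te``, ``full_length``.
    """

    chrom: str
    start: int
    end: int
    strand: str
    feature_id: str
    kind: str
    gene: str | None = None
    subfamily: str | None = None
    family: str | None = None
    te_class: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"malformed interval {self.feature_id}: [{self.start}, {self.end})"
            )


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def sam_header(chrom_lengths: Sequence[tuple[str, int]]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": name, "LN": length} for name, length in chrom_lengths],
        }
    )


def write_sam(
    path: str | Path,
    records: Iterable[AlignmentRecord],
    chrom_lengths: Sequence[tuple[str, int]],
    barcode_tag: str = DEFAULT_BARCODE_TAG,
) -> None:
    header = sam_header(chrom_lengths)
    refs = {name: i for i, (name, _) in enumerate(chrom_lengths)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            seg = pysam.AlignedSegment(header)
            seg.query_name = rec.name
            if not rec.mapped:
                seg.is_unmapped = True
                out.write(seg)
                continue
            seg.reference_id = refs[rec.chrom]
            seg.reference_start = rec.start
            seg.cigarstring = rec.cigar
            seg.is_reverse = rec.strand == "-"
            seg.mapping_quality = 255
            tags: list[tuple[str, object]] = [(NH_TAG, rec.nh)]
            if rec.barcode is not None:
                tags.append((barcode_tag, rec.barcode))
            if rec.sample is not None:
                tags.append((SAMPLE_TAG, rec.sample))
            seg.set_tags(tags)
            out.write(seg)


def read_sam(
    path: str | Path,
    barcode_tag: str = DEFAULT_BARCODE_TAG,
    sample: str | None = None,
) -> Iterator[AlignmentRecord]:
    """Stream a SAM/BAM file as AlignmentRecords.

    ``sample`` overrides the per-record RG tag when the file is single-sample.
    """
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped:
                yield AlignmentRecord(
                    name=seg.query_name, chrom="*", start=0, cigar="",
                    mapped=False, sample=sample,
                )
                continue
            yield AlignmentRecord(
                name=seg.query_name,
                chrom=seg.reference_name,
                start=seg.reference_start,
                cigar=seg.cigarstring,
                strand="-" if seg.is_reverse else "+",
                nh=seg.get_tag(NH_TAG) if seg.has_tag(NH_TAG) else 1,
                barcode=seg.get_tag(barcode_tag) if seg.has_tag(barcode_tag) else None,
                sample=sample
                or (seg.get_tag(SAMPLE_TAG) if seg.has_tag(SAMPLE_TAG) else None),
            )


# ---------------------------------------------------------------------------
# FASTA / GTF / BED / TSV
# ---------------------------------------------------------------------------

def write_fasta(path: str | Path, sequences: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gtf(path: str | Path, intervals: Iterable[AnnotationInterval]) -> None:
    """Write gene/TE intervals as GTF (1-based closed on disk)."""
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.kind == "gene":
                attrs = f'gene_id "{iv.gene}"; transcript_id "{iv.gene}.t1";'
                feature = "exon"
            else:
                attrs = (
                    f'gene_id "{iv.subfamily}"; transcript_id "{iv.feature_id}"; '
                    f'family_id "{iv.family}"; class_id "{iv.te_class}";'
                )
                feature = "exon"
            fh.write(
                f"{iv.chrom}\tterv\t{feature}\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )


def read_gene_gtf(path: str | Path) -> list[AnnotationInterval]:
    """Read exon records from a gene GTF into annotation intervals."""
    df = pr.read_gtf(str(path)).df
    df = df[df.Feature == "exon"]
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        out.append(
            AnnotationInterval(
                chrom=str(row.Chromosome), start=int(row.Start), end=int(row.End),
                strand=str(row.Strand), feature_id=f"{row.gene_id}.exon{i}",
                kind="gene", gene=str(row.gene_id),
            )
        )
    return out


TE_BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand",
                  "subfamily", "family", "class"]

_EXCLUDED_TE_CLASSES = {"Simple_repeat", "rRNA", "scRNA", "snRNA", "srpRNA", "tRNA"}


def write_te_bed(path: str | Path, intervals: Iterable[AnnotationInterval]) -> None:
    """TE fragments / full-length predictions as BED6+3 (0-based half-open)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                "\t".join(
                    [iv.chrom, str(iv.start), str(iv.end), iv.feature_id, "0",
                     iv.strand, iv.subfamily or ".", iv.family or ".",
                     iv.te_class or "."]
                )
                + "\n"
            )


def read_te_bed(
    path: str | Path, kind: str = "te", exclude_noncoding_repeats: bool = False
) -> list[AnnotationInterval]:
    """Read a BED6+3 TE annotation.

    ``exclude_noncoding_repeats`` drops simple repeats and structural-RNA
    repeat classes (rRNA, scRNA, snRNA, srpRNA, tRNA), mirroring curated TE
    annotation sets that keep only transposon-derived intervals.
    """
    df = pd.read_csv(str(path), sep="\t", header=None, names=TE_BED_COLUMNS)
    out = []
    for row in df.itertuples(index=False):
        te_class = None if row[8] == "." else str(row[8])
        if exclude_noncoding_repeats and te_class in _EXCLUDED_TE_CLASSES:
            continue
        out.append(
            AnnotationInterval(
                chrom=str(row.chrom), start=int(row.start), end=int(row.end),
                strand=str(row.strand), feature_id=str(row.name), kind=kind,
                subfamily=None if row.subfamily == "." else str(row.subfamily),
                family=None if row.family == "." else str(row.family),
                te_class=te_class,
            )
        )
    return out


def read_barcode_map(path: str | Path) -> dict[tuple[str, str], str]:
    """TSV with columns sample, barcode, cluster -> {(sample, barcode): cluster}."""
    df = pd.read_csv(str(path), sep="\t", dtype=str)
    required = {"sample", "barcode", "cluster"}
    if not required.issubset(df.columns):
        raise ValueError(f"barcode map needs columns {sorted(required)}")
    return {(r.sample, r.barcode): r.cluster for r in df.itertuples(index=False)}
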