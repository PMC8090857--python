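"""CRISPR amplicon editing quantification.

A read is *edited* when its alignment carries at least one insertion or
deletion whose reference footprint (deletions) or anchor position (insertions)
falls within a window around the guide cut site. Multiple indels in one read
are combined by net length (sum of insertions minus deletions inside the
window), and the net length decides the frameshift call: net % 3 != 0 under
mathematical modulo, so -4 shifts the frame while -3 and +6 do not.
Substitutions and soft-clipped bases never count as edits; unmapped reads are
excluded from the denominator and reported separately.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .core import AlignmentRecord, parse_cigar


@dataclass
class CutSiteSpec:
    """Guide cut site (0-based, between bases) and classification half-width."""

    chrom: str
    cut: int
    window: int = 10

    def __post_init__(self) -> None:
        if self.window < 0:
            raise ValueError("window half-width must be >= 0")


@dataclass
class AmpliconEditingSummary:
    n_reads: int
    n_edited: int
    n_frameshift: int
    n_unmapped: int
    indel_length_histogram: dict[int, int] = field(default_factory=dict)

    @property
    def indel_frequency(self) -> float:
        return self.n_edited / self.n_reads

    @property
    def frameshift_fraction(self) -> float:
        return self.n_frameshift / self.n_edited if self.n_edited else float("nan")

    def to_frame(self, label: str = "site") -> pd.DataFrame:
        return pd.DataFrame(
            [{
                "site": label, "n_reads": self.n_reads, "n_edited": self.n_edited,
                "indel_frequency": self.indel_frequency,
                "frameshift_fraction": self.frameshift_fraction,
                "n_unmapped": self.n_unmapped,
            }]
        )


def is_frameshift(net_indel: int) -> bool:
    """Net indel lengths that are not multiples of 3 disrupt the reading frame."""
    return net_indel % 3 != 0


def classify_read(record: AlignmentRecord, site: CutSiteSpec) -> tuple[bool, int]:
    """(edited, net indel length) for one aligned read.

    Walks the CIGAR tracking the reference position; a deletion counts when its
    footprint [pos, pos+len) intersects [cut-w, cut+w], an insertion when its
    anchor lies in that window.
    """
    if not record.mapped:
        raise ValueError("classify_read requires a mapped record")
    lo, hi = site.cut - site.window, site.cut + site.window
    pos = record.start
    net = 0
    edited = False
    for op, n in parse_cigar(record.cigar):
        if op == "I":
            if lo <= pos <= hi:
                edited = True
                net += n
        elif op == "D":
            if pos <= hi and pos + n > lo:  # footprint intersects window
                edited = True
                net -= n
            pos += n
        elif op in "MN=X":
            pos += n
        # S/H/P consume no reference
    return edited, net


def estimate_editing(
    records: Iterable[AlignmentRecord], site: CutSiteSpec
) -> AmpliconEditingSummary:
    """Aggregate per-read classifications into an editing summary."""
    n_reads = n_edited = n_fs = n_unmapped = 0
    hist: Counter[int] = Counter()
    for rec in records:
        if not rec.mapped:
            n_unmapped += 1
            continue
        n_reads += 1
        edited, net = classify_read(rec, site)
        if edited:
            n_edited += 1
            hist[net] += 1
            if is_frameshift(net):
                n_fs += 1
    if n_reads == 0:
        raise ValueError("no evaluable (mapped) reads")
    return AmpliconEditingSummary(
        n_reads=n_reads, n_edited=n_edited, n_frameshift=n_fs,
        n_unmapped=n_unmapped, indel_length_histogram=dict(sorted(hist.items())),
    )
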