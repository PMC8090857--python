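"""Synthetic genomes, barcoded multimapping alignments, and edited amplicons.

Every downstream stage of the package is exercised on data from this module,
which records per-read ground truth so that quantification, back-tracing,
differential expression and editing summaries can be checked exactly.

The generator emits alignment records directly (no sequence-level read
simulation and no aligner): read positions, CIGARs, multiplicity tags and cell
barcodes are drawn from the declared expression program. Multimapping is
modelled through *homology groups*: TE copies in one group are
alignment-indistinguishable, so a read from any member is emitted once per
member with NH equal to the group size.

Counts per (sample, cluster, feature) are negative-binomial with mean
``baseline * 2^log2FC * library_multiplier`` and variance ``mu + alpha*mu^2``
— the same mean/dispersion parameterization the differential-expression
module fits, so parameter recovery is well-posed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import AlignmentRecord, AnnotationInterval


class PlacementError(ValueError):
    """A feature could not be placed inside its chromosome."""


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class GenomeModel:
    """Chromosome names/lengths and the master RNG seed."""

    chromosomes: list[tuple[str, int]]
    seed: int = 0

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")


@dataclass
class GeneSpec:
    name: str
    length: int
    strand: str = "+"
    chrom: str | None = None  # None: assigned round-robin


@dataclass
class TECopySpec:
    """A TE subfamily with ``n_copies`` genomic copies.

    ``homology_group``: copies sharing a group label are emitted as
    indistinguishable alignment targets (multimapping). ``full_length`` copies
    are emitted as adjacent LTR-internal-LTR fragment triplets plus a
    full-length prediction interval spanning the triplet; the internal fragment
    gets subfamily ``<subfamily>-int`` and the LTRs ``<subfamily>-LTR``.
    """

    subfamily: str
    family: str
    te_class: str
    n_copies: int
    copy_length: int
    homology_group: str | None = None
    full_length: bool = False
    ltr_length: int = 400
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.n_copies < 1:
            raise ValueError(f"{self.subfamily}: n_copies must be >= 1")
        if self.full_length and self.copy_length <= 2 * self.ltr_length:
            raise ValueError(
                f"{self.subfamily}: full-length copy needs length > 2*ltr_length"
            )


@dataclass
class ExpressionProgram:
    """Expected read counts per feature, per cluster, with injected effects.

    ``gene_baseline[cluster][gene]`` and ``te_baseline[cluster][subfamily]``
    are expected reads in a control sample at library multiplier 1.
    ``injected_log2fc[(cluster, subfamily)]`` applies to KO samples only;
    absent pairs are null (log2FC = 0). ``dispersion`` is the NB alpha per
    feature kind ('gene' / 'te').
    """

    gene_baseline: Mapping[str, Mapping[str, float]]
    te_baseline: Mapping[str, Mapping[str, float]]
    injected_log2fc: Mapping[tuple[str, str], float] = field(default_factory=dict)
    dispersion: Mapping[str, float] = field(
        default_factory=lambda: {"gene": 0.05, "te": 0.05}
    )
    library_multiplier: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for table in (self.gene_baseline, self.te_baseline):
            for cluster, vec in table.items():
                if any(v < 0 for v in vec.values()):
                    raise ValueError(f"negative baseline in cluster {cluster}")
        if any(a <= 0 for a in self.dispersion.values()):
            raise ValueError("dispersion must be positive")


@dataclass
class CellPopulation:
    """Barcoded cells: (sample, barcode) -> cluster, plus sample conditions."""

    cells: list[tuple[str, str, str]]  # (sample, barcode, cluster)
    condition: Mapping[str, str]  # sample -> 'control' | 'KO'

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for sample, barcode, _ in self.cells:
            key = (sample, barcode)
            if key in seen:
                raise ValueError(f"duplicate barcode {barcode} in sample {sample}")
            seen.add(key)

    @property
    def clusters(self) -> set[str]:
        return {c for _, _, c in self.cells}

    @property
    def samples(self) -> list[str]:
        return sorted({s for s, _, _ in self.cells})

    def barcodes_by(self, sample: str, cluster: str) -> list[str]:
        return sorted(b for s, b, c in self.cells if s == sample and c == cluster)


def random_barcodes(n: int, length: int, rng: np.random.Generator) -> list[str]:
    """n distinct fixed-length ACGT barcodes."""
    bases = np.array(list("ACGT"))
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        bc = "".join(rng.choice(bases, size=length))
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


@dataclass
class SimulationTruth:
    """Ground-truth ledger: one record per emitted read."""

    reads: pd.DataFrame  # columns: name, feature_id, subfamily, kind, cluster, sample
    amplicon_reads: pd.DataFrame | None = None  # name, edited, net_indel
    injected_log2fc: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.reads.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

@dataclass
class SimulatedGenome:
    sequences: dict[str, str]
    gene_exons: list[AnnotationInterval]
    te_fragments: list[AnnotationInterval]
    predictions: list[AnnotationInterval]  # full-length ERV predictions
    # homology: fragment feature_id -> list of equivalent fragments (incl. self)
    homology: dict[str, list[AnnotationInterval]]

    @property
    def chrom_lengths(self) -> list[tuple[str, int]]:
        return [(name, len(seq)) for name, seq in self.sequences.items()]

    @property
    def annotations(self) -> list[AnnotationInterval]:
        return self.gene_exons + self.te_fragments


def _place(
    rng: np.random.Generator,
    occupied: dict[str, list[tuple[int, int]]],
    chrom: str,
    chrom_len: int,
    length: int,
    label: str,
    tries: int = 2000,
) -> int:
    if length > chrom_len:
        raise PlacementError(f"{label}: length {length} exceeds {chrom} ({chrom_len})")
    for _ in range(tries):
        start = int(rng.integers(0, chrom_len - length + 1))
        end = start + length
        if all(end <= s or start >= e for s, e in occupied[chrom]):
            occupied[chrom].append((start, end))
            return start
    raise PlacementError(f"{label}: no non-overlapping placement on {chrom}")


def build_genome(
    model: GenomeModel,
    genes: Sequence[GeneSpec],
    tes: Sequence[TECopySpec],
) -> SimulatedGenome:
    """Place genes and TE copies on random-sequence chromosomes.

    Copies of one homology group share length and sequence content. Placement
    is rejection-sampled without overlaps; an impossible placement raises
    :class:`PlacementError` naming the offending feature.
    """
    rng = np.random.default_rng(model.seed)
    bases = np.array(list("ACGT"))
    seqs = {
        name: rng.choice(bases, size=length)
        for name, length in model.chromosomes
    }
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n, _ in model.chromosomes}
    chrom_len = dict(model.chromosomes)
    chrom_cycle = itertools.cycle([n for n, _ in model.chromosomes])

    gene_exons: list[AnnotationInterval] = []
    for spec in genes:
        chrom = spec.chrom or next(chrom_cycle)
        start = _place(rng, occupied, chrom, chrom_len[chrom], spec.length, spec.name)
        gene_exons.append(
            AnnotationInterval(
                chrom=chrom, start=start, end=start + spec.length,
                strand=spec.strand, feature_id=f"{spec.name}.exon1",
                kind="gene", gene=spec.name,
            )
        )

    te_fragments: list[AnnotationInterval] = []
    predictions: list[AnnotationInterval] = []
    # (homology_group, role) -> fragments; singletons get a unique key
    homology_slots: dict[tuple[str, str], list[AnnotationInterval]] = {}

    for spec in tes:
        group_template = rng.choice(bases, size=spec.copy_length)
        for i in range(spec.n_copies):
            copy_id = f"{spec.subfamily}#{i}"
            chrom = next(chrom_cycle)
            start = _place(
                rng, occupied, chrom, chrom_len[chrom], spec.copy_length, copy_id
            )
            end = start + spec.copy_length
            if spec.homology_group is not None:
                seqs[chrom][start:end] = group_template
            gkey = spec.homology_group or f"__solo_{copy_id}"
            if spec.full_length:
                L = spec.ltr_length
                frags = [
                    ("LTR", start, start + L, f"{copy_id}/LTR5",
                     f"{spec.subfamily}-LTR"),
                    ("int", start + L, end - L, f"{copy_id}/int",
                     f"{spec.subfamily}-int"),
                    ("LTR", end - L, end, f"{copy_id}/LTR3",
                     f"{spec.subfamily}-LTR"),
                ]
                predictions.append(
                    AnnotationInterval(
                        chrom=chrom, start=start, end=end, strand=spec.strand,
                        feature_id=f"{copy_id}/pred", kind="full_length",
                        subfamily=spec.subfamily, family=spec.family,
                        te_class=spec.te_class,
                    )
                )
            else:
                frags = [("copy", start, end, copy_id, spec.subfamily)]
            for role, s, e, fid, subfam in frags:
                iv = AnnotationInterval(
                    chrom=chrom, start=s, end=e, strand=spec.strand,
                    feature_id=fid, kind="te", subfamily=subfam,
                    family=spec.family, te_class=spec.te_class,
                )
                te_fragments.append(iv)
                homology_slots.setdefault((gkey, role), []).append(iv)

    homology = {
        iv.feature_id: group
        for group in homology_slots.values()
        for iv in group
    }
    return SimulatedGenome(
        sequences={n: "".join(s) for n, s in seqs.items()},
        gene_exons=gene_exons,
        te_fragments=te_fragments,
        predictions=predictions,
        homology=homology,
    )


# ---------------------------------------------------------------------------
# Alignment simulation
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: float, alpha: float) -> int:
    if mean <= 0:
        return 0
    if alpha < 1e-12:
        return int(rng.poisson(mean))
    n = 1.0 / alpha
    p = 1.0 / (1.0 + alpha * mean)
    return int(rng.negative_binomial(n, p))


def _read_interval(
    rng: np.random.Generator, iv: AnnotationInterval, read_length: int
) -> tuple[int, int]:
    """Uniform read placement fully inside the feature (clipped to length)."""
    length = min(read_length, iv.end - iv.start)
    offset = int(rng.integers(0, (iv.end - iv.start) - length + 1))
    return offset, length


def simulate_alignments(
    genome: SimulatedGenome,
    program: ExpressionProgram,
    cells: CellPopulation | None,
    seed: int,
    read_length: int = 80,
    strand_protocol: str = "forward",
) -> tuple[list[AlignmentRecord], SimulationTruth]:
    """Draw NB counts per (sample, cluster, feature) and emit alignment records.

    ``cells=None`` runs bulk mode: the program must be keyed by cluster
    ``"bulk"`` and sample conditions are taken from
    ``program.library_multiplier`` keys with condition encoded via
    ``bulk_conditions`` on the program — for bulk use
    :func:`simulate_bulk_alignments` instead.
    """
    if cells is None:
        raise ValueError("use simulate_bulk_alignments for bulk mode")
    missing = cells.clusters - set(program.gene_baseline) | (
        cells.clusters - set(program.te_baseline)
    )
    if missing:
        raise ValueError(f"clusters missing from expression program: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    sub_fragments: dict[str, list[AnnotationInterval]] = {}
    for iv in genome.te_fragments:
        sub_fragments.setdefault(iv.subfamily, []).append(iv)
    gene_by_name: dict[str, list[AnnotationInterval]] = {}
    for iv in genome.gene_exons:
        gene_by_name.setdefault(iv.gene, []).append(iv)

    records: list[AlignmentRecord] = []
    truth_rows: list[dict] = []
    counter = itertools.count()

    def emit_gene_read(gene: str, sample: str, cluster: str, barcode: str | None):
        name = f"r{next(counter):09d}"
        exons = gene_by_name[gene]
        iv = exons[int(rng.integers(0, len(exons)))]
        offset, length = _read_interval(rng, iv, read_length)
        strand = iv.strand if strand_protocol == "forward" else (
            "-" if iv.strand == "+" else "+"
        )
        records.append(
            AlignmentRecord(
                name=name, chrom=iv.chrom, start=iv.start + offset,
                cigar=f"{length}M", strand=strand, nh=1,
                barcode=barcode, sample=sample,
            )
        )
        truth_rows.append(
            dict(name=name, feature_id=gene, subfamily="", kind="gene",
                 cluster=cluster, sample=sample)
        )

    def emit_te_read(subfamily: str, sample: str, cluster: str, barcode: str | None):
        name = f"r{next(counter):09d}"
        frags = sub_fragments[subfamily]
        origin = frags[int(rng.integers(0, len(frags)))]
        group = genome.homology[origin.feature_id]
        offset, length = _read_interval(rng, origin, read_length)
        # homologous copies may be shorter at the shared offset only if lengths
        # differ; groups share length by construction so the offset is valid
        strand_of = lambda iv: iv.strand if strand_protocol == "forward" else (
            "-" if iv.strand == "+" else "+"
        )
        for iv in group:
            records.append(
                AlignmentRecord(
                    name=name, chrom=iv.chrom, start=iv.start + offset,
                    cigar=f"{length}M", strand=strand_of(iv), nh=len(group),
                    barcode=barcode, sample=sample,
                )
            )
        truth_rows.append(
            dict(name=name, feature_id=origin.feature_id, subfamily=subfamily,
                 kind="te", cluster=cluster, sample=sample)
        )

    for sample in cells.samples:
        cond = cells.condition[sample]
        lib = program.library_multiplier.get(sample, 1.0)
        for cluster in sorted(cells.clusters):
            barcodes = cells.barcodes_by(sample, cluster)
            if not barcodes:
                continue
            pick_bc = lambda: barcodes[int(rng.integers(0, len(barcodes)))]
            for gene in sorted(program.gene_baseline[cluster]):
                mean = program.gene_baseline[cluster][gene] * lib
                count = _nb_draw(rng, mean, program.dispersion["gene"])
                for _ in range(count):
                    emit_gene_read(gene, sample, cluster, pick_bc())
            for subfamily in sorted(program.te_baseline[cluster]):
                if subfamily not in sub_fragments:
                    raise ValueError(f"unknown subfamily in program: {subfamily}")
                mean = program.te_baseline[cluster][subfamily] * lib
                if cond != "control":
                    lfc = program.injected_log2fc.get((cluster, subfamily), 0.0)
                    mean *= 2.0 ** lfc
                count = _nb_draw(rng, mean, program.dispersion["te"])
                for _ in range(count):
                    emit_te_read(subfamily, sample, cluster, pick_bc())

    truth = SimulationTruth(
        reads=pd.DataFrame(
            truth_rows,
            columns=["name", "feature_id", "subfamily", "kind", "cluster", "sample"],
        ),
        injected_log2fc=dict(program.injected_log2fc),
    )
    return records, truth


def simulate_bulk_alignments(
    genome: SimulatedGenome,
    program: ExpressionProgram,
    sample_conditions: Mapping[str, str],
    seed: int,
    read_length: int = 80,
    strand_protocol: str = "reverse",
) -> tuple[list[AlignmentRecord], SimulationTruth]:
    """Bulk mode: one pseudo-cell per sample, no barcode tags.

    The program must be keyed by the single cluster ``"bulk"``.
    """
    cells = CellPopulation(
        cells=[(s, f"BULK{s}", "bulk") for s in sorted(sample_conditions)],
        condition=dict(sample_conditions),
    )
    records, truth = simulate_alignments(
        genome, program, cells, seed, read_length, strand_protocol
    )
    for rec in records:
        rec.barcode = None
    return records, truth


# ---------------------------------------------------------------------------
# Amplicon simulation
# ---------------------------------------------------------------------------

DEFAULT_INDEL_LENGTHS = tuple(range(-10, 0)) + tuple(range(1, 11))


def simulate_amplicons(
    amplicon_length: int,
    cut_site: int,
    indel_freq: float,
    frameshift_frac: float,
    n_reads: int,
    seed: int,
    indel_lengths: Sequence[int] = DEFAULT_INDEL_LENGTHS,
    amplicon_name: str = "amplicon",
) -> tuple[list[AlignmentRecord], SimulationTruth]:
    """Emit amplicon reads with a controlled indel rate at the cut site.

    Each read spans the full amplicon. Edited reads carry one insertion or
    deletion anchored at ``cut_site`` (0-based, between bases); the net indel
    length is frameshifting (length mod 3 != 0) with probability
    ``frameshift_frac`` among edits.
    """
    if not (0 <= indel_freq <= 1 and 0 <= frameshift_frac <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    if not 0 < cut_site < amplicon_length:
        raise ValueError(
            f"cut site {cut_site} outside amplicon of length {amplicon_length}"
        )
    if any(l == 0 for l in indel_lengths):
        raise ValueError("indel lengths must be nonzero")
    fs_lengths = [l for l in indel_lengths if l % 3 != 0]
    if_lengths = [l for l in indel_lengths if l % 3 == 0]
    if indel_freq > 0:
        if frameshift_frac > 0 and not fs_lengths:
            raise ValueError("no frameshifting lengths available")
        if frameshift_frac < 1 and not if_lengths:
            raise ValueError("no in-frame lengths available")
    max_del = max((-l for l in indel_lengths if l < 0), default=0)
    if cut_site + max_del > amplicon_length:
        raise ValueError("deletions would run past the amplicon end")

    rng = np.random.default_rng(seed)
    records: list[AlignmentRecord] = []
    rows: list[dict] = []
    for i in range(n_reads):
        name = f"amp{i:07d}"
        edited = bool(rng.random() < indel_freq)
        net = 0
        if edited:
            pool = fs_lengths if rng.random() < frameshift_frac else if_lengths
            net = int(pool[int(rng.integers(0, len(pool)))])
            if net > 0:
                cigar = f"{cut_site}M{net}I{amplicon_length - cut_site}M"
            else:
                cigar = f"{cut_site}M{-net}D{amplicon_length - cut_site + net}M"
        else:
            cigar = f"{amplicon_length}M"
        records.append(
            AlignmentRecord(name=name, chrom=amplicon_name, start=0, cigar=cigar)
        )
        rows.append(dict(name=name, edited=edited, net_indel=net))

    truth = SimulationTruth(
        reads=pd.DataFrame(
            columns=["name", "feature_id", "subfamily", "kind", "cluster", "sample"]
        ),
        amplicon_reads=pd.DataFrame(rows, columns=["name", "edited", "net_indel"]),
    )
    return records, truth
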