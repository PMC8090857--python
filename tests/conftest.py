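import numpy as np
import pytest

from terv.core import AlignmentRecord, AnnotationInterval
from terv.quant import FeatureIndex


def make_read(
    name, chrom="chr1", start=0, length=50, strand="+", nh=1,
    barcode=None, sample="s1", cigar=None,
):
    return AlignmentRecord(
        name=name, chrom=chrom, start=start,
        cigar=cigar or f"{length}M", strand=strand, nh=nh,
        barcode=barcode, sample=sample,
    )


@pytest.fixture
def toy_annotation():
    """Two chromosomes with two genes and three TE subfamilies.

    subA has two homologous copies (chr1:5000, chr2:5000); subB and subC are
    single-copy. geneA overlaps nothing; geneB's exon overlaps the subC copy.
    """
    genes = [
        AnnotationInterval("chr1", 1000, 2000, "+", "geneA.e1", "gene", gene="geneA"),
        AnnotationInterval("chr2", 1000, 2000, "-", "geneB.e1", "gene", gene="geneB"),
    ]
    tes = [
        AnnotationInterval("chr1", 5000, 6000, "+", "subA#0", "te",
                           subfamily="subA", family="famA", te_class="LTR"),
        AnnotationInterval("chr2", 5000, 6000, "+", "subA#1", "te",
                           subfamily="subA", family="famA", te_class="LTR"),
        AnnotationInterval("chr1", 8000, 9000, "+", "subB#0", "te",
                           subfamily="subB", family="famB", te_class="LTR"),
        AnnotationInterval("chr2", 1500, 2500, "-", "subC#0", "te",
                           subfamily="subC", family="famC", te_class="LINE"),
    ]
    return genes, tes


@pytest.fixture
def toy_index(toy_annotation):
    genes, tes = toy_annotation
    return FeatureIndex(genes, tes)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
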