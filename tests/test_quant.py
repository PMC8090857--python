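"""Unique counting vs brute-force overlap scans, and EM vs fixed-point oracle."""

import numpy as np
import pytest

from terv.core import AnnotationInterval
from terv.quant import (
    FeatureIndex,
    count_elements_unique,
    count_genes_unique,
    count_te_em,
)
from tests.conftest import make_read


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def em_fixed_point_oracle(unique, ambiguous, tol=1e-9, max_iter=50_000):
    """Direct fixed-point iteration on subfamily counts, independent of the
    package's EM loop: c_s = unique_s + sum over ambiguous sets containing s of
    n * c_s / sum_{t in set} c_t, from a uniform split until the largest count
    change drops below tol. Boundary fixed points (a subfamily decaying to 0)
    converge sublinearly, so the oracle uses the same stopping rule as the
    implementation under test rather than a fixed iteration count."""
    subs = sorted(set(unique) | {s for cs, _ in ambiguous for s in cs})
    c = {s: float(unique.get(s, 0)) for s in subs}
    for cs, n in ambiguous:
        for s in cs:
            c[s] += n / len(cs)
    for _ in range(max_iter):
        new = {s: float(unique.get(s, 0)) for s in subs}
        for cs, n in ambiguous:
            tot = sum(c[s] for s in cs)
            for s in cs:
                new[s] += n / len(cs) if tot == 0 else n * c[s] / tot
        delta = max(abs(new[s] - c[s]) for s in subs)
        c = new
        if delta < tol:
            break
    return c


def brute_force_unique(records, intervals, key, strandedness):
    """Quadratic scan: NH=1 records assigned when exactly one feature overlaps."""
    counts = {}
    for rec in records:
        if rec.nh != 1 or not rec.mapped:
            continue
        hits = set()
        for iv in intervals:
            if iv.chrom != rec.chrom:
                continue
            if rec.start < iv.end and iv.start < rec.end:
                if strandedness == "unstranded" or (
                    (rec.strand == iv.strand) == (strandedness == "forward")
                ):
                    hits.add(key(iv))
        if len(hits) == 1:
            h = hits.pop()
            counts[h] = counts.get(h, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Unique counting
# ---------------------------------------------------------------------------

class TestUniqueCounting:
    def test_unique_read_in_exon_counts_once(self, toy_index):
        recs = [make_read("r1", "chr1", 1200, strand="+")]
        counts = count_genes_unique(recs, toy_index, "forward")
        assert counts.loc["geneA", "s1"] == 1
        assert counts.loc["geneB", "s1"] == 0

    def test_multimapped_read_not_counted(self, toy_index):
        recs = [
            make_read("r1", "chr1", 1200, nh=2),
            make_read("r1", "chr2", 5100, nh=2),
        ]
        counts = count_genes_unique(recs, toy_index, "forward")
        assert int(counts.to_numpy().sum()) == 0

    def test_wrong_strand_not_counted(self, toy_index):
        recs = [make_read("r1", "chr1", 1200, strand="-")]
        assert count_genes_unique(recs, toy_index, "forward").loc["geneA", "s1"] == 0
        assert count_genes_unique(recs, toy_index, "reverse").loc["geneA", "s1"] == 1
        assert count_genes_unique(recs, toy_index, "unstranded").loc["geneA", "s1"] == 1

    def test_read_over_two_genes_discarded_as_ambiguous(self):
        genes = [
            AnnotationInterval("c", 100, 300, "+", "a.e", "gene", gene="a"),
            AnnotationInterval("c", 250, 500, "+", "b.e", "gene", gene="b"),
        ]
        index = FeatureIndex(genes, [])
        recs = [make_read("r1", "c", 240, length=30)]
        assert int(count_genes_unique(recs, index, "forward").sum().sum()) == 0

    def test_nh4_read_over_element_not_counted(self, toy_index):
        recs = [make_read("r1", "chr1", 5100, nh=4)]
        counts = count_elements_unique(recs, toy_index, "unstranded")
        assert int(counts.to_numpy().sum()) == 0

    def test_random_fixture_equals_brute_force(self, toy_annotation, rng):
        genes, tes = toy_annotation
        index = FeatureIndex(genes, tes)
        recs = [
            make_read(
                f"r{i}",
                chrom=rng.choice(["chr1", "chr2"]),
                start=int(rng.integers(0, 9500)),
                length=int(rng.integers(30, 120)),
                strand=rng.choice(["+", "-"]),
                nh=int(rng.choice([1, 1, 1, 2, 4])),
            )
            for i in range(500)
        ]
        for strandedness in ("forward", "reverse", "unstranded"):
            got = count_elements_unique(recs, index, strandedness)["s1"]
            expect = brute_force_unique(
                recs, tes, lambda iv: iv.feature_id, strandedness
            )
            for fid in got.index:
                assert got[fid] == expect.get(fid, 0)
            got_g = count_genes_unique(recs, index, strandedness)["s1"]
            expect_g = brute_force_unique(
                recs, genes, lambda iv: iv.gene, strandedness
            )
            for gid in got_g.index:
                assert got_g[gid] == expect_g.get(gid, 0)


# ---------------------------------------------------------------------------
# EM counting
# ---------------------------------------------------------------------------

def em_instance(index_intervals, reads):
    """Build records for (candidate tuple) reads over synthetic one-subfamily
    intervals on distinct chromosomes, where a read listing k subfamilies gets
    k records (NH=k), one on each subfamily's interval."""
    records = []
    for i, cands in enumerate(reads):
        for sub in cands:
            iv = index_intervals[sub]
            records.append(
                make_read(f"r{i}", chrom=iv.chrom, start=iv.start + 1,
                          length=10, nh=len(cands), strand="+")
            )
    return records


@pytest.fixture
def abc_intervals():
    ivs = {
        name: AnnotationInterval(f"chr_{name}", 100, 1000, "+", f"{name}#0",
                                 "te", subfamily=name, family="f", te_class="LTR")
        for name in "ABC"
    }
    return ivs


class TestEMCounting:
    def test_symmetric_split(self, abc_intervals):
        index = FeatureIndex([], list(abc_intervals.values()))
        records = em_instance(abc_intervals, [("A", "B")])
        counts = count_te_em(records, index, "forward")["s1"]
        assert counts["A"] == pytest.approx(0.5)
        assert counts["B"] == pytest.approx(0.5)

    def test_worked_fixed_point_six_two(self, abc_intervals):
        # unique A=3, B=1 plus 4 A/B-ambiguous reads: w = (3+4w)/8 -> A=6, B=2
        index = FeatureIndex([], [abc_intervals["A"], abc_intervals["B"]])
        reads = [("A",)] * 3 + [("B",)] + [("A", "B")] * 4
        counts = count_te_em(em_instance(abc_intervals, reads), index, "forward")
        assert counts.loc["A", "s1"] == pytest.approx(6.0, abs=1e-5)
        assert counts.loc["B", "s1"] == pytest.approx(2.0, abs=1e-5)

    def test_no_ambiguity_reduces_to_unique_counting(self, abc_intervals):
        index = FeatureIndex([], list(abc_intervals.values()))
        reads = [("A",)] * 5 + [("B",)] * 2 + [("C",)] * 3
        counts = count_te_em(em_instance(abc_intervals, reads), index, "forward")
        assert counts["s1"].tolist() == [5.0, 2.0, 3.0]

    def test_order_invariance(self, abc_intervals, rng):
        index = FeatureIndex([], list(abc_intervals.values()))
        reads = [("A",)] * 3 + [("B",)] + [("A", "B")] * 4 + [("A", "B", "C")] * 5
        records = em_instance(abc_intervals, reads)
        base = count_te_em(records, index, "forward")
        for _ in range(3):
            perm = [records[i] for i in rng.permutation(len(records))]
            again = count_te_em(perm, index, "forward")
            assert np.allclose(base.to_numpy(), again.to_numpy())

    def test_matches_fixed_point_oracle_on_random_instances(self, abc_intervals, rng):
        index = FeatureIndex([], list(abc_intervals.values()))
        subsets = [("A",), ("B",), ("C",), ("A", "B"), ("A", "C"), ("B", "C"),
                   ("A", "B", "C")]
        for _ in range(150):
            n_reads = int(rng.integers(1, 21))
            reads = [subsets[int(rng.integers(0, len(subsets)))]
                     for _ in range(n_reads)]
            counts = count_te_em(em_instance(abc_intervals, reads), index,
                                 "forward", max_iter=50_000, tol=1e-9)["s1"]
            unique = {}
            ambiguous = {}
            for cands in reads:
                if len(cands) == 1:
                    unique[cands[0]] = unique.get(cands[0], 0) + 1
                else:
                    ambiguous[cands] = ambiguous.get(cands, 0) + 1
            oracle = em_fixed_point_oracle(unique, list(ambiguous.items()))
            for sub, val in oracle.items():
                assert counts[sub] == pytest.approx(val, abs=1e-6)
            assert counts.sum() == pytest.approx(n_reads, abs=1e-9)

    def test_mass_conservation_random_fixtures(self, toy_annotation, rng):
        genes, tes = toy_annotation
        index = FeatureIndex(genes, tes)
        for _ in range(20):
            recs = []
            n = int(rng.integers(5, 80))
            for i in range(n):
                if rng.random() < 0.5:  # homologous subA pair
                    off = int(rng.integers(0, 950))
                    recs += [
                        make_read(f"m{i}", "chr1", 5000 + off, nh=2),
                        make_read(f"m{i}", "chr2", 5000 + off, nh=2),
                    ]
                else:
                    recs.append(make_read(
                        f"u{i}", rng.choice(["chr1", "chr2"]),
                        int(rng.integers(0, 9000)), length=60))
            counts = count_te_em(recs, index, "unstranded")
            n_te_reads = len({
                r.name for r in recs
                if index.overlapping_subfamilies(r, "unstranded")
            })
            assert counts.to_numpy().sum() == pytest.approx(n_te_reads, abs=1e-9)

    def test_nonconvergence_warns_but_returns(self, abc_intervals):
        index = FeatureIndex([], list(abc_intervals.values()))
        reads = [("A",)] * 3 + [("B",)] + [("A", "B")] * 4
        with pytest.warns(RuntimeWarning, match="EM did not converge"):
            counts = count_te_em(em_instance(abc_intervals, reads), index,
                                 "forward", max_iter=1, tol=1e-12)
        assert counts.attrs["converged"]["s1"] is False
        assert counts["s1"].sum() == pytest.approx(8.0)
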