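"""Size factors, NB Wald test, BH adjustment, and significance rules."""

import numpy as np
import pandas as pd
import pytest

from terv.diffexpr import (
    adjust_bh,
    call_significant,
    cluster_gene_wilcoxon,
    estimate_dispersion,
    nb_wald_test,
    normalize_with_gene_factors,
    run_de,
    size_factors_median_ratio,
    wilcoxon_rank_sum,
)


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 50, 3], "b": [10, 50, 3]})
        assert np.allclose(size_factors_median_ratio(counts), 1.0)

    def test_doubled_sample(self):
        counts = pd.DataFrame({"a": [10, 50, 4], "b": [20, 100, 8]})
        s = size_factors_median_ratio(counts)
        assert s["a"] == pytest.approx(1 / np.sqrt(2))
        assert s["b"] == pytest.approx(np.sqrt(2))
        normalized = counts / s
        assert np.allclose(normalized["a"], normalized["b"])

    def test_three_gene_hand_example(self):
        counts = pd.DataFrame({"a": [100, 10, 40], "b": [200, 10, 80],
                               "c": [400, 10, 160]})
        k = counts.to_numpy(float)
        ref = np.exp(np.log(k).mean(axis=1))
        expected = np.median(k / ref[:, None], axis=0)
        s = size_factors_median_ratio(counts)
        assert np.allclose(s.to_numpy(), expected)

    def test_equivariance_under_scaling_one_sample(self):
        counts = pd.DataFrame({"a": [12, 30, 7, 90], "b": [11, 33, 9, 85]})
        s0 = size_factors_median_ratio(counts)
        scaled = counts.copy()
        scaled["b"] = counts["b"] * 4
        s1 = size_factors_median_ratio(scaled)
        # all genes scale together, so the ratio structure is exact
        assert s1["b"] / s0["b"] * s0["a"] / s1["a"] == pytest.approx(4.0)

    def test_no_all_positive_gene_fails_and_fallback_works(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="pseudo_reference"):
            size_factors_median_ratio(counts)
        s = size_factors_median_ratio(counts, pseudo_reference=True)
        assert (s > 0).all()

    def test_matches_pydeseq2_reference(self, rng):
        pydeseq2 = pytest.importorskip("pydeseq2.dds")
        counts = pd.DataFrame(
            rng.integers(1, 800, size=(50, 6)),
            columns=[f"s{i}" for i in range(6)],
        )
        meta = pd.DataFrame({"condition": ["A"] * 3 + ["B"] * 3},
                            index=counts.columns)
        dds = pydeseq2.DeseqDataSet(counts=counts.T, metadata=meta,
                                    design="~condition", quiet=True)
        dds.fit_size_factors()
        ours = size_factors_median_ratio(counts).to_numpy()
        theirs = np.asarray(dds.obs["size_factors"], float)
        assert np.allclose(ours, theirs, rtol=1e-2)


class TestNormalization:
    def test_unit_factors_identity(self):
        te = pd.DataFrame({"a": [5.0, 1.0], "b": [2.0, 0.0]})
        s = pd.Series({"a": 1.0, "b": 1.0})
        assert normalize_with_gene_factors(te, s).equals(te)

    def test_doubling_factor_halves_column(self):
        te = pd.DataFrame({"a": [8.0], "b": [8.0]})
        s = pd.Series({"a": 1.0, "b": 2.0})
        out = normalize_with_gene_factors(te, s)
        assert out.loc[0, "b"] == pytest.approx(out.loc[0, "a"] / 2)

    def test_missing_factor_fails(self):
        te = pd.DataFrame({"a": [1.0], "b": [1.0]})
        with pytest.raises(ValueError, match="b"):
            normalize_with_gene_factors(te, pd.Series({"a": 1.0}))

    def test_depth_scaled_replicates_normalize_together(self, rng):
        base = rng.integers(50, 500, size=30).astype(float)
        depth = np.array([1.0, 2.0, 0.5, 1.5])
        genes = pd.DataFrame(
            np.outer(rng.integers(100, 1000, 40), depth),
            columns=list("abcd"),
        )
        te = pd.DataFrame(np.outer(base, depth), columns=list("abcd"))
        s = size_factors_median_ratio(genes)
        out = normalize_with_gene_factors(te, s)
        for col in "bcd":
            assert np.allclose(out[col], out["a"], rtol=1e-9)


LABELS = ["control"] * 3 + ["KO"] * 3
ONES = np.ones(6)


class TestNBWald:
    def test_identical_counts_null_result(self):
        r = nb_wald_test([5, 5, 5, 5, 5, 5], LABELS, ONES)
        assert r.log2fc == pytest.approx(0.0, abs=1e-9)
        assert r.stat == pytest.approx(0.0, abs=1e-9)
        assert r.p == pytest.approx(1.0)

    def test_label_swap_flips_sign_keeps_p(self):
        k = [10, 14, 9, 60, 70, 55]
        a = nb_wald_test(k, LABELS, ONES, reference="control")
        b = nb_wald_test(k, LABELS, ONES, reference="KO")
        assert a.log2fc == pytest.approx(-b.log2fc)
        assert a.p == pytest.approx(b.p)
        assert np.sign(a.stat) == np.sign(a.log2fc)

    def test_recovers_large_effect(self, rng):
        # injected log2FC = 3 at mean 500, alpha = 0.05, 3 vs 3. The sampling
        # sd of the estimate is dispersion-dominated: sqrt(2*alpha/3)/ln2
        # ~ 0.27, so the check is unbiasedness within the Monte-Carlo error
        # and p < 1e-4 power, plus deviations consistent with that sd.
        n_rep = 60
        devs, hits = [], 0
        for _ in range(n_rep):
            mu = np.array([500.0] * 3 + [4000.0] * 3)
            k = rng.negative_binomial(1 / 0.05, 1 / (1 + 0.05 * mu))
            r = nb_wald_test(k, LABELS, ONES, reference="control")
            devs.append(r.log2fc - 3.0)
            hits += r.p < 1e-4
        devs = np.array(devs)
        sd_theory = np.sqrt(2 * 0.05 / 3) / np.log(2)
        assert abs(devs.mean()) < 3 * sd_theory / np.sqrt(n_rep)
        assert np.median(np.abs(devs)) < 2 * sd_theory
        assert hits >= 0.95 * n_rep

    def test_size_factor_offsets_remove_depth_effect(self):
        k = np.array([100, 100, 100, 200, 200, 200], float)
        s = np.array([1, 1, 1, 2, 2, 2], float)
        r = nb_wald_test(k, LABELS, s)
        assert r.log2fc == pytest.approx(0.0, abs=1e-9)

    def test_all_zero_row_filtered(self):
        r = nb_wald_test([0] * 6, LABELS, ONES)
        assert r.filtered and np.isnan(r.p)

    def test_dispersion_estimate_order_of_magnitude(self, rng):
        alphas = []
        for _ in range(40):
            mu = np.full(6, 200.0)
            k = rng.negative_binomial(1 / 0.2, 1 / (1 + 0.2 * mu))
            alphas.append(estimate_dispersion(k.astype(float), ONES,
                                              np.array([0, 0, 0, 1, 1, 1])))
        assert 0.05 < np.median(alphas) < 0.8


class TestBH:
    def test_step_up_hand_example(self):
        # sorted p * m / rank = (.04, .04, .04, .04) after monotone enforcement
        assert np.allclose(adjust_bh([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_single_test_identity(self):
        assert adjust_bh([0.037])[0] == pytest.approx(0.037)

    def test_all_ones(self):
        assert np.allclose(adjust_bh([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_and_order_invariant(self, rng):
        p = rng.uniform(size=50)
        adj = adjust_bh(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= p - 1e-12).all()
        perm = rng.permutation(50)
        assert np.allclose(adjust_bh(p[perm]), adj[perm])

    def test_filtered_nan_excluded_from_family(self):
        adj = adjust_bh([0.01, np.nan, 0.02])
        assert np.isnan(adj[1])
        # m = 2, not 3
        assert adj[0] == pytest.approx(0.02)


class TestSignificanceRules:
    def make(self, padj, lfc):
        return pd.DataFrame({"padj": [padj], "log2FC": [lfc]})

    @pytest.mark.parametrize(
        "mode, padj, lfc, expected",
        [
            ("bulk", 0.04, 0.6, True),
            ("bulk", 0.04, -0.6, True),    # two-sided on |log2FC|
            ("bulk", 0.04, 0.4, False),
            ("bulk", 0.06, 2.0, False),
            ("cluster-te", 0.005, 2.5, False),  # log2FC <= 3
            ("cluster-te", 0.005, 3.5, True),
            ("cluster-te", 0.02, 5.0, False),
            ("cluster-gene", 0.005, 0.1, True),
        ],
    )
    def test_rules(self, mode, padj, lfc, expected):
        out = call_significant(self.make(padj, lfc), mode)
        assert bool(out.significant.iloc[0]) is expected

    def test_unknown_mode_fails(self):
        with pytest.raises(ValueError, match="unknown mode"):
            call_significant(self.make(0.01, 1.0), "nonsense")


class TestWilcoxonPath:
    def test_shifted_samples_detected(self, rng):
        a = rng.normal(3, 1, 40)
        b = rng.normal(0, 1, 40)
        _, p = wilcoxon_rank_sum(a, b)
        assert p < 1e-6

    def test_cluster_gene_table(self, rng):
        cells = [f"c{i}" for i in range(30)]
        cond = {c: ("KO" if i < 15 else "control") for i, c in enumerate(cells)}
        values = pd.DataFrame(
            rng.poisson(10, size=(5, 30)).astype(float), columns=cells,
            index=[f"g{i}" for i in range(5)],
        )
        values.iloc[0, :15] += 40  # strongly up in KO
        out = cluster_gene_wilcoxon(values, cond, reference="control")
        called = call_significant(out, "cluster-gene")
        assert bool(called.significant.iloc[0])
        assert called.significant.iloc[1:].sum() <= 1


class TestRunDE:
    def test_min_total_filter_and_padj(self, rng):
        counts = pd.DataFrame(
            rng.negative_binomial(20, 0.2, size=(20, 6)),
            columns=list("abcdef"), dtype=float,
        )
        counts.iloc[0] = [1, 0, 0, 0, 1, 0]  # below min_total
        cond = dict(zip("abcdef", LABELS))
        s = pd.Series(1.0, index=list("abcdef"))
        df = run_de(counts, cond, s)
        assert bool(df["filtered"].iloc[0])
        assert np.isnan(df["padj"].iloc[0])
        ok = df.loc[~df.filtered]
        assert (ok["padj"] >= ok["p"] - 1e-12).all()
        assert ((ok["stat"] * ok["log2FC"]) >= -1e-12).all()
        assert (ok["baseMean"] >= 0).all()
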