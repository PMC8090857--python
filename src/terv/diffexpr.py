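"""Gene-anchored normalization and negative-binomial Wald differential expression.

Normalization uses the median-of-ratios size factors computed from a *gene*
count matrix; TE counts are then scaled by those gene-derived factors so TE
fold changes are not distorted by global TE derepression itself.

The test fits, per feature, a negative-binomial GLM with log link,
log-size-factor offsets and design intercept + condition:

    K_j ~ NB(mean = s_j * q_{g(j)},  variance = mu + alpha * mu^2)

The two-group design makes the fit separable: each group mean q_g solves a
one-dimensional score equation by Newton iteration, and the dispersion alpha
maximizes the Cox-Reid-adjusted profile likelihood (no empirical-Bayes
shrinkage). The condition coefficient beta = log(q_ko / q_ctl) is reported in
log2 units with its Wald statistic W = beta / SE(beta) and two-sided normal p;
p values are Benjamini-Hochberg adjusted over the unfiltered features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

LN2 = np.log(2.0)
MIN_ALPHA = 1e-8
MAX_ALPHA = 100.0
# floor for a group mean when one condition has zero counts; keeps the fold
# change finite while the blown-up SE keeps the feature non-significant
_Q_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# Size factors
# ---------------------------------------------------------------------------

def size_factors_median_ratio(
    gene_counts: pd.DataFrame, pseudo_reference: bool = False
) -> pd.Series:
    """Median-of-ratios size factors from a gene count matrix.

    s_j = median over reference genes of k_gj / geometric-mean_g. By default
    the reference set is genes with positive counts in every sample; with
    ``pseudo_reference=True`` the per-gene geometric mean is taken over the
    positive entries only, rescuing sparse matrices where no gene is
    all-positive.
    """
    if gene_counts.shape[1] < 2:
        raise ValueError("size factors need at least 2 samples")
    k = gene_counts.to_numpy(float)
    if pseudo_reference:
        usable = (k > 0).any(axis=1)
        if not usable.any():
            raise ValueError("no gene with a positive count in any sample")
        with np.errstate(divide="ignore"):
            logk = np.where(k > 0, np.log(k, where=k > 0), 0.0)
        ref = np.exp(logk[usable].sum(axis=1) / (k[usable] > 0).sum(axis=1))
        ratios = np.where(k[usable] > 0, k[usable] / ref[:, None], np.nan)
        s = np.nanmedian(ratios, axis=0)
    else:
        usable = (k > 0).all(axis=1)
        if not usable.any():
            raise ValueError(
                "no gene has positive counts in every sample; rerun with "
                "pseudo_reference=True to use a positive-counts reference"
            )
        logk = np.log(k[usable])
        ref = np.exp(logk.mean(axis=1))
        s = np.median(k[usable] / ref[:, None], axis=0)
    if not np.all(np.isfinite(s)) or np.any(s <= 0):
        raise ValueError("degenerate size factors")
    factors = pd.Series(s, index=gene_counts.columns, name="size_factor")
    factors.attrs["source"] = gene_counts.attrs.get("provenance", "genes")
    return factors


def normalize_with_gene_factors(
    te_counts: pd.DataFrame, size_factors: pd.Series
) -> pd.DataFrame:
    """Divide each TE count column by its sample's gene-derived size factor."""
    missing = [c for c in te_counts.columns if c not in size_factors.index]
    if missing:
        raise ValueError(f"no size factor for columns: {missing}")
    out = te_counts / size_factors.reindex(te_counts.columns)
    out.attrs["provenance"] = "cross-normalized (TE counts, gene-derived factors)"
    return out


# ---------------------------------------------------------------------------
# Two-group NB GLM
# ---------------------------------------------------------------------------

def _fit_group_mean(k: np.ndarray, s: np.ndarray, alpha: float) -> float:
    """Solve the NB score equation sum (k - s q) / (1 + alpha s q) = 0 for q."""
    if k.sum() == 0:
        return 0.0
    q = float(k.sum() / s.sum())
    if alpha < 1e-12:
        return q  # Poisson MLE is exact
    for _ in range(100):
        mu = s * q
        d = 1.0 + alpha * mu
        f = float(np.sum((k - mu) / d))
        fp = float(np.sum((-s * d - (k - mu) * alpha * s) / d**2))
        if fp == 0.0:
            break
        q_new = q - f / fp
        if q_new <= 0:
            q_new = q / 2.0
        if abs(q_new - q) < 1e-12 * (1.0 + q):
            return q_new
        q = q_new
    return q


def _nb_loglik(k: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    if alpha < 1e-12:
        return float(np.sum(stats.poisson.logpmf(k, np.maximum(mu, 1e-300))))
    r = 1.0 / alpha
    mu = np.maximum(mu, 1e-300)
    return float(
        np.sum(
            special.gammaln(k + r) - special.gammaln(r) - special.gammaln(k + 1)
            + r * np.log(r / (r + mu)) + k * np.log(mu / (r + mu))
        )
    )


def _cr_profile(
    log_alpha: float,
    k_by_group: Sequence[np.ndarray],
    s_by_group: Sequence[np.ndarray],
) -> float:
    """Negative Cox-Reid-adjusted profile log-likelihood at log(alpha).

    For the separable two-group design X'WX is block diagonal, so the CR term
    is -1/2 * sum_g log(I_g) with I_g = sum_j mu_j / (1 + alpha mu_j).
    """
    alpha = float(np.exp(log_alpha))
    total = 0.0
    for k, s in zip(k_by_group, s_by_group):
        q = _fit_group_mean(k, s, alpha)
        mu = s * max(q, _Q_FLOOR)
        total += _nb_loglik(k, mu, alpha)
        info = float(np.sum(mu / (1.0 + alpha * mu)))
        total -= 0.5 * np.log(max(info, 1e-300))
    return -total


def estimate_dispersion(
    k: np.ndarray, s: np.ndarray, groups: np.ndarray
) -> float:
    """Per-feature Cox-Reid-adjusted ML dispersion (floored at 1e-8)."""
    ks = [k[groups == g] for g in (0, 1)]
    ss = [s[groups == g] for g in (0, 1)]
    res = optimize.minimize_scalar(
        _cr_profile,
        bounds=(np.log(MIN_ALPHA), np.log(MAX_ALPHA)),
        args=(ks, ss),
        method="bounded",
        options={"xatol": 1e-3},
    )
    return float(np.exp(res.x))


def estimate_common_dispersion(
    counts: np.ndarray, s: np.ndarray, groups: np.ndarray
) -> float:
    """Cox-Reid-adjusted ML of a single dispersion shared by all rows.

    Used as the moderation anchor in :func:`run_de`: with few replicates the
    per-feature ML is noisy and downward-biased excursions inflate the Wald
    statistic, so each feature's working dispersion is floored at this
    common value (upward-only moderation; see run_de).
    """
    rows = [
        ([row[groups == g] for g in (0, 1)], [s[groups == g] for g in (0, 1)])
        for row in counts
        if row.sum() > 0
    ]
    if not rows:
        raise ValueError("no nonzero rows")

    def objective(log_alpha: float) -> float:
        return sum(_cr_profile(log_alpha, ks, ss) for ks, ss in rows)

    res = optimize.minimize_scalar(
        objective, bounds=(np.log(MIN_ALPHA), np.log(MAX_ALPHA)),
        method="bounded", options={"xatol": 1e-3},
    )
    return float(np.exp(res.x))


@dataclass
class DEResult:
    """Wald-test summary for one feature."""

    feature_id: str
    base_mean: float
    log2fc: float
    se: float  # SE of log2fc
    stat: float
    p: float
    alpha: float
    padj: float | None = None
    filtered: bool = False


def nb_wald_test(
    counts: np.ndarray | Sequence[float],
    conditions: Sequence[str],
    size_factors: np.ndarray | Sequence[float],
    reference: str | None = None,
    feature_id: str = "feature",
    alpha: float | None = None,
) -> DEResult:
    """NB GLM Wald test of condition for one feature's count row.

    ``reference`` names the baseline condition (default: first label in sorted
    order). ``alpha`` overrides the estimated dispersion. An all-zero row is
    returned with ``filtered=True`` and undefined (NaN) statistics.
    """
    k = np.asarray(counts, float)
    s = np.asarray(size_factors, float)
    labels = np.asarray(conditions)
    levels = sorted(set(labels.tolist()))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 conditions, got {levels}")
    if reference is None:
        reference = levels[0]
    if reference not in levels:
        raise ValueError(f"reference {reference!r} not among {levels}")
    other = levels[1] if levels[0] == reference else levels[0]
    groups = (labels == other).astype(int)
    if min((groups == 0).sum(), (groups == 1).sum()) < 2:
        raise ValueError("need at least 2 samples per condition")

    base_mean = float(np.mean(k / s))
    if k.sum() == 0:
        return DEResult(feature_id, 0.0, np.nan, np.nan, np.nan, np.nan,
                        np.nan, filtered=True)

    if alpha is None:
        alpha = estimate_dispersion(k, s, groups)
    qs, infos = [], []
    for g in (0, 1):
        kg, sg = k[groups == g], s[groups == g]
        q = max(_fit_group_mean(kg, sg, alpha), _Q_FLOOR)
        mu = sg * q
        qs.append(q)
        infos.append(float(np.sum(mu / (1.0 + alpha * mu))))
    beta = np.log(qs[1] / qs[0])  # natural log
    se_nat = float(np.sqrt(1.0 / max(infos[0], 1e-300)
                           + 1.0 / max(infos[1], 1e-300)))
    log2fc = beta / LN2
    se = se_nat / LN2
    stat = beta / se_nat if se_nat > 0 else 0.0
    p = float(2.0 * stats.norm.sf(abs(stat)))
    return DEResult(feature_id, base_mean, float(log2fc), se, float(stat), p,
                    float(alpha))


def adjust_bh(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaN entries (filtered features)
    are excluded from the number of tests and stay NaN."""
    p = np.asarray(p, float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def run_de(
    counts: pd.DataFrame,
    conditions: Mapping,
    size_factors: pd.Series,
    reference: str | None = None,
    min_total: float = 10.0,
    alpha: float | None = None,
    moderate_dispersion: bool = True,
) -> pd.DataFrame:
    """Matrix-level NB Wald DE: per-row test + BH adjustment.

    ``conditions`` maps column -> condition label. Rows whose total count is
    below ``min_total`` are reported with ``filtered=True``, excluded from the
    BH family, and carry NaN statistics.

    With ``moderate_dispersion`` (default) each feature's dispersion is the
    larger of its own Cox-Reid ML estimate and the matrix-wide common
    estimate: features are never allowed a smaller variance than the shared
    signal supports, which keeps the Wald test calibrated with few replicates
    at a modest power cost for genuinely low-dispersion features. ``alpha``
    overrides dispersion estimation entirely.
    """
    cols = list(counts.columns)
    labels = np.asarray([conditions[c] for c in cols])
    s = size_factors.reindex(cols).to_numpy(float)
    levels = sorted(set(labels.tolist()))
    ref = reference if reference is not None else levels[0]
    other = [l for l in levels if l != ref][0]
    groups = (labels == other).astype(int)

    kept = counts.to_numpy(float)[counts.sum(axis=1).to_numpy() >= min_total]
    common = None
    if alpha is None and moderate_dispersion and len(kept):
        common = estimate_common_dispersion(kept, s, groups)

    rows = []
    for fid, row in counts.iterrows():
        k = row.to_numpy(float)
        if k.sum() < min_total:
            rows.append(DEResult(str(fid), float(np.mean(k / s)), np.nan,
                                 np.nan, np.nan, np.nan, np.nan, filtered=True))
        else:
            a = alpha
            if a is None:
                a = estimate_dispersion(k, s, groups)
                if common is not None:
                    a = max(a, common)
            rows.append(nb_wald_test(k, labels, s, reference=reference,
                                     feature_id=str(fid), alpha=a))
    df = pd.DataFrame(
        {
            "feature": [r.feature_id for r in rows],
            "baseMean": [r.base_mean for r in rows],
            "log2FC": [r.log2fc for r in rows],
            "SE": [r.se for r in rows],
            "stat": [r.stat for r in rows],
            "p": [r.p for r in rows],
            "filtered": [r.filtered for r in rows],
            "alpha": [r.alpha for r in rows],
        }
    ).set_index("feature")
    df["padj"] = adjust_bh(df["p"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# Wilcoxon path (per-cluster genes) and significance rules
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided rank-sum test, normal approximation with tie and continuity
    correction."""
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def cluster_gene_wilcoxon(
    per_cell_values: pd.DataFrame, cell_conditions: Mapping, reference: str
) -> pd.DataFrame:
    """Per-gene rank-sum test on normalized per-cell values (genes x cells)."""
    labels = np.asarray([cell_conditions[c] for c in per_cell_values.columns])
    ref_mask = labels == reference
    if ref_mask.all() or not ref_mask.any():
        raise ValueError("both conditions must be present among cells")
    ps, lfcs = [], []
    eps = 1e-9
    x = per_cell_values.to_numpy(float)
    for i in range(x.shape[0]):
        a, b = x[i, ~ref_mask], x[i, ref_mask]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            ps.append(1.0)
        else:
            ps.append(wilcoxon_rank_sum(a, b)[1])
        lfcs.append(np.log2((a.mean() + eps) / (b.mean() + eps)))
    df = pd.DataFrame(
        {"log2FC": lfcs, "p": ps}, index=per_cell_values.index
    )
    df["padj"] = adjust_bh(df["p"].to_numpy())
    return df


SIGNIFICANCE_MODES = {
    # bulk genes / TE subfamilies / elements: padj < 0.05 and |log2FC| > 0.5
    "bulk": dict(padj=0.05, abs_lfc=0.5, signed=False),
    # per-cluster TE subfamilies: padj < 0.01 and log2FC > 3 (upregulation)
    "cluster-te": dict(padj=0.01, abs_lfc=3.0, signed=True),
    # per-cluster genes (rank-sum path): padj < 0.01
    "cluster-gene": dict(padj=0.01, abs_lfc=0.0, signed=False),
    # element-level upregulation for window analyses: padj < 0.05, log2FC > 0
    "element-up": dict(padj=0.05, abs_lfc=0.0, signed=True),
}


def call_significant(results: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Apply a named significance rule, adding a boolean ``significant`` column."""
    if mode not in SIGNIFICANCE_MODES:
        raise ValueError(
            f"unknown mode {mode!r}; expected one of {sorted(SIGNIFICANCE_MODES)}"
        )
    rule = SIGNIFICANCE_MODES[mode]
    lfc = results["log2FC"]
    effect = lfc > rule["abs_lfc"] if rule["signed"] else lfc.abs() > rule["abs_lfc"]
    out = results.copy()
    out["significant"] = (results["padj"] < rule["padj"]) & effect
    out["significant"] = out["significant"].fillna(False).astype(bool)
    return out
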