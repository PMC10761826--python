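"""Composite differential-expression calling between sample groups A and B.

A gene is called "lower" or "higher" in group A only when BOTH a per-gene
Student t-test on log expression AND a negative-binomial count-based test
agree: raw p < 0.05 and Benjamini-Hochberg adjusted p < 0.1 in each test,
with the linear fold change A/B outside (0.8, 1.25) and all three signals
pointing the same way.  The count-based test is a simplified NB Wald test:
median-of-ratios size factors, method-of-moments dispersion with a floor,
and a delta-method Wald statistic on the log mean ratio referred to the
standard normal (the usual Wald reference).  The variance floor makes the
test mildly conservative under near-Poisson data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import CountMatrix, DataError, ExpressionMatrix, logger

DISPERSION_FLOOR = 1e-8


@dataclass(frozen=True)
class DEThresholds:
    """The joint decision rule's gates (strict inequalities)."""

    p: float = 0.05
    q: float = 0.1
    fc_low: float = 0.8
    fc_high: float = 1.25


def _two_group_arrays(
    data: pd.DataFrame, grouping: pd.Series
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    grouping = grouping.reindex(data.columns).dropna()
    groups = sorted(grouping.unique())
    if len(groups) != 2:
        raise DataError(f"expected exactly two groups, got {groups}")
    a_cols = grouping.index[grouping == groups[0]]
    b_cols = grouping.index[grouping == groups[1]]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise DataError("each group needs at least 2 samples")
    return (
        data[a_cols].to_numpy(dtype=float),
        data[b_cols].to_numpy(dtype=float),
        groups,
    )


def t_test_per_gene(logexpr: ExpressionMatrix, grouping: pd.Series) -> pd.DataFrame:
    """Two-sided pooled-variance Student t-test per gene (A vs B).

    Genes that are constant and equal in both groups get statistic 0 and
    p = 1 by convention (logged).
    """
    A, B, _ = _two_group_arrays(logexpr.data, grouping)
    res = stats.ttest_ind(A, B, axis=1, equal_var=True)
    stat = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(stat)
    if degenerate.any():
        logger.info("%d degenerate genes (zero pooled variance): p set to 1",
                    int(degenerate.sum()))
        stat[degenerate] = 0.0
        p[degenerate] = 1.0
    return pd.DataFrame(
        {"statistic": stat, "p_t": p,
         "mean_A": A.mean(axis=1), "mean_B": B.mean(axis=1)},
        index=logexpr.gene_ids,
    )


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    The reference is the per-gene geometric mean over samples; genes with
    any zero count are excluded from the median (their geometric-mean
    reference would vanish).
    """
    data = counts.data if isinstance(counts, CountMatrix) else counts
    values = data.to_numpy(dtype=float)
    if (values.sum(axis=0) == 0).any():
        raise DataError("sample with all-zero counts")
    usable = (values > 0).all(axis=1)
    if not usable.any():
        raise DataError("no gene is free of zeros; cannot compute size factors")
    logv = np.log(values[usable])
    log_ref = logv.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logv - log_ref, axis=0))
    return pd.Series(sf, index=data.columns, name="size_factor")


def nb_wald_per_gene(
    counts: CountMatrix, grouping: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """Simplified negative-binomial Wald test per gene.

    Normalised counts y = K / s; per-group means estimate the NB mean; the
    per-gene dispersion alpha is method-of-moments on normalised counts
    (pooled within-group excess variance over the Poisson part, floored at
    1e-8); the Wald statistic is the log mean ratio over its delta-method
    standard error, Var(y_j) = mu / s_j + alpha * mu^2.

    All-zero genes get p = 1 and missing fold change.  Returns the
    per-gene frame and the size-factor series.
    """
    sf = size_factors(counts)
    norm = counts.data.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    grouping = grouping.reindex(counts.sample_ids).dropna()
    groups = sorted(grouping.unique())
    if len(groups) != 2:
        raise DataError(f"expected exactly two groups, got {groups}")
    mask_a = (grouping.reindex(counts.sample_ids) == groups[0]).to_numpy()
    mask_b = (grouping.reindex(counts.sample_ids) == groups[1]).to_numpy()
    inv_s = 1.0 / sf.to_numpy()
    nA, nB = int(mask_a.sum()), int(mask_b.sum())
    if nA < 2 or nB < 2:
        raise DataError("each group needs at least 2 samples")

    yA, yB = norm[:, mask_a], norm[:, mask_b]
    muA, muB = yA.mean(axis=1), yB.mean(axis=1)
    mu = norm[:, mask_a | mask_b].mean(axis=1)

    # pooled within-group variance of normalised counts
    vA = yA.var(axis=1, ddof=1)
    vB = yB.var(axis=1, ddof=1)
    pooled = ((nA - 1) * vA + (nB - 1) * vB) / (nA + nB - 2)
    poisson_part = mu * inv_s.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled - poisson_part) / np.square(mu)
    alpha = np.where(np.isfinite(alpha), alpha, 0.0)
    alpha = np.maximum(alpha, DISPERSION_FLOOR)

    all_zero = mu == 0
    # continuity-correct group means that are exactly zero but not all-zero
    cc = 0.5
    muA_adj = np.where(muA == 0, cc / nA, muA)
    muB_adj = np.where(muB == 0, cc / nB, muB)

    var_muA = (muA_adj * inv_s[mask_a].mean() + alpha * muA_adj**2) / nA
    var_muB = (muB_adj * inv_s[mask_b].mean() + alpha * muB_adj**2) / nB
    se = np.sqrt(var_muA / muA_adj**2 + var_muB / muB_adj**2)
    log2fc = np.log2(muA_adj / muB_adj)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.log(muA_adj / muB_adj) / se
    p = 2.0 * stats.norm.sf(np.abs(z))

    z[all_zero] = 0.0
    p[all_zero] = 1.0
    log2fc = np.where(all_zero, np.nan, log2fc)

    table = pd.DataFrame(
        {"log2fc_nb": log2fc, "statistic": z, "p_nb": p,
         "dispersion": alpha, "mean_norm_A": muA, "mean_norm_B": muB},
        index=counts.gene_ids,
    )
    return table, sf


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(
    linear_expr: ExpressionMatrix, grouping: pd.Series, pseudocount: float = 0.0
) -> pd.Series:
    """Linear-scale fold change (mean_A + pc) / (mean_B + pc) per gene."""
    if linear_expr.scale != "linear":
        raise DataError("fold_change expects a linear-scale matrix")
    A, B, _ = _two_group_arrays(linear_expr.data, grouping)
    num = A.mean(axis=1) + pseudocount
    den = B.mean(axis=1) + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = num / den
    return pd.Series(fc, index=linear_expr.gene_ids, name="fc")


def composite_call(
    t_results: pd.DataFrame,
    nb_results: pd.DataFrame,
    fc: pd.Series,
    thresholds: DEThresholds = DEThresholds(),
) -> pd.DataFrame:
    """Join the two tests and the fold-change gate into a three-way call.

    BH adjustment is applied within the supplied gene universe.  A gene is
    "lower" (in A) when p < 0.05 and q < 0.1 in both tests, fc < 0.8, and
    both test statistics are negative; "higher" symmetrically with
    fc > 1.25 and positive statistics; otherwise "unchanged".  Direction
    disagreements between the fold change and either statistic are logged
    and forced to "unchanged".
    """
    genes = t_results.index
    if not (genes.equals(nb_results.index) and genes.equals(fc.index)):
        raise DataError("gene universes of t, NB and fold-change inputs differ")
    th = thresholds
    q_t = bh_adjust(t_results["p_t"].to_numpy())
    q_nb = bh_adjust(nb_results["p_nb"].to_numpy())

    p_t = t_results["p_t"].to_numpy()
    p_nb = nb_results["p_nb"].to_numpy()
    t_stat = t_results["statistic"].to_numpy()
    nb_stat = nb_results["statistic"].to_numpy()
    fcv = fc.to_numpy(dtype=float)

    sig = (p_t < th.p) & (p_nb < th.p) & (q_t < th.q) & (q_nb < th.q)
    with np.errstate(invalid="ignore"):
        low_fc = fcv < th.fc_low
        high_fc = fcv > th.fc_high
    lower = sig & low_fc & (t_stat < 0) & (nb_stat < 0)
    higher = sig & high_fc & (t_stat > 0) & (nb_stat > 0)
    discordant = sig & ((low_fc & ~lower) | (high_fc & ~higher))
    if discordant.any():
        logger.info("%d significant genes with discordant direction set to unchanged",
                    int(discordant.sum()))

    call = np.where(lower, "lower", np.where(higher, "higher", "unchanged"))
    return pd.DataFrame(
        {
            "mean_A": t_results["mean_A"].to_numpy(),
            "mean_B": t_results["mean_B"].to_numpy(),
            "fc": fcv,
            "p_t": p_t,
            "q_t": q_t,
            "p_nb": p_nb,
            "q_nb": q_nb,
            "call": call,
        },
        index=genes,
    )


def run_de(
    counts: CountMatrix,
    linear_expr: ExpressionMatrix,
    logexpr: ExpressionMatrix,
    grouping: pd.Series,
    genes: list[str] | None = None,
    thresholds: DEThresholds = DEThresholds(),
) -> pd.DataFrame:
    """Full composite pipeline on an optional gene subset (BH within it)."""
    if genes is not None:
        genes = [g for g in genes if g in counts.gene_ids]
        counts = CountMatrix(counts.data.loc[genes])
        linear_expr = ExpressionMatrix(linear_expr.data.loc[genes], scale="linear")
        logexpr = ExpressionMatrix(
            logexpr.data.loc[genes], scale=logexpr.scale,
            purity_used=logexpr.purity_used,
        )
    t_res = t_test_per_gene(logexpr, grouping)
    nb_res, _ = nb_wald_per_gene(counts, grouping)
    fc = fold_change(linear_expr, grouping)
    return composite_call(t_res, nb_res, fc, thresholds)
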