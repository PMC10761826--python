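"""Category-level summaries of DE calls and categorical association tests.

Covers the chaperone-family / subcellular-compartment breakdowns of the
composite calls, mean set-expression contrasts (e.g. the small heat shock
proteins), transcription-factor target coverage of the DE gene list, the
exact 2xk Fisher test, and the pigmentation-score recode.
"""

from __future__ import annotations

from itertools import product
from math import lgamma

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import DataError, ExpressionMatrix, GeneSetCollection, logger

CALLS = ("lower", "higher", "unchanged")


def family_breakdown(de_calls: pd.DataFrame, families: GeneSetCollection) -> pd.DataFrame:
    """Per-family proportions (and counts) of lower / higher / unchanged calls.

    Family members absent from the call table are dropped with a logged
    warning; a family left empty after intersection is reported with
    ``missing=True`` and NaN proportions.
    """
    if "call" not in de_calls:
        raise DataError("de_calls must carry a 'call' column")
    universe = set(de_calls.index)
    rows = []
    for name in families.names():
        members = sorted(families[name])
        present = [g for g in members if g in universe]
        dropped = len(members) - len(present)
        if dropped:
            logger.warning("family %s: %d genes absent from the call table", name, dropped)
        row: dict = {"family": name, "n_genes": len(present), "missing": not present}
        if present:
            calls = de_calls.loc[present, "call"]
            for c in CALLS:
                row[f"n_{c}"] = int((calls == c).sum())
                row[f"prop_{c}"] = float((calls == c).mean())
        else:
            for c in CALLS:
                row[f"n_{c}"] = 0
                row[f"prop_{c}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("family")


def mean_set_expression_test(
    logexpr: ExpressionMatrix, gene_set, grouping: pd.Series
) -> dict:
    """Mean expression over a gene set per sample, contrasted between groups.

    Per-sample means over the set's genes are compared with a two-sample
    pooled-variance Student t-test.
    """
    genes = [g for g in gene_set if g in logexpr.gene_ids]
    if not genes:
        raise DataError("gene set has no members in the expression matrix")
    grouping = grouping.reindex(logexpr.sample_ids).dropna()
    groups = sorted(grouping.unique())
    if len(groups) != 2:
        raise DataError(f"expected exactly two groups, got {groups}")
    sample_means = logexpr.data.loc[genes].mean(axis=0)
    a = sample_means[grouping.index[grouping == groups[0]]].to_numpy()
    b = sample_means[grouping.index[grouping == groups[1]]].to_numpy()
    res = stats.ttest_ind(a, b, equal_var=True)
    p = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
    return {
        "groups": groups,
        "mean_per_group": {groups[0]: float(a.mean()), groups[1]: float(b.mean())},
        "difference": float(a.mean() - b.mean()),
        "statistic": float(res.statistic) if np.isfinite(res.statistic) else 0.0,
        "p": p,
        "n_genes": len(genes),
    }


def tf_target_coverage(
    de_genes, tf_targets: GeneSetCollection
) -> tuple[pd.Series, pd.DataFrame]:
    """Fraction of DE genes that are targets of each transcription factor.

    Returns the per-TF coverage |targets ∩ de_genes| / |de_genes| and the
    binary gene x TF membership matrix behind it.
    """
    de_genes = list(dict.fromkeys(de_genes))
    if not de_genes:
        raise DataError("empty DE gene list")
    tfs = tf_targets.names()
    membership = pd.DataFrame(
        {tf: [g in tf_targets[tf] for g in de_genes] for tf in tfs},
        index=de_genes,
    )
    coverage = membership.mean(axis=0).rename("coverage")
    return coverage, membership


def _log_table_prob(table: np.ndarray) -> float:
    """Log conditional probability of a 2xk table given all margins."""
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    total = table.sum()
    lp = sum(lgamma(m + 1) for m in row) + sum(lgamma(m + 1) for m in col)
    lp -= lgamma(total + 1)
    lp -= sum(lgamma(v + 1) for v in table.ravel())
    return lp


def fisher_category_test(table_2xk, max_tables: int = 5_000_000) -> float:
    """Two-sided exact conditional test for a 2 x k contingency table.

    Enumerates every table with the observed margins and sums the
    probabilities of tables no more probable than the observed one (the
    standard two-sided convention; for 2x2 this reproduces Fisher's exact
    test).  Intended for the small tables arising from clinical-attribute
    contrasts; refuses tables whose enumeration would be too large.
    """
    table = np.asarray(table_2xk)
    if table.ndim != 2 or table.shape[0] != 2:
        raise DataError("expected a 2 x k table")
    if not np.issubdtype(table.dtype, np.integer):
        if not np.array_equal(table, np.round(table)):
            raise DataError("contingency table cells must be integers")
        table = table.astype(np.int64)
    if (table < 0).any():
        raise DataError("contingency table cells must be non-negative")
    col = table.sum(axis=0)
    r1 = int(table.sum(axis=1)[0])
    space = np.prod([min(int(c), r1) + 1 for c in col])
    if space > max_tables:
        raise DataError("table too large for exact enumeration")

    log_obs = _log_table_prob(table)
    total_p = 0.0
    ranges = [range(int(c) + 1) for c in col]
    for top in product(*ranges):
        if sum(top) != r1:
            continue
        cand = np.array([list(top), (col - np.array(top)).tolist()])
        lp = _log_table_prob(cand)
        if lp <= log_obs + 1e-9:
            total_p += np.exp(lp)
    return float(min(1.0, total_p))


def recode_pigmentation(scores: pd.Series) -> pd.Series:
    """Recode the 0-3 pigmentation score: 0,1 -> low; 2,3 -> high; NA kept."""
    out = pd.Series(pd.NA, index=scores.index, dtype="object")
    present = scores.notna()
    vals = pd.to_numeric(scores[present], errors="raise")
    if not vals.isin([0, 1, 2, 3]).all():
        bad = vals[~vals.isin([0, 1, 2, 3])].index[0]
        raise DataError(f"pigmentation score outside 0-3 for sample {bad!r}")
    out[present] = np.where(vals <= 1, "low", "high")
    return out
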