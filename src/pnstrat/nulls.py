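"""Resampling null distributions for gene-set enrichment of DE calls.

Two procedures:

* ``random_geneset_de_proportion`` — draw many gene sets of the PN set's
  size uniformly without replacement from the full gene universe, run the
  composite DE caller restricted to each set (BH re-applied within the
  set), and compare the PN set's called fraction against the resulting
  null distribution.
* ``overlap_permutation`` — the two-list overlap test: repeatedly draw two
  independent uniform subsets of a gene universe and record their
  intersection size; the analytic counterpart is the hypergeometric tail
  (``overlap_hypergeometric``), used as an exact oracle.

Empirical p-values follow the count convention p = #{draw >= observed} /
n_draws, so every emitted p is an integer multiple of 1 / n_draws; the
(count + 1) / (n + 1) variant is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .datamodel import CountMatrix, DataError, ExpressionMatrix
from .diffexp import DEThresholds, bh_adjust, fold_change, nb_wald_per_gene, t_test_per_gene


@dataclass
class NullDistribution:
    draws: np.ndarray
    observed: float
    p_emp: float
    seed: int

    @property
    def n_draws(self) -> int:
        return int(self.draws.size)

    def summary(self) -> dict:
        return {
            "n_draws": self.n_draws,
            "observed": float(self.observed),
            "p_emp": float(self.p_emp),
            "draw_mean": float(self.draws.mean()),
            "draw_sd": float(self.draws.std(ddof=0)),
            "seed": self.seed,
        }


def empirical_p(draws: np.ndarray, observed: float, plus_one: bool = False) -> float:
    """Count-convention upper-tail empirical p-value."""
    count = int(np.sum(draws >= observed))
    if plus_one:
        return (count + 1) / (draws.size + 1)
    return count / draws.size


def per_gene_de_stats(
    counts: CountMatrix,
    linear_expr: ExpressionMatrix,
    logexpr: ExpressionMatrix,
    grouping: pd.Series,
    thresholds: DEThresholds = DEThresholds(),
) -> pd.DataFrame:
    """Raw per-gene statistics of the composite caller over the whole universe.

    Raw p-values, statistics and fold changes do not depend on the gene
    set; only the BH step does, so these are computed once and re-ranked
    within each resampled set.
    """
    t_res = t_test_per_gene(logexpr, grouping)
    nb_res, _ = nb_wald_per_gene(counts, grouping)
    fc = fold_change(linear_expr, grouping)
    th = thresholds
    fcv = fc.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        gate = (
            (t_res["p_t"].to_numpy() < th.p)
            & (nb_res["p_nb"].to_numpy() < th.p)
            & (
                ((fcv < th.fc_low) & (t_res["statistic"].to_numpy() < 0)
                 & (nb_res["statistic"].to_numpy() < 0))
                | ((fcv > th.fc_high) & (t_res["statistic"].to_numpy() > 0)
                   & (nb_res["statistic"].to_numpy() > 0))
            )
        )
    return pd.DataFrame(
        {
            "p_t": t_res["p_t"].to_numpy(),
            "p_nb": nb_res["p_nb"].to_numpy(),
            "fc": fcv,
            "raw_gate": gate,
        },
        index=t_res.index,
    )


def _called_fraction(stats_df: pd.DataFrame, idx: np.ndarray, q_thresh: float) -> float:
    """Composite called fraction within a gene subset, BH within the subset."""
    p_t = stats_df["p_t"].to_numpy()[idx]
    p_nb = stats_df["p_nb"].to_numpy()[idx]
    gate = stats_df["raw_gate"].to_numpy()[idx]
    q_t = bh_adjust(p_t)
    q_nb = bh_adjust(p_nb)
    called = gate & (q_t < q_thresh) & (q_nb < q_thresh)
    return float(called.mean())


def random_geneset_de_proportion(
    counts: CountMatrix,
    linear_expr: ExpressionMatrix,
    logexpr: ExpressionMatrix,
    grouping: pd.Series,
    pn_genes,
    set_size: int = 428,
    n_iter: int = 1000,
    seed: int = 0,
    thresholds: DEThresholds = DEThresholds(),
    plus_one: bool = False,
) -> NullDistribution:
    """Null distribution of the DE-called fraction over random gene sets.

    Each iteration samples ``set_size`` genes without replacement from the
    full universe and records the fraction the composite caller (with BH
    adjustment within that set) calls lower or higher.  The observed value
    is the same statistic on the designated PN set.
    """
    universe = list(counts.gene_ids)
    if set_size > len(universe):
        raise DataError(f"set_size {set_size} exceeds universe of {len(universe)}")
    pn_genes = [g for g in pn_genes if g in counts.gene_ids]
    if not pn_genes:
        raise DataError("PN set has no genes in the matrix")

    stats_df = per_gene_de_stats(counts, linear_expr, logexpr, grouping, thresholds)
    rng = np.random.default_rng(seed)
    n_genes = len(universe)
    draws = np.empty(n_iter)
    for i in range(n_iter):
        idx = rng.choice(n_genes, size=set_size, replace=False)
        draws[i] = _called_fraction(stats_df, idx, thresholds.q)

    pn_idx = stats_df.index.get_indexer(pn_genes)
    observed = _called_fraction(stats_df, pn_idx, thresholds.q)
    return NullDistribution(
        draws=draws,
        observed=observed,
        p_emp=empirical_p(draws, observed, plus_one=plus_one),
        seed=seed,
    )


def _check_overlap_args(universe_size, size_a, size_b, observed_overlap) -> None:
    if size_a > universe_size or size_b > universe_size:
        raise DataError("list sizes cannot exceed the universe")
    if min(size_a, size_b) < 0 or universe_size <= 0:
        raise DataError("sizes must be non-negative, universe positive")
    if not 0 <= observed_overlap <= min(size_a, size_b):
        raise DataError(
            f"observed overlap {observed_overlap} outside [0, {min(size_a, size_b)}]"
        )


def overlap_permutation(
    universe_size: int,
    size_a: int,
    size_b: int,
    observed_overlap: int,
    n_sim: int = 5000,
    seed: int = 0,
    plus_one: bool = False,
) -> NullDistribution:
    """Monte-Carlo tail probability of a two-list overlap.

    Each simulation draws two independent uniform subsets (sizes
    ``size_a`` and ``size_b``) of the universe without replacement and
    records the intersection size; p = #{overlap >= observed} / n_sim.
    """
    _check_overlap_args(universe_size, size_a, size_b, observed_overlap)
    rng = np.random.default_rng(seed)
    draws = np.empty(n_sim)
    member = np.zeros(universe_size, dtype=bool)
    for i in range(n_sim):
        a = rng.choice(universe_size, size=size_a, replace=False)
        b = rng.choice(universe_size, size=size_b, replace=False)
        member[:] = False
        member[a] = True
        draws[i] = member[b].sum()
    return NullDistribution(
        draws=draws,
        observed=float(observed_overlap),
        p_emp=empirical_p(draws, observed_overlap, plus_one=plus_one),
        seed=seed,
    )


def overlap_hypergeometric(
    universe_size: int, size_a: int, size_b: int, observed_overlap: int
) -> float:
    """Exact tail P(X >= observed) for X ~ Hypergeom(universe, size_a, size_b).

    Summed in log space over the support for numerical stability.
    """
    _check_overlap_args(universe_size, size_a, size_b, observed_overlap)
    if observed_overlap == 0:
        return 1.0
    upper = min(size_a, size_b)
    support = np.arange(observed_overlap, upper + 1)
    logpmf = stats.hypergeom.logpmf(support, universe_size, size_a, size_b)
    return float(min(1.0, np.exp(logsumexp(logpmf))))
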