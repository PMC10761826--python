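"""Synthetic tumour-cohort generator with planted ground truth.

Emulates the statistical structure the stratification analysis assumes:
two latent sample groups, negative-binomial counts with symmetric planted
fold changes concentrated in a designated proteostasis-network-like (PN)
gene set, tumour-purity confounding entering as a per-gene stromal effect
scaled by the stromal fraction (1 - purity), and exponential survival
times whose hazard differs between groups.

All randomness flows from one root seed: ``numpy.random.SeedSequence(seed)``
is spawned into four independent child streams (gene/sample structure,
counts, purity, survival) so individual stages can be re-run reproducibly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import ClinicalTable, CountMatrix, DataError, ExpressionMatrix

#: per-sample library total for the FPKM-surrogate linear matrix
LINEAR_TOTAL = 1e6

#: sub-stream order for SeedSequence.spawn
_STREAMS = ("structure", "counts", "purity", "survival")


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the study conditions the analysis is exercised under:
    50 samples per group, a 2000-gene universe containing a 428-gene PN
    set, 300 differentially expressed genes at fold change 1.5 of which
    136 fall inside the PN set (the PN set is thus enriched for DE, as in
    the real cohorts), negative-binomial dispersion 0.2, Beta(6, 2)
    purity, and stromal confounding with per-gene effect spread 1.5 on the
    log2 scale.  Survival is exponential with baseline hazard 0.15 / year,
    hazard ratio 2.5 for group B, censored at 10 years.
    """

    n_samples_per_group: int = 50
    n_genes: int = 2000
    pn_set_size: int = 428
    n_de_in_pn: int = 136
    n_de_outside_pn: int = 164
    de_fold_change: float = 1.5
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 1.5
    nb_dispersion: float = 0.2
    purity_beta_params: tuple[float, float] = (6.0, 2.0)
    stroma_shift: float = 1.5
    survival_hazard_ratio: float = 2.5
    baseline_hazard: float = 0.15
    censor_horizon: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.n_de_in_pn <= self.pn_set_size <= self.n_genes):
            raise DataError(
                "need n_de_in_pn <= pn_set_size <= n_genes, got "
                f"{self.n_de_in_pn}/{self.pn_set_size}/{self.n_genes}"
            )
        if self.n_de_outside_pn > self.n_genes - self.pn_set_size:
            raise DataError("n_de_outside_pn exceeds the non-PN universe")
        if self.n_samples_per_group < 2:
            raise DataError("need at least 2 samples per group")
        for name in ("de_fold_change", "nb_dispersion", "survival_hazard_ratio",
                     "baseline_hazard", "censor_horizon"):
            if getattr(self, name) <= 0:
                raise DataError(f"{name} must be > 0")
        a, b = self.purity_beta_params
        if a <= 0 or b <= 0:
            raise DataError("purity_beta_params must be positive")
        if self.baseline_log2_sd < 0 or self.stroma_shift < 0:
            raise DataError("spreads must be >= 0")


@dataclass
class SimTruth:
    """Planted parameters: with the seed they fully determine the cohort."""

    group_of_sample: pd.Series            # sample_id -> "A" | "B"
    de_log2fc: pd.Series                  # DE gene -> signed log2 FC of A vs B
    pn_genes: frozenset[str]
    purity: pd.Series
    stromal_effect: pd.Series             # per-gene log2 effect of (1 - purity)
    seed: int
    config: SimConfig = field(repr=False)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "seed": self.seed,
            "config": dataclasses.asdict(self.config),
            "group_of_sample": self.group_of_sample.to_dict(),
            "de_log2fc": self.de_log2fc.to_dict(),
            "pn_genes": sorted(self.pn_genes),
            "purity": self.purity.to_dict(),
            "stromal_effect": self.stromal_effect.to_dict(),
        }
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw: Var = mu + dispersion * mu^2."""
    if dispersion < 1e-12:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_cohort(config: SimConfig) -> dict:
    """Generate one cohort.

    Returns a dict with keys ``counts`` (:class:`CountMatrix`), ``linear``
    (:class:`ExpressionMatrix`, counts rescaled to a fixed per-sample
    total), ``purity`` (Series), ``clinical`` (:class:`ClinicalTable`) and
    ``truth`` (:class:`SimTruth`).

    Per gene g and sample j the count mean on the log2 scale is

        b_g + I[group_j = B] * delta_g + (1 - purity_j) * c_g

    with b_g the gene baseline, delta_g = +-log2(de_fold_change) for the
    planted DE genes (0 otherwise; the sign of the A-vs-B log2 FC recorded
    in the truth is -delta_g), and c_g ~ N(0, stroma_shift) the stromal
    effect.  Counts are negative binomial with that mean and the
    configured dispersion.
    """
    cfg = config
    rngs = _streams(cfg.seed)
    rng = rngs["structure"]

    n = 2 * cfg.n_samples_per_group
    gene_ids = np.array([f"G{i:05d}" for i in range(cfg.n_genes)])
    sample_ids = np.array([f"S{i:04d}" for i in range(n)])

    # latent groups, shuffled so sample order does not encode the group
    group = np.array(["A"] * cfg.n_samples_per_group + ["B"] * cfg.n_samples_per_group)
    group = group[rng.permutation(n)]

    pn_idx = rng.choice(cfg.n_genes, size=cfg.pn_set_size, replace=False)
    pn_mask = np.zeros(cfg.n_genes, dtype=bool)
    pn_mask[pn_idx] = True

    de_in_pn = rng.choice(np.flatnonzero(pn_mask), size=cfg.n_de_in_pn, replace=False)
    de_outside = rng.choice(
        np.flatnonzero(~pn_mask), size=cfg.n_de_outside_pn, replace=False
    )
    de_idx = np.concatenate([de_in_pn, de_outside])
    signs = rng.choice([-1.0, 1.0], size=de_idx.size)

    delta = np.zeros(cfg.n_genes)
    if cfg.de_fold_change != 1.0:
        delta[de_idx] = signs * np.log2(cfg.de_fold_change)

    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, cfg.n_genes)
    stromal = (
        rng.normal(0.0, cfg.stroma_shift, cfg.n_genes)
        if cfg.stroma_shift > 0
        else np.zeros(cfg.n_genes)
    )

    a, b = cfg.purity_beta_params
    purity = rngs["purity"].beta(a, b, size=n)

    is_b = (group == "B").astype(float)
    log2_mean = (
        baseline[:, None]
        + delta[:, None] * is_b[None, :]
        + stromal[:, None] * (1.0 - purity)[None, :]
    )
    mu = np.exp2(log2_mean)
    counts = _nb_counts(rngs["counts"], mu, cfg.nb_dispersion)

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    totals = counts_df.sum(axis=0).to_numpy().astype(float)
    if (totals == 0).any():
        raise DataError("a simulated sample has zero total counts; increase means")
    linear_df = counts_df / totals * LINEAR_TOTAL

    clinical = simulate_survival(
        pd.Series(group, index=sample_ids),
        hazard_ratio=cfg.survival_hazard_ratio,
        baseline_hazard=cfg.baseline_hazard,
        censor_horizon=cfg.censor_horizon,
        rng=rngs["survival"],
    )

    # A-vs-B log2 fold change: group B carries +delta, so A relative to B is -delta
    de_genes = gene_ids[de_idx]
    truth = SimTruth(
        group_of_sample=pd.Series(group, index=sample_ids),
        de_log2fc=pd.Series(-delta[de_idx], index=de_genes),
        pn_genes=frozenset(gene_ids[pn_mask]),
        purity=pd.Series(purity, index=sample_ids),
        stromal_effect=pd.Series(stromal, index=gene_ids),
        seed=cfg.seed,
        config=cfg,
    )
    return {
        "counts": CountMatrix(counts_df),
        "linear": ExpressionMatrix(linear_df, scale="linear"),
        "purity": truth.purity.copy(),
        "clinical": clinical,
        "truth": truth,
    }


def simulate_survival(
    groups: pd.Series,
    hazard_ratio: float,
    baseline_hazard: float,
    censor_horizon: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ClinicalTable:
    """Exponential survival with a proportional-hazards group contrast.

    Group "B" samples have hazard ``baseline_hazard * hazard_ratio``;
    events beyond ``censor_horizon`` are emitted censored at the horizon.
    Age, gender, stage, pigmentation and subsequent metastasis are drawn
    independently of the group so covariate-adjusted analyses are exercised
    under a clean null for those covariates.
    """
    if groups.nunique() < 2:
        raise DataError("survival simulation needs two groups")
    if hazard_ratio <= 0 or baseline_hazard <= 0 or censor_horizon < 0:
        raise DataError("rates must be positive and horizon non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)

    n = len(groups)
    hazard = baseline_hazard * np.where(groups.to_numpy() == "B", hazard_ratio, 1.0)
    raw_times = rng.exponential(1.0 / hazard)
    event = (raw_times <= censor_horizon).astype(int)
    times = np.minimum(raw_times, censor_horizon)
    times = np.maximum(times, 1e-6)  # time_to_event must stay positive

    df = pd.DataFrame(
        {
            "time_years": times,
            "event": event,
            "age": np.round(rng.normal(60.0, 12.0, n), 1),
            "gender": rng.choice(["female", "male"], size=n),
            "stage": rng.choice(["I", "II", "III", "IV"], size=n, p=[0.3, 0.35, 0.25, 0.1]),
            "pigmentation_score": rng.choice([0, 1, 2, 3], size=n).astype(float),
            "subsequent_metastasis": rng.choice(["yes", "no"], size=n),
        },
        index=groups.index,
    )
    # sprinkle missingness into optional clinical fields, as in real registries
    miss = rng.random(n) < 0.1
    df.loc[miss, "pigmentation_score"] = np.nan
    return ClinicalTable(df)
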