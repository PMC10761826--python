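"""End-to-end orchestration: cohort -> purity adjustment -> clustering ->
composite DE -> resampling nulls -> annotation -> survival, into one
machine-readable JSON report.

The cohort is either simulated (a ``synthetic`` config section) or read
from TSV/GMT files (an ``inputs`` section).  Every stochastic stage
records its seed in the report; an identical config yields an identical
report.
"""

from __future__ import annotations

import dataclasses
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score

from . import annotation as ann
from . import datamodel as dm
from . import diffexp, nulls, purity, stratify, survival as surv
from .datamodel import DataError, GeneSetCollection, logger
from .synthetic import SimConfig, simulate_cohort

DEFAULTS = {
    "k_samples": 2,
    "k_genes": 2,
    "de_thresholds": {"p": 0.05, "q": 0.1, "fc_low": 0.8, "fc_high": 1.25},
    "null": {"n_iter": 1000, "set_size": 428, "n_sim": 5000},
    "survival": {"horizon": None, "covariates": ["age", "stage", "gender"]},
    "pseudocount": 1.0,
    "seed": 0,
}


def load_config(config: str | Path | dict) -> dict:
    if isinstance(config, (str, Path)):
        with open(config, encoding="utf-8") as handle:
            config = yaml.safe_load(handle)
    config = dict(config)
    if None in config:  # YAML parses a bare "null:" key as None
        config["null"] = config.pop(None)
    cfg = {**DEFAULTS, **config}
    for key in ("de_thresholds", "null", "survival"):
        cfg[key] = {**DEFAULTS[key], **(config.get(key) or {})}
    if ("synthetic" in cfg) == ("inputs" in cfg):
        raise DataError("config must name exactly one of 'synthetic' or 'inputs'")
    return cfg


def _synthetic_annotation_sets(pn_genes: list[str], de_universe: list[str],
                               seed: int) -> tuple[GeneSetCollection, GeneSetCollection]:
    """Pseudo chaperone families (a partition of the PN set into chunks) and
    pseudo TF target sets (random subsets of the gene universe) so the
    annotation stage is exercised on synthetic cohorts."""
    rng = np.random.default_rng(seed)
    pn = sorted(pn_genes)
    n_fam = 7
    chunks = np.array_split(np.array(pn), n_fam)
    fam_names = ["HSP70_like", "HSP90_like", "HSP40_like", "HSP60_like",
                 "PPIase_like", "NEF_like", "sHSP_like"]
    families = GeneSetCollection(
        sets={name: frozenset(chunk) for name, chunk in zip(fam_names, chunks)},
        roles={name: "family" for name in fam_names},
    )
    tf_sets = {}
    for tf in ("TF1", "TF2", "TF3"):
        size = max(1, int(0.4 * len(de_universe)))
        tf_sets[tf] = frozenset(rng.choice(de_universe, size=size, replace=False))
    tfs = GeneSetCollection(sets=tf_sets, roles={t: "tf_targets" for t in tf_sets})
    return families, tfs


def run_pipeline(config: str | Path | dict) -> dict:
    """Run the full analysis; returns the report dict.

    On a stage failure the report carries an ``error`` section naming the
    stage and the partial results computed so far.
    """
    cfg = load_config(config)
    report: dict = {"config": _jsonable(cfg), "stages": []}
    stage = "setup"
    t0 = time.time()
    try:
        # ---------------- cohort ----------------
        stage = "cohort"
        if "synthetic" in cfg:
            sim_cfg = SimConfig(**{**cfg["synthetic"], "seed": cfg["synthetic"].get("seed", cfg["seed"])})
            sim = simulate_cohort(sim_cfg)
            counts, linear = sim["counts"], sim["linear"]
            purity_vec, clinical, truth = sim["purity"], sim["clinical"], sim["truth"]
            pn_genes = sorted(truth.pn_genes)
            families, tf_targets = _synthetic_annotation_sets(
                pn_genes, list(counts.gene_ids), sim_cfg.seed + 1
            )
            report["cohort"] = {
                "source": "synthetic",
                "seed": sim_cfg.seed,
                "n_genes": counts.shape[0],
                "n_samples": counts.shape[1],
                "pn_set_size": len(pn_genes),
                "n_planted_de": int(truth.de_log2fc.size),
            }
        else:
            paths = cfg["inputs"]
            for key in ("counts", "fpkm", "purity", "clinical"):
                if key in paths and not Path(paths[key]).exists():
                    raise DataError(f"input file missing: {paths[key]}")
            if "pn_sets" not in cfg or not Path(cfg["pn_sets"]["gmt"]).exists():
                raise DataError("real-data runs need pn_sets: {gmt, pn_core}")
            counts = dm.read_expression_table(paths["counts"], "counts")
            linear = dm.read_expression_table(paths["fpkm"], "linear")
            purity_vec = dm.read_purity_table(paths["purity"])
            clinical = dm.read_clinical_table(paths["clinical"])
            collection = dm.read_gene_sets_gmt(cfg["pn_sets"]["gmt"])
            pn_genes = sorted(collection[cfg["pn_sets"]["pn_core"]])
            truth = None
            families = (dm.read_gene_sets_gmt(cfg["families_gmt"])
                        if cfg.get("families_gmt") else None)
            tf_targets = (dm.read_gene_sets_gmt(cfg["tf_targets_gmt"])
                          if cfg.get("tf_targets_gmt") else None)
            report["cohort"] = {
                "source": "files",
                "n_genes": counts.shape[0],
                "n_samples": counts.shape[1],
                "pn_set_size": len(pn_genes),
            }
        report["stages"].append("cohort")

        # ---------------- purity adjustment ----------------
        stage = "adjust"
        logexpr = purity.log_transform(linear, pseudocount=cfg["pseudocount"])
        residuals = purity.adjust_for_purity(logexpr, purity_vec)
        corr = _max_abs_purity_corr(residuals)
        report["adjust"] = {
            "n_samples_used": residuals.shape[1],
            "pseudocount": cfg["pseudocount"],
            "max_abs_residual_purity_corr": corr,
        }
        report["stages"].append("adjust")

        # ---------------- clustering ----------------
        stage = "cluster"
        pn_present = [g for g in pn_genes if g in residuals.gene_ids]
        pn_resid = residuals.data.loc[pn_present]
        z_resid = stratify.zscore_genes(pn_resid)
        raw_samples = stratify.ward_cluster(z_resid, axis="samples", k=cfg["k_samples"])
        gene_grouping = stratify.ward_cluster(z_resid, axis="genes", k=cfg["k_genes"])
        grouping = stratify.label_groups(raw_samples, gene_grouping, pn_resid)
        merged = grouping
        if grouping.k > 2:
            merge_map = {lab: lab[0] for lab in grouping.labels.unique()}
            merged = stratify.merge_subgroups(grouping, merge_map)
        cluster_section = {
            "k_samples": cfg["k_samples"],
            "k_genes": cfg["k_genes"],
            "sizes": grouping.sizes(),
            "merged_sizes": merged.sizes(),
            "labels": merged.labels.to_dict(),
        }
        if truth is not None:
            truth_labels = truth.group_of_sample.reindex(merged.labels.index)
            ari_adj = adjusted_rand_score(truth_labels, merged.labels)
            # unadjusted comparison: same clustering on z-scored log expression
            z_unadj = stratify.zscore_genes(logexpr.data.loc[pn_present,
                                                             residuals.sample_ids])
            unadj = stratify.ward_cluster(z_unadj, axis="samples", k=cfg["k_samples"])
            ari_unadj = adjusted_rand_score(
                truth.group_of_sample.reindex(unadj.labels.index), unadj.labels
            )
            cluster_section["adjusted_rand_vs_truth"] = float(ari_adj)
            cluster_section["adjusted_rand_unadjusted"] = float(ari_unadj)
            purity_used = residuals.purity_used
            cluster_section["corr_label_purity_unadjusted"] = float(abs(np.corrcoef(
                pd.factorize(unadj.labels)[0], purity_used.reindex(unadj.labels.index)
            )[0, 1]))
        report["cluster"] = cluster_section
        report["stages"].append("cluster")

        # ---------------- differential expression ----------------
        stage = "de"
        th = diffexp.DEThresholds(**cfg["de_thresholds"])
        de_table = diffexp.run_de(
            counts, linear, residuals, merged.labels, genes=pn_present, thresholds=th
        )
        de_counts = de_table["call"].value_counts().to_dict()
        de_section = {
            "thresholds": dataclasses.asdict(th),
            "n_lower": int(de_counts.get("lower", 0)),
            "n_higher": int(de_counts.get("higher", 0)),
            "n_unchanged": int(de_counts.get("unchanged", 0)),
            "proportion_called": float((de_table["call"] != "unchanged").mean()),
        }
        if truth is not None:
            de_section.update(_de_recovery(de_table, truth, merged.labels))
        report["de"] = de_section
        report["stages"].append("de")

        # ---------------- resampling nulls ----------------
        stage = "nulls"
        null_cfg = cfg["null"]
        set_size = min(null_cfg["set_size"], counts.shape[0])
        null = nulls.random_geneset_de_proportion(
            counts, linear, residuals, merged.labels, pn_present,
            set_size=set_size, n_iter=null_cfg["n_iter"],
            seed=cfg["seed"] + 101, thresholds=th,
        )
        report["nulls"] = {
            "random_geneset": null.summary(),
            "n_iter": null_cfg["n_iter"],
            "set_size": set_size,
        }
        report["stages"].append("nulls")

        # ---------------- annotation ----------------
        stage = "annotate"
        annotate_section = {}
        if families is not None:
            breakdown = ann.family_breakdown(de_table, families)
            annotate_section["families"] = {
                fam: {"prop_lower": row["prop_lower"],
                      "prop_higher": row["prop_higher"],
                      "prop_unchanged": row["prop_unchanged"],
                      "n_genes": int(row["n_genes"])}
                for fam, row in breakdown.iterrows()
            }
            first = families.names()[-1]
            annotate_section["mean_set_test"] = ann.mean_set_expression_test(
                residuals, families[first], merged.labels
            ) | {"set": first}
        de_genes = list(de_table.index[de_table["call"] != "unchanged"])
        if tf_targets is not None and de_genes:
            coverage, _ = ann.tf_target_coverage(de_genes, tf_targets)
            annotate_section["tf_coverage"] = coverage.to_dict()
        report["annotate"] = annotate_section
        report["stages"].append("annotate")

        # ---------------- survival / clinical ----------------
        stage = "survival"
        surv_cfg = cfg["survival"]
        km = surv.km_logrank(clinical, merged.labels, horizon_years=surv_cfg["horizon"])
        cox = surv.cox_ph(clinical, merged.labels,
                          covariates=surv_cfg["covariates"],
                          horizon_years=surv_cfg["horizon"])
        km.cox = cox
        surv_section = km.summary()
        pig = ann.recode_pigmentation(clinical.data["pigmentation_score"])
        recoded = dm.ClinicalTable(clinical.data.assign(pigmentation=pig))
        surv_section["attributes"] = {
            name: surv.attribute_association(recoded, merged.labels, name)
            for name in ("age", "gender", "pigmentation", "subsequent_metastasis")
            if name in recoded.data.columns
        }
        report["survival"] = surv_section
        report["stages"].append("survival")
    except Exception as exc:
        report["error"] = {"stage": stage, "message": str(exc)}
        logger.error("pipeline failed at stage %s: %s", stage, exc)
    report["elapsed_seconds"] = round(time.time() - t0, 3)
    return report


def _max_abs_purity_corr(residuals) -> float:
    p = residuals.purity_used.reindex(residuals.sample_ids).to_numpy(dtype=float)
    pc = p - p.mean()
    denom_p = np.sqrt((pc**2).sum())
    y = residuals.data.to_numpy()
    yc = y - y.mean(axis=1, keepdims=True)
    denom_y = np.sqrt((yc**2).sum(axis=1))
    denom_y[denom_y == 0] = 1.0
    if denom_p == 0:
        return 0.0
    corr = (yc @ pc) / (denom_y * denom_p)
    return float(np.max(np.abs(corr)))


def _de_recovery(de_table: pd.DataFrame, truth, grouping: pd.Series) -> dict:
    called = de_table.index[de_table["call"] != "unchanged"]
    planted = set(truth.de_log2fc.index) & set(de_table.index)
    tp = len(set(called) & planted)
    sensitivity = tp / len(planted) if planted else float("nan")
    fdr = 1 - tp / len(called) if len(called) else 0.0
    # direction agreement: the clustering's A/B assignment is arbitrary
    # relative to the truth, so align labels by majority overlap first
    truth_labels = truth.group_of_sample.reindex(grouping.index)
    flipped = (grouping == truth_labels).mean() < 0.5
    agree = 0
    for g in set(called) & planted:
        sign = truth.de_log2fc[g]
        want = "lower" if (sign < 0) != flipped else "higher"
        agree += de_table.loc[g, "call"] == want
    return {
        "sensitivity": float(sensitivity),
        "empirical_fdr": float(fdr),
        "direction_agreement": float(agree / tp) if tp else float("nan"),
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj
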