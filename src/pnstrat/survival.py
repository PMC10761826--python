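"""Survival contrasts between expression subtypes and clinical associations.

Kaplan-Meier curves with a log-rank test across subtypes, Cox
proportional-hazards models with clinical covariates (Efron ties), and a
dispatcher that associates arbitrary clinical attributes with the
grouping (Fisher's exact test for categorical, Student's t for numeric).
Events past an analysis horizon are recoded as censored at the horizon
before estimation, matching a fixed-window survival analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .annotation import fisher_category_test
from .datamodel import ClinicalTable, DataError, logger

STAGE_ORDER = ("I", "II", "III", "IV")


@dataclass
class SurvivalResult:
    km_curves: dict[str, pd.DataFrame]   # per group: time, survival, at_risk
    logrank_statistic: float
    logrank_p: float
    horizon: float | None
    cox: pd.DataFrame | None = field(default=None)

    def summary(self) -> dict:
        out = {
            "logrank_statistic": self.logrank_statistic,
            "logrank_p": self.logrank_p,
            "horizon": self.horizon,
            "groups": {
                g: {"n": int(df["at_risk"].iloc[0]), "final_survival": float(df["survival"].iloc[-1])}
                for g, df in self.km_curves.items()
            },
        }
        if self.cox is not None:
            out["cox"] = {
                cov: {"hazard_ratio": float(r["hazard_ratio"]),
                      "p": float(r["p"]),
                      "log_hr": float(r["log_hr"]),
                      "se": float(r["se"])}
                for cov, r in self.cox.iterrows()
            }
        return out


def apply_horizon(clinical: ClinicalTable, horizon_years: float | None) -> pd.DataFrame:
    """Recode events beyond the horizon as censored at the horizon."""
    df = clinical.data[["time_years", "event"]].dropna().copy()
    df["time_years"] = df["time_years"].astype(float)
    df["event"] = df["event"].astype(int)
    if horizon_years is not None:
        if horizon_years <= 0:
            raise DataError("horizon must be positive")
        past = df["time_years"] > horizon_years
        df.loc[past, "event"] = 0
        df.loc[past, "time_years"] = horizon_years
    return df


def km_logrank(
    clinical: ClinicalTable,
    grouping: pd.Series,
    horizon_years: float | None = None,
) -> SurvivalResult:
    """Kaplan-Meier curves per group and the log-rank test across groups."""
    df = apply_horizon(clinical, horizon_years)
    grouping = grouping.reindex(df.index).dropna()
    df = df.loc[grouping.index]
    groups = sorted(grouping.unique())
    if len(groups) < 2:
        raise DataError("need at least two groups for a survival contrast")
    for g in groups:
        if (grouping == g).sum() == 0:
            raise DataError(f"group {g!r} has no subjects")

    curves: dict[str, pd.DataFrame] = {}
    for g in groups:
        sub = df.loc[grouping.index[grouping == g]]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time_years"], sub["event"], label=str(g))
        table = kmf.event_table
        curves[str(g)] = pd.DataFrame(
            {
                "time": table.index.to_numpy(dtype=float),
                "survival": kmf.survival_function_.iloc[:, 0].reindex(table.index).to_numpy(),
                "at_risk": table["at_risk"].to_numpy(),
            }
        )
    res = multivariate_logrank_test(df["time_years"], grouping, df["event"])
    return SurvivalResult(
        km_curves=curves,
        logrank_statistic=float(res.test_statistic),
        logrank_p=float(res.p_value),
        horizon=horizon_years,
    )


def _encode_covariates(clinical: pd.DataFrame, covariates) -> pd.DataFrame:
    """Numeric design columns for the Cox fit.

    ``stage`` collapses TCGA-style sub-stages (e.g. IIIa) to the major
    Roman numeral and enters as ordinal 1-4; ``gender`` and other
    categoricals are dummy-coded against their alphabetically first level.
    """
    out = pd.DataFrame(index=clinical.index)
    for cov in covariates:
        if cov not in clinical.columns:
            raise DataError(f"covariate {cov!r} absent from the clinical table")
        col = clinical[cov]
        if cov == "stage":
            major = col.astype(str).str.upper().str.extract(r"(IV|III|II|I)")[0]
            out["stage"] = major.map({s: i + 1 for i, s in enumerate(STAGE_ORDER)})
        elif pd.api.types.is_numeric_dtype(col):
            out[cov] = col.astype(float)
        else:
            levels = sorted(col.dropna().unique())
            for lev in levels[1:]:
                out[f"{cov}_{lev}"] = (col == lev).astype(float)
    return out


def cox_ph(
    clinical: ClinicalTable,
    grouping: pd.Series,
    covariates=("age", "stage", "gender"),
    horizon_years: float | None = None,
) -> pd.DataFrame:
    """Cox proportional-hazards fit of the group contrast with covariates.

    The group enters as a dummy against the alphabetically first label
    (the indexed coefficient is named ``group_<label>``); ties are handled
    by Efron's method (the lifelines default).  Zero-variance covariates
    are dropped with a warning.
    """
    surv = apply_horizon(clinical, horizon_years)
    grouping = grouping.reindex(surv.index).dropna()
    surv = surv.loc[grouping.index]
    groups = sorted(grouping.unique())
    if len(groups) < 2:
        raise DataError("need at least two groups")

    design = pd.DataFrame(index=surv.index)
    for g in groups[1:]:
        design[f"group_{g}"] = (grouping == g).astype(float)
    design = design.join(_encode_covariates(clinical.data.loc[surv.index], covariates))

    keep = design.notna().all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("Cox fit: dropping %d subjects with missing covariates", dropped)
    design, surv = design.loc[keep], surv.loc[keep]

    for col in list(design.columns):
        if design[col].nunique() <= 1:
            logger.warning("Cox fit: dropping zero-variance covariate %r", col)
            design = design.drop(columns=col)

    frame = pd.concat([surv, design], axis=1)
    cph = CoxPHFitter()
    try:
        cph.fit(frame, duration_col="time_years", event_col="event")
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise DataError(f"Cox model failed to converge: {exc}") from exc
    summary = cph.summary
    return pd.DataFrame(
        {
            "log_hr": summary["coef"],
            "hazard_ratio": summary["exp(coef)"],
            "se": summary["se(coef)"],
            "p": summary["p"],
        }
    )


def attribute_association(
    clinical: ClinicalTable, grouping: pd.Series, attribute: str
) -> dict:
    """Associate a clinical attribute with the grouping.

    Numeric attributes are compared with a two-sample Student t-test (two
    groups required); categorical attributes with the exact 2xk Fisher
    test on the group x level contingency table.
    """
    if attribute not in clinical.data.columns:
        raise DataError(f"attribute {attribute!r} absent from the clinical table")
    col = clinical.data[attribute]
    grouping = grouping.reindex(clinical.sample_ids)
    keep = col.notna() & grouping.notna()
    col, grouping = col[keep], grouping[keep]
    groups = sorted(grouping.unique())

    if pd.api.types.is_numeric_dtype(col):
        if len(groups) != 2:
            raise DataError("numeric attribute contrast needs exactly two groups")
        a = col[grouping == groups[0]].astype(float).to_numpy()
        b = col[grouping == groups[1]].astype(float).to_numpy()
        res = stats.ttest_ind(a, b, equal_var=True)
        p = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
        return {
            "attribute": attribute,
            "test": "t",
            "means": {groups[0]: float(a.mean()), groups[1]: float(b.mean())},
            "p": p,
        }
    if len(groups) != 2:
        raise DataError("categorical association implemented for two groups")
    table = pd.crosstab(grouping, col)
    p = fisher_category_test(table.to_numpy())
    return {
        "attribute": attribute,
        "test": "fisher",
        "table": {str(g): table.loc[g].to_dict() for g in table.index},
        "p": p,
    }
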