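"""Derivation of the eight cardiovascular risk-factor outcomes.

Outcomes: BMI, waist circumference, fasting glucose, triglycerides, HDL- and
LDL-cholesterol, systolic and diastolic blood pressure, each at baseline and
after one year, plus their one-year changes.  LDL uses the Friedewald
formula below 300 mg/dL triglycerides and the directly measured value above;
blood pressure is the mean of up to three readings; missing follow-up BMI
and diastolic BP are mean-imputed, mirroring the cohort analysis plan.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["bmi", "mean_bp", "ldl", "impute_mean", "outcome_change",
           "derive_outcomes", "OUTCOMES"]

#: canonical outcome column names, in table order
OUTCOMES = ("glucose", "hdl", "tg", "ldl", "dbp", "sbp", "bmi", "waist")

FRIEDEWALD_TG_LIMIT = 300.0  # mg/dL


def bmi(weight_kg: float, height_m: float) -> float:
    """Body mass index: weight (kg) divided by height (m) squared."""
    if height_m <= 0:
        raise ValueError("height must be positive")
    return weight_kg / height_m**2


def mean_bp(readings) -> float:
    """Mean of up to three blood-pressure readings (mmHg).

    Partial reading sets use the mean of the available readings; an empty
    set yields NaN.
    """
    r = np.asarray(readings, dtype=float)
    if r.size == 0 or np.isnan(r).all():
        return float("nan")
    return float(np.nanmean(r))


def ldl(tc: float, hdl: float, tg: float,
        direct_ldl: float | None = None) -> float:
    """LDL cholesterol in mg/dL.

    Friedewald estimate ``tc - hdl - tg/5`` when triglycerides are below
    300 mg/dL; otherwise the direct measurement (NaN, with a warning, when
    no direct value is available).
    """
    if tg < 0:
        raise ValueError("triglycerides must be non-negative")
    if tc < hdl:
        raise ValueError("total cholesterol below HDL")
    if tg < FRIEDEWALD_TG_LIMIT:
        return tc - hdl - tg / 5.0
    if direct_ldl is None or (isinstance(direct_ldl, float)
                              and np.isnan(direct_ldl)):
        warnings.warn("triglycerides >= 300 mg/dL with no direct LDL "
                      "measurement; LDL set missing", stacklevel=2)
        return float("nan")
    return float(direct_ldl)


def impute_mean(values: pd.Series) -> tuple[pd.Series, pd.Index]:
    """Replace missing entries by the mean of the observed entries.

    Returns the completed vector and the index of imputed positions.
    Observed entries are untouched; the observed mean is preserved.
    """
    v = pd.Series(values, dtype=float)
    missing = v.index[v.isna()]
    if len(missing) == len(v):
        raise ValueError("cannot mean-impute an all-missing vector")
    out = v.fillna(v.mean())
    return out, missing


def outcome_change(baseline, year1):
    """One-year change, ``year1 - baseline`` (same orientation as the
    dietary-index change).  Missing values propagate."""
    return year1 - baseline


def derive_outcomes(cohort: pd.DataFrame,
                    impute: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the eight outcomes and their changes from raw measurements.

    Parameters
    ----------
    cohort
        One row per participant x timepoint with raw fields
        ``participant_id, timepoint, weight_kg, height_m, waist_cm,
        sbp1..sbp3, dbp1..dbp3, glucose, tc, hdl, tg`` and optionally
        ``ldl_direct``.
    impute
        Mean-impute missing year-1 BMI and diastolic BP (the two variables
        the analysis plan imputes); everything else stays complete-case.

    Returns
    -------
    wide
        One row per participant with ``<outcome>_baseline``,
        ``<outcome>_year1`` and ``<outcome>_change`` columns.
    imputation_log
        ``participant_id, variable`` rows for each imputed value.
    """
    df = cohort.copy()
    df["bmi"] = df["weight_kg"] / df["height_m"] ** 2
    df["waist"] = df["waist_cm"]
    sbp_cols = [c for c in ("sbp1", "sbp2", "sbp3") if c in df.columns]
    dbp_cols = [c for c in ("dbp1", "dbp2", "dbp3") if c in df.columns]
    df["sbp"] = df[sbp_cols].mean(axis=1)
    df["dbp"] = df[dbp_cols].mean(axis=1)
    direct = df["ldl_direct"] if "ldl_direct" in df.columns else np.nan
    friedewald = df["tc"] - df["hdl"] - df["tg"] / 5.0
    df["ldl"] = np.where(df["tg"] < FRIEDEWALD_TG_LIMIT, friedewald, direct)

    wide = df.pivot(index="participant_id", columns="timepoint",
                    values=list(OUTCOMES))
    out = pd.DataFrame(index=wide.index)
    for oc in OUTCOMES:
        out[f"{oc}_baseline"] = wide[(oc, "baseline")]
        out[f"{oc}_year1"] = wide[(oc, "year1")]

    log_rows = []
    if impute:
        for oc in ("bmi", "dbp"):
            col = f"{oc}_year1"
            if out[col].isna().any():
                out[col], imputed = impute_mean(out[col])
                log_rows += [(pid, col) for pid in imputed]
    for oc in OUTCOMES:
        out[f"{oc}_change"] = outcome_change(out[f"{oc}_baseline"],
                                             out[f"{oc}_year1"])
    log = pd.DataFrame(log_rows, columns=["participant_id", "variable"])
    return out.reset_index(), log
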