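"""Linear-regression association analysis of CVD risk factors on the
FSAm-NPS dietary index.

Implements the three-tier modelling strategy of the cohort analysis:

* **crude** -- exposure only;
* **model 1** -- adds age, sex, BMI, education, smoking, total energy,
  physical activity and marital status (BMI is removed when BMI or waist is
  the outcome);
* **fully adjusted** -- model 1 plus lipid/hypertension/diabetes medication
  and recruitment-centre size class; the prospective analysis additionally
  adjusts for intervention arm and, from model 1 up, for the outcome's
  baseline level.

The exposure enters either as tertile indicators (T1 = reference, best
nutritional quality) or as a continuous variable.  All variances are
cluster-robust sandwich estimates with the small-sample factor
``(G/(G-1)) * ((N-1)/(N-k))``; confidence intervals use the normal 1.96
multiplier by default.  A trend test across tertiles replaces the
indicators by an ordinal 1/2/3 term in the same adjusted model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
import statsmodels.formula.api as smf

from .outcomes import OUTCOMES

__all__ = ["ModelSpec", "ModelResult", "fit_linear", "robust_cluster_vcov",
           "p_trend", "run_table2", "run_table3", "descriptive_table"]

TIERS = ("crude", "model1", "full")

#: (data column, patsy term) pairs; reference levels are explicit
_MODEL1_TERMS = [
    ("age", "age"),
    ("sex", 'C(sex, Treatment("female"))'),
    ("bmi_baseline", "bmi_baseline"),
    ("education", 'C(education, Treatment("primary"))'),
    ("smoking", 'C(smoking, Treatment("never"))'),
    ("energy_kcal", "energy_kcal"),
    ("pa_met_min_week", "pa_met_min_week"),
    ("marital", 'C(marital, Treatment("married"))'),
]
_FULL_EXTRA_TERMS = [
    ("med_lipid", "med_lipid"),
    ("med_htn", "med_htn"),
    ("med_diabetes", "med_diabetes"),
    ("center_size", 'C(center_size, Treatment("<250"))'),
]
_ARM_TERM = ("arm", 'C(arm, Treatment("control"))')


@dataclass(frozen=True)
class ModelSpec:
    """One regression of the analysis grid.

    ``exposure`` is ``"tertile"`` or ``"continuous"``; ``tier`` one of
    crude/model1/full; ``analysis`` ``"cross_sectional"`` (baseline levels
    on baseline index) or ``"prospective"`` (1-year changes on index
    change).  ``cluster`` names the intra-cluster correlation unit.
    """

    outcome: str
    exposure: str = "continuous"
    tier: str = "crude"
    analysis: str = "cross_sectional"
    cluster: str = "cluster_id"

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.exposure not in ("tertile", "continuous"):
            raise ValueError(f"unknown exposure coding {self.exposure!r}")
        if self.tier not in TIERS:
            raise ValueError(f"unknown adjustment tier {self.tier!r}")
        if self.analysis not in ("cross_sectional", "prospective"):
            raise ValueError(f"unknown analysis {self.analysis!r}")

    @property
    def outcome_col(self) -> str:
        suffix = "baseline" if self.analysis == "cross_sectional" else "change"
        return f"{self.outcome}_{suffix}"

    @property
    def exposure_col(self) -> str:
        base = "di_baseline" if self.analysis == "cross_sectional" else "di_change"
        return f"{base}_tertile" if self.exposure == "tertile" else base

    def exposure_term(self, ordinal: bool = False) -> str:
        if self.exposure == "continuous":
            return self.exposure_col
        return self.exposure_col if ordinal \
            else f"C({self.exposure_col}, Treatment(1))"

    def covariate_terms(self) -> list[tuple[str, str]]:
        """(column, patsy term) pairs for the spec's adjustment tier."""
        if self.tier == "crude":
            return []
        terms = list(_MODEL1_TERMS)
        if self.outcome in ("bmi", "waist"):
            terms = [t for t in terms if t[0] != "bmi_baseline"]
        if self.analysis == "prospective":
            base = f"{self.outcome}_baseline"
            if all(c != base for c, _ in terms):
                terms.append((base, base))
        if self.tier == "full":
            terms += _FULL_EXTRA_TERMS
            if self.analysis == "prospective":
                terms.append(_ARM_TERM)
        return terms

    def columns(self) -> list[str]:
        cols = [self.outcome_col, self.exposure_col, self.cluster]
        cols += [c for c, _ in self.covariate_terms()]
        return list(dict.fromkeys(cols))

    def formula(self, ordinal: bool = False) -> str:
        rhs = [self.exposure_term(ordinal=ordinal)]
        rhs += [t for _, t in self.covariate_terms()]
        return f"{self.outcome_col} ~ " + " + ".join(rhs)


@dataclass
class ModelResult:
    """Fitted coefficients of interest with robust inference.

    ``params`` holds one row per exposure coefficient (T2/T3 versus T1, or
    the continuous slope) with ``beta, se, ci_low, ci_high, p``.  ``r2``
    follows the reporting convention of multiplying R-squared by 100.
    """

    spec: ModelSpec
    params: pd.DataFrame
    n: int
    r2: float
    p_trend: float | None = None
    robust: str = "cluster"
    fit: object = field(default=None, repr=False)


def _check_rank(model) -> None:
    X = np.asarray(model.exog)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, piv = scipy.linalg.qr(X, pivoting=True, mode="economic")
        names = np.asarray(model.exog_names)
        collinear = sorted(names[piv[rank:]])
        raise ValueError(f"rank-deficient design; collinear columns: "
                         f"{collinear}")


def _fit(formula: str, data: pd.DataFrame, cluster: np.ndarray):
    model = smf.ols(formula, data=data)
    _check_rank(model)
    if len(np.unique(cluster)) < 2:
        warnings.warn("fewer than 2 clusters; falling back to "
                      "heteroskedasticity-robust (HC1) variance", stacklevel=3)
        return model.fit(cov_type="HC1", use_t=False), "HC1"
    return model.fit(cov_type="cluster",
                     cov_kwds={"groups": cluster, "use_correction": True},
                     use_t=False), "cluster"


def fit_linear(data: pd.DataFrame, spec: ModelSpec,
               ci_mult: float = 1.959963984540054) -> ModelResult:
    """Fit one regression of the grid on complete-case rows.

    OLS point estimates; cluster-robust sandwich variance (HC1 fallback
    below two clusters, with a warning); CI = beta +/- 1.96 * SE.
    """
    cols = spec.columns()
    missing_cols = [c for c in cols if c not in data.columns]
    if missing_cols:
        raise KeyError(f"data lacks columns {missing_cols}")
    sub = data[cols].dropna()
    if sub[spec.cluster].isna().any():
        raise ValueError("missing cluster id")
    res, robust = _fit(spec.formula(), sub, sub[spec.cluster].to_numpy())
    if spec.exposure == "continuous":
        terms = {spec.exposure_col: "continuous"}
    else:
        base = f"C({spec.exposure_col}, Treatment(1))"
        terms = {f"{base}[T.2]": "T2", f"{base}[T.3]": "T3"}
    rows = []
    for name, label in terms.items():
        beta = res.params[name]
        se = res.bse[name]
        rows.append({"term": label, "beta": beta, "se": se,
                     "ci_low": beta - ci_mult * se,
                     "ci_high": beta + ci_mult * se,
                     "p": res.pvalues[name]})
    pt = p_trend(data, spec) if spec.exposure == "tertile" else None
    return ModelResult(spec=spec, params=pd.DataFrame(rows),
                       n=int(res.nobs), r2=100.0 * res.rsquared,
                       p_trend=pt, robust=robust, fit=res)


def robust_cluster_vcov(results, groups) -> np.ndarray:
    """Cluster-robust sandwich covariance of an OLS fit.

    Applies the small-sample factor ``(G/(G-1)) * ((N-1)/(N-k))``; with
    every cluster a singleton this reduces to the HC1-type estimator up to
    that factor.
    """
    groups = pd.Series(np.asarray(groups))
    if len(groups) != int(results.nobs):
        raise ValueError("cluster ids must align with model rows")
    if groups.isna().any():
        raise ValueError("missing cluster id")
    robust = results.get_robustcov_results(
        "cluster", groups=groups.to_numpy(), use_correction=True,
        df_correction=True)
    return np.asarray(robust.cov_params())


def p_trend(data: pd.DataFrame, spec: ModelSpec) -> float:
    """Wald p of an ordinal 1/2/3 tertile term in the same adjusted model.

    Invariant to affine recoding of the ordinal scores.
    """
    if spec.exposure != "tertile":
        raise ValueError("trend test requires a tertile exposure")
    cols = spec.columns()
    sub = data[cols].dropna()
    res, _ = _fit(spec.formula(ordinal=True), sub,
                  sub[spec.cluster].to_numpy())
    return float(res.pvalues[spec.exposure_col])


def _table_grid(data: pd.DataFrame, analysis: str,
                cluster: str) -> pd.DataFrame:
    rows = []
    for outcome in OUTCOMES:
        for tier in TIERS:
            common = dict(outcome=outcome, tier=tier, analysis=analysis,
                          cluster=cluster)
            tert = fit_linear(data, ModelSpec(exposure="tertile", **common))
            cont = fit_linear(data, ModelSpec(exposure="continuous", **common))
            for _, r in tert.params.iterrows():
                rows.append({"outcome": outcome, "tier": tier,
                             "term": r["term"], "beta": r["beta"],
                             "ci_low": r["ci_low"], "ci_high": r["ci_high"],
                             "p": r["p"], "n": tert.n, "r2": tert.r2,
                             "p_trend": tert.p_trend})
            r = cont.params.iloc[0]
            rows.append({"outcome": outcome, "tier": tier,
                         "term": "continuous", "beta": r["beta"],
                         "ci_low": r["ci_low"], "ci_high": r["ci_high"],
                         "p": r["p"], "n": cont.n, "r2": cont.r2,
                         "p_trend": None})
    return pd.DataFrame(rows)


def run_table2(data: pd.DataFrame, cluster: str = "cluster_id") -> pd.DataFrame:
    """Cross-sectional grid: 8 baseline outcomes x 3 tiers x
    (T2, T3 vs T1 + continuous), with robust CIs, n, R2 x 100 and trend p.

    ``data`` is one row per participant carrying outcome, exposure
    (``di_baseline``, ``di_baseline_tertile``) and covariate columns.
    """
    return _table_grid(data, "cross_sectional", cluster)


def run_table3(data: pd.DataFrame, cluster: str = "cluster_id") -> pd.DataFrame:
    """Prospective grid: 1-year outcome changes on dietary-index change
    (tertiles of change and continuous), baseline-outcome-adjusted from
    model 1 and intervention-arm-adjusted in the full tier."""
    return _table_grid(data, "prospective", cluster)


def descriptive_table(data: pd.DataFrame, variables: dict[str, str],
                      tertile_col: str = "di_baseline_tertile") -> pd.DataFrame:
    """Baseline characteristics by dietary-index tertile.

    ``variables`` maps column name to one of ``"continuous"`` (mean +/- SD,
    one-way ANOVA p), ``"median"`` (median [P25-P75], ANOVA p; used for
    skewed lipid variables) or ``"categorical"`` (% (n) per level,
    chi-square p).
    """
    groups = [g for _, g in data.groupby(tertile_col, sort=True)]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("descriptive table needs >= 2 non-empty tertiles")
    rows = []
    for var, kind in variables.items():
        if kind in ("continuous", "median"):
            samples = [g[var].dropna().to_numpy() for g in groups]
            stat, p = scipy.stats.f_oneway(*samples)
            for tlab, s in zip(sorted(data[tertile_col].unique()), samples):
                if kind == "continuous":
                    cell = f"{np.mean(s):.3g} ± {np.std(s, ddof=1):.3g}"
                else:
                    q25, q50, q75 = np.percentile(s, [25, 50, 75])
                    cell = f"{q50:.3g} [{q25:.3g}–{q75:.3g}]"
                rows.append({"variable": var, "level": "", "tertile": tlab,
                             "summary": cell, "p": p})
        elif kind == "categorical":
            counts = pd.crosstab(data[var], data[tertile_col])
            _, p, _, _ = scipy.stats.chi2_contingency(counts)
            for level in counts.index:
                for tlab in counts.columns:
                    n = counts.loc[level, tlab]
                    pct = 100.0 * n / counts[tlab].sum()
                    rows.append({"variable": var, "level": str(level),
                                 "tertile": tlab,
                                 "summary": f"{pct:.1f} ({n})", "p": p})
        else:
            raise ValueError(f"unknown variable kind {kind!r} for {var!r}")
    return pd.DataFrame(rows)
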