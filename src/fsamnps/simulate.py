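"""Synthetic cohort generator with planted effects.

Emulates a PREDIMED-Plus-like study: a 143-item food-composition table, a
nine-category semi-quantitative FFQ administered at baseline and after one
year, covariates for participants aged 55-75 with overweight/obesity and
metabolic-syndrome-range biomarkers, recruitment-site cluster structure, and
the eight CVD risk-factor outcomes generated from a linear-Gaussian model
with additive cluster random effects::

    y_b  = a + beta_b * (DI_b - 8) + g_age (age - 65) + g_male * male + u_c + e
    y_1  = y_b + beta_d * (DI_1 - DI_b) + d_arm * arm + u'_c + e'

where the dietary index DI is computed from the generated FFQ through the
actual scoring/intake pipeline, so the planted coefficients are recoverable
by the regression grid when it is run end to end.  The linear-Gaussian form
with cluster effects is the weakest structure under which OLS with
cluster-robust variance is correctly specified.

Participants differ through a latent diet-quality trait that tilts their
item-choice probabilities toward high- or low-scored foods, which gives the
index realistic between-person spread; the trait enters outcomes only
through the index, so the planted effects are the causal ones.  Configured
fractions of records are injected with implausible energy intakes or a
missing year-1 FFQ so the exclusion screens have real work to do.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.stats

from . import ffq
from .dietary_index import compute_di_table
from .outcomes import OUTCOMES
from .pipeline import build_analysis_table
from .profiling import KCAL_TO_KJ, score_table

__all__ = ["SimConfig", "generate_composition", "generate_cohort",
           "recovery_experiment", "SyntheticCohort"]

#: planted continuous effect of baseline DI on each baseline outcome
DEFAULT_BETA_BASELINE = {
    "glucose": 0.11, "hdl": -0.21, "tg": 0.36, "ldl": 0.35,
    "dbp": -0.11, "sbp": 0.10, "bmi": 0.08, "waist": 0.22,
}
#: planted effect of 1-year DI change on each outcome change
DEFAULT_BETA_CHANGE = {
    "glucose": 0.35, "hdl": -0.02, "tg": 1.75, "ldl": -0.34,
    "dbp": 0.15, "sbp": 0.17, "bmi": 0.11, "waist": 0.28,
}
#: residual SD of each baseline outcome (cohort-scale dispersions)
DEFAULT_RESID_SD = {
    "glucose": 29.0, "hdl": 11.0, "tg": 40.0, "ldl": 33.0,
    "dbp": 10.0, "sbp": 17.0, "bmi": 3.4, "waist": 9.0,
}
#: residual SD of the 1-year change innovations
DEFAULT_CHANGE_SD = {
    "glucose": 15.0, "hdl": 6.0, "tg": 30.0, "ldl": 18.0,
    "dbp": 7.0, "sbp": 10.0, "bmi": 1.0, "waist": 3.0,
}
_INTERCEPT = {
    "glucose": 113.0, "hdl": 47.0, "tg": 140.0, "ldl": 117.0,
    "dbp": 81.0, "sbp": 139.0, "bmi": 32.4, "waist": 107.0,
}
_AGE_EFFECT = {
    "glucose": 0.3, "hdl": 0.1, "tg": -0.5, "ldl": 0.2,
    "dbp": -0.1, "sbp": 0.5, "bmi": -0.02, "waist": 0.05,
}
_MALE_EFFECT = {
    "glucose": 4.0, "hdl": -6.0, "tg": 10.0, "ldl": -2.0,
    "dbp": 1.5, "sbp": 3.0, "bmi": -0.3, "waist": 7.0,
}
_ARM_CHANGE_EFFECT = {
    "glucose": -1.0, "hdl": 0.5, "tg": -4.0, "ldl": -1.0,
    "dbp": -0.5, "sbp": -1.0, "bmi": -0.4, "waist": -1.0,
}
_DI_CENTER = 8.0  # centre of the index scale in the emulated cohort


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic study; the defaults are the study conditions."""

    n_participants: int = 1000
    n_items: int = 143
    n_clusters: int = 50
    seed: int = 0
    beta_baseline: dict = field(default_factory=lambda: dict(DEFAULT_BETA_BASELINE))
    beta_change: dict = field(default_factory=lambda: dict(DEFAULT_BETA_CHANGE))
    resid_sd: dict = field(default_factory=lambda: dict(DEFAULT_RESID_SD))
    change_sd: dict = field(default_factory=lambda: dict(DEFAULT_CHANGE_SD))
    cluster_sd_frac: float = 0.3      # cluster RE sd as fraction of resid sd
    covariate_effects: bool = True    # age/sex/arm effects on outcomes
    bp_reading_sd: float = 3.0        # per-reading measurement noise, mmHg
    diet_trait_strength: float = 0.2  # tilt of item choice by diet quality
    diet_trait_persistence: float = 0.6  # 1-year correlation of the trait
    freq_persistence: float = 0.7     # P(keep baseline frequency at year 1)
    missing_ffq_rate: float = 0.10    # participants losing the year-1 FFQ
    implausible_energy_rate: float = 0.04
    missing_bmi_rate: float = 0.002   # missing year-1 weight
    missing_dbp_rate: float = 0.001   # missing year-1 diastolic readings
    category_mix: dict = field(default_factory=lambda: {
        "general": 0.72, "beverage": 0.14, "cheese": 0.07, "added_fat": 0.07})

    def __post_init__(self) -> None:
        for name in ("beta_baseline", "beta_change", "resid_sd", "change_sd"):
            unknown = set(getattr(self, name)) - set(OUTCOMES)
            if unknown:
                raise ValueError(f"{name} refers to unknown outcomes "
                                 f"{sorted(unknown)}")
        for rate in (self.missing_ffq_rate, self.implausible_energy_rate,
                     self.missing_bmi_rate, self.missing_dbp_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if any(sd < 0 for sd in {**self.resid_sd, **self.change_sd}.values()):
            raise ValueError("residual SDs must be >= 0")
        if self.n_items < 10:
            raise ValueError("need at least 10 FFQ items")


@dataclass
class SyntheticCohort:
    """Generated study data plus the ground truth used to create it."""

    composition: pd.DataFrame
    participants: pd.DataFrame
    responses: pd.DataFrame
    measurements: pd.DataFrame
    truth: pd.DataFrame       # per-participant DI values used in generation
    config: SimConfig


def generate_composition(config: SimConfig) -> pd.DataFrame:
    """Per-100 g/ml composition of the FFQ item list.

    Nutrients are drawn from per-category log-normal distributions spanning
    all scoring bands; the fruit/vegetable/legume percentage is a mixture
    with a point mass at zero.  Two items are placed constructively at the
    score extremes (40 and -15) so the full scale is exercised, and two
    olive-oil items (virgin, refined) anchor the sensitivity analysis.
    Deterministic under the config seed.
    """
    rng = np.random.default_rng([config.seed, 1])
    m = config.n_items
    cats = []
    for cat, frac in config.category_mix.items():
        cats += [cat] * int(round(frac * m))
    cats = (cats + ["general"] * m)[:m]
    rows = []
    for i in range(m):
        cat = cats[i]
        item = {"item_id": f"item{i:03d}", "name": f"food {i}",
                "category": cat}
        if cat == "general":
            item.update(
                energy_kj=float(np.clip(rng.lognormal(np.log(800), 0.9), 20, 3900)),
                sugars_g=float(np.clip(rng.lognormal(np.log(5), 1.0), 0, 80)),
                satfat_g=float(np.clip(rng.lognormal(np.log(1.5), 1.0), 0, 25)),
                sodium_mg=float(np.clip(rng.lognormal(np.log(150), 1.2), 0, 2000)),
                fiber_g=float(np.clip(rng.lognormal(np.log(1.5), 0.8), 0, 15)),
                protein_g=float(np.clip(rng.lognormal(np.log(6), 0.8), 0, 35)),
                fvln_pct=0.0 if rng.random() < 0.55
                else float(rng.uniform(10, 100)),
                portion_g=float(np.clip(rng.lognormal(np.log(80), 0.6), 5, 400)),
            )
            item["fat_g"] = item["satfat_g"] * float(rng.uniform(1.5, 4.0))
        elif cat == "beverage":
            energy = 0.0 if rng.random() < 0.25 else float(rng.uniform(5, 300))
            item.update(
                energy_kj=energy,
                sugars_g=float(energy / 17.0 * rng.uniform(0.3, 1.0)),
                satfat_g=0.0, fat_g=0.0,
                sodium_mg=float(rng.uniform(0, 50)),
                fiber_g=0.0,
                protein_g=float(rng.uniform(0, 3)),
                fvln_pct=0.0 if rng.random() < 0.5
                else float(rng.uniform(30, 100)),
                portion_g=float(rng.uniform(150, 330)),
            )
        elif cat == "cheese":
            satfat = float(rng.uniform(10, 22))
            item.update(
                energy_kj=float(rng.uniform(1200, 1800)),
                sugars_g=float(rng.uniform(0, 3)), satfat_g=satfat,
                fat_g=satfat * float(rng.uniform(1.3, 1.8)),
                sodium_mg=float(rng.uniform(400, 900)),
                fiber_g=0.0, protein_g=float(rng.uniform(18, 30)),
                fvln_pct=0.0,
                portion_g=float(rng.uniform(20, 60)),
            )
        else:  # added_fat
            fat = float(rng.uniform(80, 100))
            ratio = float(rng.uniform(0.08, 0.70))
            item.update(
                energy_kj=fat * 37.0, sugars_g=0.0,
                satfat_g=fat * ratio, fat_g=fat,
                sodium_mg=float(rng.uniform(0, 100)),
                fiber_g=0.0, protein_g=0.0, fvln_pct=0.0,
                portion_g=float(rng.uniform(5, 15)),
            )
        rows.append(item)
    df = pd.DataFrame(rows)

    # constructive extremes: one item at +40 and one at -15
    df.loc[0, ["category", "energy_kj", "sugars_g", "satfat_g", "fat_g",
               "sodium_mg", "fiber_g", "protein_g", "fvln_pct",
               "portion_g"]] = \
        ["general", 3900.0, 50.0, 12.0, 30.0, 1000.0, 0.0, 0.0, 0.0, 60.0]
    df.loc[0, "name"] = "confectionery, extreme"
    df.loc[1, ["category", "energy_kj", "sugars_g", "satfat_g", "fat_g",
               "sodium_mg", "fiber_g", "protein_g", "fvln_pct",
               "portion_g"]] = \
        ["general", 300.0, 1.0, 0.2, 0.8, 10.0, 8.0, 9.0, 100.0, 150.0]
    df.loc[1, "name"] = "legumes, extreme"

    # designated olive-oil items for the sensitivity analysis
    fat_idx = df.index[df["category"] == "added_fat"][:2]
    for idx, kind in zip(fat_idx, ("virgin", "refined")):
        df.loc[idx, "item_id"] = f"olive_oil_{kind}"
        df.loc[idx, "name"] = f"olive oil, {kind}"
        df.loc[idx, ["fat_g", "satfat_g", "fvln_pct"]] = [100.0, 14.0, 100.0]
        df.loc[idx, "energy_kj"] = 3700.0
        df.loc[idx, "portion_g"] = 10.0

    # item popularity (how often a typical participant reports it) is an
    # item attribute; portions are then calibrated so that a typical diet
    # lands near 2,400 kcal/day, the cohort-scale mean intake
    df["popularity_logit"] = rng.normal(-1.6, 0.5, size=m)
    servings = ffq.DEFAULT_FREQUENCY_MAP.as_array()
    p_bar = 1.0 / (1.0 + np.exp(-df["popularity_logit"].to_numpy()))
    exp_serv = np.zeros(m)
    for k in range(9):
        exp_serv += scipy.stats.binom.pmf(k, 8, p_bar) * servings[k]
    kcal_per_serv = (df["portion_g"].to_numpy() * df["energy_kj"].to_numpy()
                     / (100.0 * KCAL_TO_KJ))
    df["portion_g"] *= 2400.0 / float(exp_serv @ kcal_per_serv)
    return df


def _draw_frequencies(rng, popularity_logit: np.ndarray, trait: np.ndarray,
                      score_z: np.ndarray, strength: float) -> np.ndarray:
    """(n, m) frequency categories 1..9, tilted by the diet-quality trait."""
    logit = popularity_logit[None, :] + strength * trait[:, None] * score_z[None, :]
    p = 1.0 / (1.0 + np.exp(-logit))
    return 1 + rng.binomial(8, p)


def _repair_energy(freq: np.ndarray, kcal_per_serving: np.ndarray,
                   servings: np.ndarray, lo: float = 900.0,
                   hi: float = 3300.0) -> np.ndarray:
    """Nudge natural diets into a safe energy window.

    Greedily decrements the frequency category of the largest energy
    contributor (or increments the densest item) until every participant's
    total lies in ``[lo, hi]`` kcal/day, a window strictly inside both
    sexes' plausibility limits.  Keeps the generated population free of
    accidental screen violations so the injected ones are the only ones.
    """
    freq = freq.copy()
    for _ in range(200):
        contrib = servings[freq - 1] * kcal_per_serving[None, :]
        total = contrib.sum(axis=1)
        over = total > hi
        under = total < lo
        if not (over.any() or under.any()):
            break
        if over.any():
            masked = np.where(freq[over] > 1, contrib[over], -np.inf)
            worst = masked.argmax(axis=1)
            freq[np.flatnonzero(over), worst] -= 1
        if under.any():
            masked = np.where(freq[under] < 9, kcal_per_serving[None, :],
                              -np.inf)
            best = masked.argmax(axis=1)
            freq[np.flatnonzero(under), best] += 1
    return freq


def generate_cohort(config: SimConfig,
                    composition: pd.DataFrame | None = None) -> SyntheticCohort:
    """Generate participants, two-timepoint FFQ responses, and measurements.

    Outcomes carry the planted linear effects of the dietary index computed
    from the generated diet through the real scoring/intake pipeline.
    Byte-identical output under a fixed config.
    """
    if composition is None:
        composition = generate_composition(config)
    n, m = config.n_participants, len(composition)
    rng = np.random.default_rng([config.seed, 2])

    scores = score_table(composition).set_index("item_id")["total"]
    fs = composition["item_id"].map(scores).to_numpy(dtype=float)
    score_z = (fs - fs.mean()) / fs.std()
    if "popularity_logit" in composition.columns:
        popularity_logit = composition["popularity_logit"].to_numpy()
    else:  # composition from an external source: draw popularity here
        popularity_logit = rng.normal(-1.6, 0.5, size=m)

    trait_b = rng.normal(size=n)
    trait_1 = (config.diet_trait_persistence * trait_b
               + np.sqrt(1 - config.diet_trait_persistence**2)
               * rng.normal(size=n))
    freq_b = _draw_frequencies(rng, popularity_logit, trait_b, score_z,
                               config.diet_trait_strength)
    freq_1_new = _draw_frequencies(rng, popularity_logit, trait_1, score_z,
                                   config.diet_trait_strength)
    keep = rng.random((n, m)) < config.freq_persistence
    freq_1 = np.where(keep, freq_b, freq_1_new)

    servings = ffq.DEFAULT_FREQUENCY_MAP.as_array()
    kcal_per_serving = (composition["portion_g"].to_numpy()
                        * composition["energy_kj"].to_numpy()
                        / (100.0 * KCAL_TO_KJ))
    freq_b = _repair_energy(freq_b, kcal_per_serving, servings)
    freq_1 = _repair_energy(freq_1, kcal_per_serving, servings)

    pid = np.array([f"p{i:05d}" for i in range(n)])
    sex = np.where(rng.random(n) < 0.517, "male", "female")

    # inject implausible-energy and missing-FFQ violations
    u = rng.random(n)
    implausible = u < config.implausible_energy_rate
    missing_ffq = (u >= config.implausible_energy_rate) & \
        (u < config.implausible_energy_rate + config.missing_ffq_rate)
    low_energy = rng.random(n) < 0.5
    for i in np.flatnonzero(implausible):
        if low_energy[i]:
            freq_b[i, :] = 1
            freq_b[i, 0] = 2  # a token nibble; total energy far below limits
        else:
            freq_b[i, :] = 9  # everything many times a day

    def _long(freq: np.ndarray, timepoint: str) -> pd.DataFrame:
        return pd.DataFrame({
            "participant_id": np.repeat(pid, m),
            "timepoint": timepoint,
            "item_id": np.tile(composition["item_id"].to_numpy(), n),
            "frequency_category": freq.ravel(),
        })

    responses = pd.concat([_long(freq_b, "baseline"), _long(freq_1, "year1")],
                          ignore_index=True)
    responses = responses[~(responses["participant_id"].isin(pid[missing_ffq])
                            & (responses["timepoint"] == "year1"))]
    responses = responses.reset_index(drop=True)

    # dietary index through the real pipeline
    _, item_energy = ffq.intake_table(responses, composition, composition)
    di = compute_di_table(item_energy, scores)
    di_wide = di.pivot(index="participant_id", columns="timepoint", values="di")
    di_b = pd.Series(pid).map(di_wide["baseline"]).to_numpy()
    di_1 = pd.Series(pid).map(
        di_wide["year1"] if "year1" in di_wide.columns
        else pd.Series(dtype=float)).to_numpy()
    d_di = np.where(np.isnan(di_1), 0.0, di_1 - di_b)

    # covariates
    cluster_id = rng.integers(config.n_clusters, size=n)
    age = rng.uniform(55, 75, size=n)
    male = (sex == "male").astype(float)
    education = rng.choice(["primary", "secondary", "university"], size=n,
                           p=[0.50, 0.29, 0.21])
    smoking = rng.choice(["never", "current", "former"], size=n,
                         p=[0.45, 0.12, 0.43])
    marital = rng.choice(["married", "widowed", "single", "religious"], size=n,
                         p=[0.77, 0.10, 0.12, 0.01])
    pa = np.clip(rng.lognormal(np.log(2000), 0.8, size=n), 0, 15000)
    med_lipid = (rng.random(n) < 0.45).astype(int)
    med_htn = (rng.random(n) < 0.55).astype(int)
    med_diabetes = (rng.random(n) < 0.25).astype(int)
    arm = rng.choice(["control", "intervention"], size=n)
    center_levels = np.array(["<250", "250-<300", "300-<400", ">=400"])
    center_of_cluster = rng.choice(center_levels, size=config.n_clusters)
    center_size = center_of_cluster[cluster_id]

    participants = pd.DataFrame({
        "participant_id": pid, "cluster_id": cluster_id, "sex": sex,
        "age": age, "education": education, "smoking": smoking,
        "marital": marital, "pa_met_min_week": pa, "med_lipid": med_lipid,
        "med_htn": med_htn, "med_diabetes": med_diabetes, "arm": arm,
        "center_size": center_size,
    })

    # outcomes: linear predictor + cluster RE + Gaussian noise
    cov_on = 1.0 if config.covariate_effects else 0.0
    arm_ind = (arm == "intervention").astype(float)
    y_b, y_1 = {}, {}
    for oc in OUTCOMES:
        sd = config.resid_sd.get(oc, 0.0)
        csd = config.cluster_sd_frac * sd
        u_c = rng.normal(0, 1, size=config.n_clusters) * csd
        lp = (_INTERCEPT[oc]
              + config.beta_baseline.get(oc, 0.0) * (di_b - _DI_CENTER)
              + cov_on * _AGE_EFFECT[oc] * (age - 65.0)
              + cov_on * _MALE_EFFECT[oc] * male)
        y_b[oc] = lp + u_c[cluster_id] + rng.normal(0, 1, size=n) * sd
        dsd = config.change_sd.get(oc, 0.0)
        u_c1 = rng.normal(0, 1, size=config.n_clusters) * \
            (config.cluster_sd_frac * dsd)
        y_1[oc] = (y_b[oc]
                   + config.beta_change.get(oc, 0.0) * d_di
                   + cov_on * _ARM_CHANGE_EFFECT[oc] * arm_ind
                   + u_c1[cluster_id] + rng.normal(0, 1, size=n) * dsd)

    # keep lipid panel internally consistent: tc = ldl + hdl + tg/5, with
    # a direct LDL supplied when triglycerides reach the Friedewald limit
    for y in (y_b, y_1):
        y["tg"] = np.clip(y["tg"], 1.0, None)
        y["hdl"] = np.clip(y["hdl"], 5.0, None)

    height = np.clip(rng.normal(1.66 - 0.10 * (1 - male), 0.07), 1.40, 2.05)

    def _measurements(y: dict, timepoint: str,
                      miss_bmi: np.ndarray, miss_dbp: np.ndarray
                      ) -> pd.DataFrame:
        weight = y["bmi"] * height**2
        weight = np.where(miss_bmi, np.nan, weight)
        read = rng.normal(0, config.bp_reading_sd, size=(n, 6))
        sbp = y["sbp"][:, None] + read[:, :3]
        dbp = y["dbp"][:, None] + read[:, 3:]
        dbp = np.where(miss_dbp[:, None], np.nan, dbp)
        tc = y["ldl"] + y["hdl"] + y["tg"] / 5.0
        direct = np.where(y["tg"] >= 300.0, y["ldl"], np.nan)
        return pd.DataFrame({
            "participant_id": pid, "timepoint": timepoint,
            "weight_kg": weight, "height_m": height, "waist_cm": y["waist"],
            "sbp1": sbp[:, 0], "sbp2": sbp[:, 1], "sbp3": sbp[:, 2],
            "dbp1": dbp[:, 0], "dbp2": dbp[:, 1], "dbp3": dbp[:, 2],
            "glucose": y["glucose"], "tc": tc, "hdl": y["hdl"],
            "tg": y["tg"], "ldl_direct": direct,
        })

    never = np.zeros(n, dtype=bool)
    miss_bmi = rng.random(n) < config.missing_bmi_rate
    miss_dbp = rng.random(n) < config.missing_dbp_rate
    measurements = pd.concat(
        [_measurements(y_b, "baseline", never, never),
         _measurements(y_1, "year1", miss_bmi, miss_dbp)],
        ignore_index=True)

    truth = pd.DataFrame({
        "participant_id": pid, "di_baseline": di_b, "di_year1": di_1,
        "di_change": np.where(np.isnan(di_1), np.nan, d_di),
        "implausible_energy": implausible, "missing_ffq": missing_ffq,
    })
    return SyntheticCohort(composition=composition, participants=participants,
                           responses=responses, measurements=measurements,
                           truth=truth, config=config)


def recovery_experiment(config: SimConfig, n_reps: int,
                        analysis: str = "cross_sectional",
                        tier: str = "model1") -> pd.DataFrame:
    """Monte-Carlo parameter recovery through the full pipeline.

    Per replicate: generate a cohort, run score -> intake -> exclusions ->
    dietary index -> outcomes, and fit the continuous-exposure regression
    for every outcome; summarise bias, RMSE, empirical SE, mean model SE and
    95% CI coverage of the planted effect.  Replicate seeds are derived from
    ``config.seed``.

    Returns one row per outcome with columns ``beta_true, mean_beta, bias,
    mcse, rmse, coverage, n_mean``.
    """
    from .association import ModelSpec, fit_linear

    if n_reps < 2:
        raise ValueError("need at least 2 replicates")
    composition = generate_composition(config)
    truth = (config.beta_baseline if analysis == "cross_sectional"
             else config.beta_change)
    est: dict[str, list] = {oc: [] for oc in OUTCOMES}
    cover: dict[str, list] = {oc: [] for oc in OUTCOMES}
    ns: list[int] = []
    for rep in range(n_reps):
        rep_config = replace(config, seed=(config.seed + 1000003 * (rep + 1))
                             % 2**31)
        cohort = generate_cohort(rep_config, composition)
        table, _ = build_analysis_table(
            composition, cohort.responses, cohort.participants,
            cohort.measurements)
        ns.append(len(table))
        for oc in OUTCOMES:
            spec = ModelSpec(outcome=oc, exposure="continuous", tier=tier,
                             analysis=analysis)
            res = fit_linear(table, spec)
            row = res.params.iloc[0]
            est[oc].append(row["beta"])
            b = truth.get(oc, 0.0)
            cover[oc].append(row["ci_low"] <= b <= row["ci_high"])
    rows = []
    for oc in OUTCOMES:
        b = np.asarray(est[oc])
        bt = truth.get(oc, 0.0)
        rows.append({
            "outcome": oc, "beta_true": bt, "mean_beta": b.mean(),
            "bias": b.mean() - bt,
            "mcse": b.std(ddof=1) / np.sqrt(n_reps),
            "empirical_se": b.std(ddof=1),
            "rmse": float(np.sqrt(np.mean((b - bt) ** 2))),
            "coverage": float(np.mean(cover[oc])),
            "n_mean": float(np.mean(ns)),
        })
    return pd.DataFrame(rows)
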