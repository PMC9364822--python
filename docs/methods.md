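# Methods

## The food-level score

`fsamnps` scores each food or beverage on the modified Food Standards
Agency Nutrient Profiling System (FSAm-NPS), the algorithm underlying the
Nutri-Score front-of-pack label. Per 100 g (solids) or 100 ml (drinks), up
to 40 "A" points are assigned for nutrients to limit — energy (kJ), total
sugars (g), saturated fat (g) and sodium (mg), 0–10 points each — and up to
15 "C" points for components to encourage — dietary fiber (g), protein (g),
and the percentage of fruits, vegetables, legumes, nuts and
rapeseed/walnut/olive oils (FVLN), 0–5 points each. The total is

    FSAm-NPS = A − C,

a discrete scale from −15 (healthiest) to 40 (least healthy) for general
foods.

The point grids are shipped as a versioned YAML file
(`src/fsamnps/data/bands_hcsp2015.yaml`, the 2015 French HCSP vintage) so
they are auditable and swappable. Each component is a step function over
`(threshold, points)` pairs. **Threshold semantics are strictly greater
than**: content exactly at a threshold does not earn the point. This is the
convention of the published grids; it matters for boundary foods (e.g.
saturated fat of exactly 5 g/100 g earns 4 points, not 5) and is asserted
by the tests.

Category exceptions (the HCSP modifications):

* **cheese** — protein points always count;
* **added fats** — saturated fat is scored as 100·satfat/total fat on a
  dedicated ratio grid (an added fat declaring zero total fat scores 0 on
  that component, with a warning);
* **beverages** — steeper energy/sugar grids and an FVLN component worth up
  to 10 points.

Protein-cap rule: a non-cheese food with A ≥ 11 whose FVLN points are below
the category maximum does not count its protein points.

The olive-oil sensitivity analysis reassigns designated olive-oil items a
total of −8 (the score of fruits, vegetables or legumes). The reassigned
total intentionally breaks the `total = A − C` identity; such scores carry
an `override` flag.

## From FFQ to intake

The FFQ model is a 143-item semi-quantitative instrument with nine
frequency categories ("never or almost never" … "more than six times a
day") and a standard portion per item. The instrument defines only the
endpoint labels; interior categories use Willett-style midpoints
(servings/day): 0, 2/30, 1/7, 3/7, 5.5/7, 1, 2.5, 5, 7. The map is a config
object and can be overridden.

Daily intake of a nutrient is Σ_items servings/day × portion × (content per
100 g)/100; energy is reported in kcal/day (grids are kJ-denominated;
loaders convert kcal → kJ by 4.184 and salt g → sodium mg by ×400).

Exclusion screens mirror the cohort analysis plan: participants lacking an
FFQ at either timepoint, or with total energy strictly outside sex-specific
limits (women 500–3,500, men 800–4,000 kcal/day) at either timepoint, are
removed with a one-reason-per-participant log. Values exactly at a limit
are retained (strict-inequality reading). The screen is applied at both
timepoints — the conservative reading, configurable via the `timepoints`
argument.

## The dietary index

The individual-level index is the energy-weighted mean of the scores of all
consumed items,

    DI = Σ_i FS_i·E_i / Σ_i E_i,

with E_i the mean daily energy from item i. Higher DI = poorer overall
dietary quality. Consequences asserted by property tests: DI is a convex
combination of consumed items' scores; it is invariant to the energy unit;
zero-energy items (water, diet drinks) are scored but cannot influence it —
a known structural limitation of the index. A participant with zero total
energy has no defined index and is flagged, not dropped silently.

Tertiles are rank-based thirds (T1 = best quality). Group sizes differ by
at most one, the remainder going to the lower tertiles (5,921 distinct
values split 1,974/1,974/1,973); ties spanning a cut point all take the
lower label, with stable input order otherwise — a deterministic rule so
regressions are exactly reproducible.

One-year change is `year1 − baseline`: positive change = score increase =
quality decrease. The opposite orientation is available as a switch.

## Outcomes

Eight CVD risk factors: BMI (weight/height²), waist circumference, fasting
glucose, triglycerides, HDL- and LDL-cholesterol, systolic and diastolic
blood pressure. BP is the mean of up to three oscillometer readings;
partial sets use the mean of available readings (maximises usable records;
logged). LDL uses the Friedewald formula tc − hdl − tg/5 below 300 mg/dL
triglycerides and the direct measurement above (missing, with a warning, if
no direct value exists). Friedewald LDL satisfies tc = ldl + hdl + tg/5
exactly wherever applied.

Imputation is deliberately narrow: only follow-up BMI and diastolic BP are
mean-imputed (the two variables the analysis plan imputes); everything else
is complete-case with per-model n reported. Units are fixed (mg/dL, mmHg,
kg, m, cm).

## Regression grids

For each outcome the association with the index is estimated by OLS under
three adjustment tiers:

* **crude** — exposure only;
* **model 1** — age (years), sex, BMI, education (primary/secondary/
  university), smoking (never/current/former), total baseline energy
  (kcal/day), physical activity (MET·min/week), marital status
  (married/widowed/single/religious);
* **fully adjusted** — model 1 + lipid/hypertension/diabetes medication and
  recruitment-centre size class (<250, 250–<300, 300–<400, ≥400).

BMI is removed from the covariates when BMI or waist is the outcome. The
prospective grid regresses 1-year outcome changes on index change, adds the
outcome's baseline level from model 1 up, and intervention arm in the full
tier only (the cross-sectional full tier omits arm, following the
table-footnote reading of the analysis plan). Reference levels are
explicit: female, primary education, never-smoker, married, control arm.

Exposure codings: tertile indicators with T1 reference, and continuous. The
trend test replaces the indicators with an ordinal 1/2/3 term in the same
model and reports its robust Wald p (affine-invariant in the coding).

All variances are cluster-robust sandwich estimates with the Stata-style
small-sample factor (G/(G−1))·((N−1)/(N−k)); the cluster unit is
configurable (default: recruitment-site id — the correlation unit is a
design choice, not dictated by the data schema). With every cluster a
singleton the estimator reduces to the HC1-type form up to that factor;
below two clusters the fit falls back to HC1 with a warning. Confidence
intervals use the normal 1.96 multiplier (t-based multipliers can be passed
via `ci_mult`); R² is reported ×100, matching the epidemiological table
convention. No multiple-testing correction is applied, matching the
analysis plan (p < 0.05). Rank-deficient designs raise an error naming the
collinear columns (QR with column pivoting).

Descriptive tables report mean ± SD or median [P25–P75] per tertile for
continuous variables (the median form for skewed lipids), % (n) for
categorical, with one-way ANOVA / chi-square p-values.

## Synthetic cohort

The generator emulates the study conditions end to end so the whole
pipeline and the parameter-recovery suite run without any data download.

*Food supply.* 143 items with category mix ≈ 72% general, 14% beverage, 7%
cheese, 7% added fat. Nutrients are log-normal per category (parameters in
`simulate.py`), FVLN is a mixture with a point mass at 0. Two items are
placed constructively at the score extremes (+40 and −15) so the full scale
is exercised; two designated olive-oil items (virgin/refined; 100% fat,
satfat ratio 14%, FVLN 100%) anchor the sensitivity analysis. Item
popularity is an item attribute; portions are calibrated so a typical diet
lands near 2,400 kcal/day, the cohort-scale mean intake.

*Diet.* Each participant has a latent diet-quality trait that tilts item
choice toward high- or low-scored foods (binomial frequency categories on a
logit scale), persisting imperfectly across the year (trait correlation
0.6; 70% of item frequencies carried over). This produces realistic
between-person index spread and non-degenerate 1-year change. Natural
diets are then deterministically nudged into a 900–3,300 kcal/day window by
decrementing/incrementing the largest energy contributors — the adjustment
depends only on the diet, happens before outcomes are generated, and keeps
the generated population free of accidental screen violations, so the
exclusion stage removes exactly the injected ones.

*Violations.* Configured fractions of participants get an implausible
energy record (4%: everything-at-maximum or almost-nothing diets) or lose
the year-1 FFQ (10%) — together ≈ 14% exclusions, the cohort-scale
attrition. Small fractions lose year-1 weight (0.2%) or diastolic readings
(0.1%) to exercise the imputation path.

*Outcomes.* Linear-Gaussian with additive cluster random effects — the
weakest structure under which OLS + cluster-robust variance is correctly
specified:

    y_b = α + β_b·(DI_b − 8) + γ_age(age − 65) + γ_male·male + u_c + ε
    y_1 = y_b + β_Δ·(DI_1 − DI_b) + δ_arm·arm + u'_c + ε′

DI is computed from the generated FFQ through the real scoring/intake
pipeline, so the planted coefficients are recoverable only if every stage
is correct. Default planted effects echo the published fully-adjusted
continuous coefficients (e.g. glucose change 0.35 mg/dL per index point);
residual SDs approximate the cohort-scale dispersions (glucose 29, BMI 3.4,
SBP 17 …); cluster SD is 0.3× the residual SD; covariates are drawn
independently of diet, so the planted effects are causal. The lipid panel
is kept internally consistent (tc = ldl + hdl + tg/5, direct LDL supplied
when tg ≥ 300; tg floored at 1 mg/dL — a physiological floor hit with
negligible probability at the default SDs). Blood-pressure readings add
per-reading noise (SD 3 mmHg), so the measured outcome is the latent value
plus mean-zero error — unbiased for the planted slope.

What the generator does **not** emulate: the real joint covariate
distribution, diet–covariate confounding, non-linear dose–response,
informative missingness, or measurement error correlated with outcomes.
Passing recovery tests therefore demonstrate internal validity of the
pipeline under a correctly specified linear model, not robustness to the
biases of real cohort data.

*Determinism.* One global seed; per-stage substreams; identical output
under identical config.

## Validation problem sizes

The Monte-Carlo recovery suite uses 1,000 participants, 50 clusters and 500
replicates per condition (cross-sectional, model-1 tier), reporting bias
against Monte-Carlo SE and 95% CI coverage per outcome; property suites use
10⁴ random baskets and 100–300 generated cases per invariant. These sizes
give Monte-Carlo error around 1% on coverage, small enough to distinguish
nominal from broken calibration.

## Known limitations

* Band boundary conventions differ between published restatements of the
  grids; this implementation is strictly-greater-than throughout and should
  not be mixed with ≥-convention tables.
* The theoretical bounds −15/40 are asserted for general foods; beverage
  grids (FVLN up to 10) allow lower totals, and no bound is claimed there.
* The score's A − C orientation follows the stated −15..40 range; sources
  describing the subtraction in the opposite order are reconciled by that
  range.
* Mean imputation understates outcome variance; it is used only where the
  emulated analysis plan used it (follow-up BMI and diastolic BP).
* The energy-weighting of the index ignores zero-energy items entirely.
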