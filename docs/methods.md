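# Methods

`metaga` implements postnatal gestational-age (GA) estimation from newborn
dried-blood-spot screening data, end to end: cohort simulation, data
preparation, model fitting and validation. The real newborn-screening
databases this kind of analysis runs on are governed by data-sharing
agreements, so the package ships a first-class synthetic-cohort generator
whose statistical structure mirrors what the analysis assumes; every claim
the test suite makes is a claim about that generative structure, not about
any real population.

## The estimation problem

Each record is one infant: sex, birth weight (g), age at blood-spot
collection (hours), a screen-positive flag, reference GA in decimal weeks
(dating-ultrasound standard), and a panel of analyte concentrations
(hemoglobin fractions, TSH, 17-OHP, amino acids, acylcarnitines, enzyme and
CF markers). The task is to regress reference GA on sex, birth weight and
the analytes, and to quantify how well the fitted equations transport to
external sites with different populations, laboratories and panels.

Three model families are fitted:

1. **Model 1** — sex, birth weight (restricted cubic spline) and their
   interaction; ordinary least squares, no selection or shrinkage.
2. **Model 2** — sex plus all panel analytes and pairwise interactions;
   elastic net.
3. **Model 3** — Model 2 plus birth weight; elastic net.

## Synthetic cohorts (`synthetic_cohort`)

* **GA mixture.** GA is a two-component mixture: an exponential tail below
  37 weeks (scale 2.1 weeks, truncated at `ga_min`) drawn with probability
  `preterm_target_fraction`, and a Gaussian term component truncated to
  [37, `ga_max`]. The term component's location and spread are solved
  numerically (nested Brent root finds on the truncated-normal moments) so
  the mixture's overall mean and SD equal `ga_mean`/`ga_sd` exactly. Because
  the two components sit strictly on either side of 37 weeks, the preterm
  count is exactly Binomial(n, p) — which is what the tests assert. The
  defaults (mean 39.3, SD 1.6 weeks, 5.6% preterm) match a large North
  American screening population; external-site configurations use
  lower means and preterm fractions typical of the screened subpopulations
  in East/South-East Asian programs.
* **Reference-GA noise.** A latent GA drives the biology; the *reported*
  reference GA adds Gaussian noise `ga_observation_noise_sd` (dating error,
  e.g. postnatal scoring in place of early ultrasound). The default is 0 so
  that distributional contracts of the generator are exact; the accuracy
  study uses 0.6 weeks, which makes the best achievable test MAE equal to
  sigma*sqrt(2/pi) ~ 0.479 weeks and puts all reported errors on the scale
  seen in real validations (~0.5–1 week).
* **Birth weight.** Expected weight is quadratic in (GA - 40) with a male
  offset (defaults: 3460 g intercept, 170 g/week, -5 g/week^2, +120 g for
  males), multiplied by a log-normal factor (SD 0.115) plus small additive
  noise. A `growth_restricted_fraction` of infants (default 3.5%; 10% in the
  growth-restriction study) has weight multiplied by
  `growth_restriction_deficit` (default 0.75), decoupling weight from GA for
  that stratum.
* **Analytes.** Each non-hemoglobin analyte is log-normal with log-level
  linear in GA. Six analytes (17-OHP, C4DC, TYR, ALA, C5, C5DC) are
  informative with |slope|/residual-SD ~ 1.7 per week; the rest are null
  (zero slope). Jointly with the hemoglobin ratio and birth weight the
  informative panel carries a combined information SD of ~0.22 weeks about
  latent GA — chosen once, analytically, so that analyte models clearly beat
  sex + birth weight while the reference-noise floor still dominates, the
  qualitative regime reported for real cohorts.
* **Hemoglobins.** The fetal fraction f is logit-linear in GA
  (logit f = 1.2 - 0.30*(GA - 40) + noise); total hemoglobin is log-normal;
  HbF/HbF1 split the fetal mass 90/10 and HbA takes the rest, so the derived
  ratio (HbF + HbF1)/(HbF + HbF1 + HbA) equals f and declines with maturity.
* **Artifacts of real screening.** Screen positives (default 0.8%) get
  several analytes spiked by e^4; sporadic outliers (0.2%) get one analyte
  spiked by e^2.5 (these exercise exclusion and winsorization). Collection
  age is log-normal (median 28 h) with an additive preterm delay, so
  late-collection exclusion removes preterm infants disproportionately — the
  mechanism behind artificially low external preterm prevalence.
* **Site shifts.** A `SiteShift` drops analytes outside the site's panel,
  applies multiplicative bias and additive log shifts, inflates residual
  dispersion by rescaling residuals around a per-analyte linear fit of
  log-concentration on GA (signal-preserving, noise-inflating), delays
  collection, and optionally floors reference GA to completed weeks. Shift
  magnitudes are free parameters: real inter-laboratory shifts are not
  quantified anywhere, so the defaults (dispersion 1.3–1.4 on the
  informative analytes, biases of 20–30%) are chosen to produce a visible
  but not catastrophic transportability loss.

What the generator does **not** emulate: assay chemistry, true concentration
reference ranges, analyte–analyte correlation beyond the shared GA factor,
collection-age effects on analyte levels, and non-Gaussian dating-error
structure. Passing tests therefore demonstrate correctness of the pipeline
and the qualitative phenomena built into the generator — not quantitative
performance on real screening data.

## Data preparation (`preprocess`)

Order is fixed: exclusions → derived hemoglobin ratio → Tukey-fence
winsorization on the raw scale → natural log (analytes only) → pareto
scaling.

* **Exclusions.** Collection later than 48 h (72 h for external cohorts),
  screen positives, then records missing sex, birth weight, GA or any panel
  analyte; each removal is attributed to the first matching rule so the
  counts partition the removed set.
* **Winsorization.** Fences at Q1 - 3*IQR and Q3 + 3*IQR. Quartiles use
  linear interpolation between order statistics (type 7); the choice is a
  convention fixed here because different quantile rules move fences by
  O(1/n).
* **Log and zeros.** Analytes are strongly right-skewed, hence natural log.
  A zero reading is replaced by half the smallest positive observed value of
  that analyte (recorded in the fitted parameters for reuse).
* **Pareto scaling.** x -> (x - mean)/sqrt(sd), with the n-1 sample SD.
  Birth weight is pareto-scaled without the log (the preparation narrative
  applies the log to measured analytes only; treated as analytes-only here
  and flagged as an interpretation choice). After scaling, a column has mean
  0 and variance equal to the pre-scaling SD — both asserted in tests.
* **Local standardization.** Fences and scaling constants are refitted per
  cohort by default, which is what makes models transportable across sites
  with level/scale batch effects; a config switch (`scaling: training`)
  reuses the training-cohort constants for sensitivity analysis.
* **Subgroups.** Preterm is GA < 37.0 (strict). SGA10/SGA3/LGA compare birth
  weight against the 10th/3rd/90th empirical centile within (completed GA
  week x sex) strata of a designated reference cohort — the training cohort
  by default, applied uniformly to all sites. Published growth-standard
  centile tables are licensed and out of scope; empirical centiles from a
  fixed reference cohort play the same role. Strata thinner than 30 records
  are not classified (counted as unclassifiable).

## Design and screening (`design`)

* **Split.** 50/25/25 development/validation/test by stratified random
  sampling within (completed week x sex) strata, largest-remainder
  allocation; strata smaller than 3 go to a global lottery.
* **Screening.** "Generalized partial Spearman correlation": all variables
  are rank-transformed and the partial correlation of GA with each candidate
  given all other candidates plus sex and birth weight is read off the
  precision matrix of the ranks (equivalent to correlating least-squares
  rank residuals, computed with one matrix inverse). This is an
  approximation to the fully general rank metric but detects non-linear
  monotone-component associations and is invariant to monotone transforms.
  The raw hemoglobin fractions are excluded from the candidate set (and from
  model predictors): the derived fetal:adult ratio represents them, and
  keeping both makes the mutual-adjustment set nearly collinear.
* **Splines.** Restricted cubic splines, k knots -> k-1 basis columns
  (identity plus truncated-power terms, linear beyond the boundary knots;
  nonlinear terms divided by the squared knot range for numerical scale).
  Knots at the 5/27.5/50/72.5/95th percentiles of the training distribution.
  Ties collapse knots with a warning and reduce the basis order. The top 7
  screened analytes are splined (6 when the hemoglobin ratio is unavailable,
  since the ratio is always among the top when present), plus birth weight
  in Models 1 and 3.
* **Interactions.** "Pairwise interactions among predictors" is ambiguous;
  the policy here is: products of every pair of scalar (pre-spline)
  standardized numeric predictors, plus sex x every spline basis column and
  sex x every non-splined numeric scalar. Spline-x-spline tensor products
  are excluded to cap dimensionality; the elastic net prunes the retained
  set. The policy is a declarative field of the model spec (`"none"`
  switches interactions off for sensitivity work).

## Fitting (`models`)

Model 1 is OLS (minimum-norm least squares with a warning if the design is
rank-deficient). Models 2–3 minimize

    (1/2) mean((y - Xb)^2) + lambda * [ t*||b||_1 + (1-t)/2 * ||b||_2^2 ]

with unpenalized intercept, via scikit-learn's coordinate descent
(`alpha = lambda`, `l1_ratio = t`); `lambda = 0` falls back to least
squares. Hyperparameters are chosen on the internal-validation sub-cohort by
MSE over a grid — by default t in {0.1, 0.5, 0.9} crossed with a 50-point
log-spaced penalty path from the all-zero penalty downward three decades;
ties prefer the larger penalty. Fits are warm-started along each descending
path and share one precomputed Gram matrix (data are centered once, the
intercept recovered in closed form). The heavy experiments in the test suite
and acceptance script use a reduced grid (t = 0.5, 12 penalties), which the
validation curves show is flat around the optimum at these sample sizes.

Panel-restricted variants for external sites drop unavailable analytes,
their splines and (by construction of the design) every interaction naming
them, then retrain from scratch on the training sub-cohort.

GA estimates are never clipped; for completed-weeks cohorts, estimates and
reference are floored before comparison.

## Validation (`validation`)

MAE, RMSE and the percentage of infants within ±1/±2 weeks (closed bounds:
|residual| <= 1.0 counts as within ±7 days; the boundary convention is
unstated in the field and fixed here). 95% bootstrap percentile CIs over
1000 replicates by default (200 in the packaged experiments), resampling
infants as the unit. Reports cover overall/preterm/SGA10/SGA3, residual
summaries per completed week, and calibration-in-the-large: the estimated
preterm rate (fraction of estimates below 37 weeks) with bootstrap CI
against the rate observed from reference GA.

## Problem sizes in the packaged experiments

The accuracy study uses 41,500 simulated infants (~20,000 development /
10,000 validation / 10,000 test after exclusions) with reference-noise SD
0.6 weeks and 10% growth restriction, plus a 10,000-infant shifted external
site. Screening recovery uses 100 replicates of n = 20,000 with 40
candidates (7 informative). Bootstrap coverage uses 200 cohorts of n = 2,000
at B = 200. The pipeline demo runs 20,000 + 8,000 + 4,000 infants at
B = 200. These sizes were chosen so each study's Monte-Carlo error is well
inside the asserted margins.

## Known limitations

* The partial-Spearman screen is a linear-in-ranks approximation; strongly
  non-monotone analyte–GA relationships would need the general metric.
* Elastic-net coefficients are interpreted only as a prediction equation;
  no inference on individual analytes is supported.
* Empirical SGA centiles from a finite reference cohort are noisy in sparse
  preterm strata; records in unclassified strata are excluded from SGA
  subgroup metrics rather than imputed.
* The generator's analytes are conditionally independent given GA, so the
  elastic net's advantage over simpler selectors is smaller here than on
  real correlated panels.
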