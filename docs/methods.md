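# Methods

## The problem

Genebanks regenerate their seed holdings in field campaigns: each year a
subset of accessions is grown out, and traits such as heading date (HD,
days), plant height (PH, cm) and thousand kernel weight (TKW, g) are scored
for identity control. Accumulated over decades this produces a severely
non-orthogonal record: most accessions appear in only one or two campaign
years, a few appear in dozens, and recording conventions and error levels
differ between years. `phenocurate` turns such raw records into curated
data, per-accession BLUEs and an entry-mean heritability that summarises
how much of the observed variation is genetic.

## Model

Every analysis stage is a configuration of the additive two-way model

    y_ij = mu + g_i + a_j + e_ij,      e_ij ~ N(0, sigma2_e[j])

for accession *i* observed in campaign year *j*. The residual variance is
year-specific: historical campaigns differ in scoring staff, instruments
and conditions, and a single pooled error would mis-weight whole decades.
The accession term `g_i` is **random** (variance `sigma2_G`) when variance
components and heritability are wanted, and **fixed** when outliers are to
be detected or BLUEs estimated — a fixed `g_i` keeps genotype signal out of
the residuals. The year term `a_j` is random (variance `sigma2_A`)
throughout, except in the campaign-quality stage, where campaign means are
fixed so that each campaign's mean and error variance can be read off
directly.

Assumptions worth stating: effects are additive (no genotype-by-year
interaction), one record per accession-year (replicates are tolerated by
the engine but the pipeline treats every record as a single observation),
and normal errors within year.

## REML engine

Variance components maximise the restricted log-likelihood over
log-parameterised variances. For this design the Henderson coefficient
matrix has a *diagonal* accession block (each record touches exactly one
accession), which is absorbed analytically; one evaluation of the
objective and its analytic gradient costs O(n_records) plus a dense solve
in the number of years. Gradients use the standard identities
`Z'PZ = G^-1 - G^-1 C^uu G^-1` and `Py = R^-1 (y - W b_hat)`.

Numerical choices:

* observations are centred internally before fitting (the constant vector
  lies in every configuration's fixed-effect space, so the objective is
  unchanged); without this, `y'Py` for a trait with mean ~150 is a
  difference of ~1e6-scale terms and the optimum cannot be located beyond
  ~1e-6 relative precision;
* L-BFGS-B provides the global search; a damped Newton polish on the
  analytic gradient (Hessian by finite differences of the gradient)
  finishes to machine precision — on balanced homogeneous designs the
  estimates agree with the closed-form ANOVA method-of-moments estimators
  to ~1e-14 relative;
* every variance is floored at 1e-8 x var(y); parameters ending on the
  floor are reported in `boundary_`, never silently clipped;
* years with fewer than `min_year_df` (default 3) residual degrees of
  freedom share a pooled error variance and are listed in `pooled_years_`;
* convergence: relative objective change below `tol` (1e-8) and projected
  gradient below `gtol` (1e-6), at most 200 iterations; non-convergence is
  flagged on the fit and propagated into the curation report.

BLUEs use cell-means coding (one fixed-effect column per accession, no
intercept), so they are directly on the observation scale `mu + g_i`; this
is equivalent to reference-level coding plus recentring but needs no
post-hoc constraint. Standard errors come from the corresponding block of
the inverse coefficient matrix under a normal approximation (no
small-sample degrees-of-freedom correction).

## Curation procedure

For one genebank x seasonal-type x trait slice, in order:

1. **Plausibility trimming.** Deliberately lax closed intervals: HD 50-250
   days, PH 5-250 cm, TKW 5-100 g (bounds inclusive).
2. **Connectivity filtering.** Accessions in fewer than 2 distinct years
   and years with fewer than 2 records are removed, iterated to a fixed
   point — removing a sparse year can strand an accession and vice versa,
   and the fixed point is the only order-independent reading. A
   `strict_plus_one` switch raises both thresholds by one for very sparse
   collections. An emptied dataset is a legal outcome and becomes an
   explicit "no data remained" report row.
3. **Campaign stage.** Fit with campaign fixed / accession random; per
   campaign compute CV_j = sigma_e[j] / |campaign mean_j|, z-standardise
   the CVs across campaigns (sample SD), drop campaigns with z > 3.5.
   One-sided — unusually *uniform* campaigns are not an error signal — and
   applied once, not iterated. Note an arithmetic constraint: a z-score
   among J campaigns cannot exceed (J-1)/sqrt(J), so the 3.5 threshold can
   only ever fire when a collection spans at least 14 campaigns; short
   series pass through this stage unchanged by construction.
4. **Point stage.** Refit with accession fixed / campaign random;
   standardized residuals e_ij / sigma_e[j] are robustly re-scaled by
   their median and MAD before two-sided normal p-values are computed and
   Holm-adjusted; records with adjusted p < 0.05 are removed. The MAD
   re-scaling matters because the REML error variances are inflated by the
   very outliers being tested (1% contamination at 8 SD inflates sigma2_e
   by ~1.5x), which would deflate every standardized residual exactly when
   it matters; the clean bulk of the residual distribution restores the
   unit scale. Setting `robust_rescale=False` gives the plain
   standardized-residual variant.
5. **Components and summaries.** A final random-genotype fit on the fully
   curated data yields `sigma2_G`, `sigma2_A` and the per-year error
   variances; BLUEs come from a fixed-genotype fit on the same data. The
   entry-mean heritability is

        h2 = sigma2_G / (sigma2_G + sigma2_e / N_bar_Y)

   with `N_bar_Y` the mean number of distinct data years per accession on
   the curated data, and `sigma2_e` the *unweighted mean* of the per-year
   error variances over retained years (record-weighted mean and median
   are available via `error_variance_summary`; the unweighted mean treats
   each campaign as one environment regardless of its size).

Every removal is logged with a per-record reason
(OUT_OF_RANGE, FEW_YEARS, SPARSE_YEAR, CAMPAIGN_CV, POINT_HOLM), and the
curation report reconciles exactly: raw = kept + sum of removals.

## Synthetic data

The simulator emulates the structure of the deposited collections rather
than any one of them: a right-skewed years-per-accession profile (default
0.55/0.25/0.10/0.05/0.05 over 1-5 years), additive accession and year
effects, year-specific residual SDs jittered uniformly within +/-20% of a
trait-scale base value, and trait presets HD (mu 150 d, sigma2_G 20,
sigma2_A 10, sigma_e ~3.2), PH (100 cm, 100, 25, 6) and TKW (40 g, 16, 4,
2), all inside the plausibility windows. Contamination is injected with
labels: point outliers shift round(rate x n) records by +/- shift x
sigma_e[j] (fair-coin sign), campaign outliers redraw a chosen year's
residuals with inflated variance — variance inflation, not a mean shift,
because that is what the CV detector targets. All draws derive from one
seed via independent named streams, so incidence, values and contamination
are separately reproducible.

What the simulator does *not* emulate: location effects and weather,
genotype-by-year interaction, within-year replicates and upstream
aggregation (e.g. arithmetic means of plots), non-normal measurement error
and digit-preference artefacts, and drifting protocols. Passing recovery
tests therefore show the pipeline is correct under its own model, not that
real collections satisfy that model.

## Evaluation conditions

Problem sizes were chosen so the whole suite runs in minutes on one core:

* heritability recovery: 2,000 accessions x 12 campaigns, default skewed
  profile, clean data, 20 seeds; generating values put the true entry-mean
  h2 near 0.85, and the per-seed truth uses the realized post-curation
  `N_bar_Y` and retained years;
* outlier recovery: ~10,000 records (2,564 accessions x 25 campaigns) with
  1% point outliers at 8 SD plus one campaign at 25x variance, 20 seeds,
  under a *replicated* profile (0.05/0.10/0.15/0.30/0.40 over 1-5 years).
  Replication is a statistical necessity here, not a convenience: for an
  accession with only two records, an 8-SD shift on one record moves the
  fixed accession estimate halfway and leaves two symmetric +/-4-SD
  residuals — the anomaly cannot be attributed to either record, by any
  detector using this model. Under the regeneration-shaped sparse profile
  the point stage therefore has low sensitivity for 2-record accessions;
  this is a limitation of the published detector on such data, and the
  replicated profile measures the detector where attribution is possible;
* oracle equivalences (Holm brute force, balanced ANOVA closed form,
  dense-matrix REML/GLS, repeat-until-stable connectivity) run on small
  fixtures where the oracle is exact.

## Known limitations

* No spatial, pedigree/kinship, multi-trait or genotype-by-year models.
* HD conventions (days from Jan 1 vs from sowing) are carried as metadata
  and never converted; results are not comparable across genebanks.
* The campaign CV uses the model-estimated error SD over the absolute
  campaign mean; for traits whose values can approach zero the CV is
  ill-conditioned (not the case for the three core traits).
* Workbook round-trips through `.xlsx` preserve 16 significant digits (a
  format limit); CSV round-trips are bit-exact.
* The `strict_plus_one` trigger is a manual switch: the criterion for when
  average connectivity warrants stricter exclusion is not operationalised.
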