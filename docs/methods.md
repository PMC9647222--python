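# Methods

`radkinetics` implements a longitudinal (delta-) radiomics analysis for
predicting moderate-to-severe xerostomia after head-and-neck
radiotherapy from daily mega-voltage CT (MVCT) image-guidance scans of
the contra-lateral parotid gland.  The clinical cohort such analyses
are built on is not publicly available, so the package pairs the
analysis pipeline with a synthetic-cohort generator whose ground truth
makes every stage testable.

## Pipeline

1. **Preprocessing.**  Patients alternate between treatment machines
   with different HU calibrations; organ voxels of non-reference
   fractions are shifted by the monthly machine offset onto the
   reference scale.  Axial slices containing voxels above a
   dental-artefact threshold (default 2000 HU, chosen above dense bone
   and below metal) inside the mask dilated by 3 voxels are removed
   from the mask; voxel values are never altered.  The contra-lateral
   parotid is the gland with the lower mean dose (ties resolve to the
   left gland, with a warning).
2. **Feature extraction.**  123 features per fraction by default:
   grey-level co-occurrence (GLCM, 25 features) and run-length (GLRLM,
   16) families in both 2-D slice-averaged and 3-D aggregation,
   first-order intensity statistics (18) and intensity-histogram
   features (23).  Discretisation defaults to 32 fixed bins (recorded in
   output metadata, since texture values depend on it); GLCM distance is
   1 voxel with symmetric matrices; 2-D aggregation computes the feature
   per (slice, direction) matrix and averages ("averaged" aggregation);
   3-D uses a single matrix over the 13 unique directions.  Degenerate
   single-grey-level regions return each feature's analytic limit
   (information correlation 1 → 0, normalised grey-level non-uniformity
   → 1) so trajectories stay numeric.
3. **Kinetics.**  Per feature and patient, the ordinary-least-squares
   slope of value on fraction number is fitted from fraction 1 to every
   complete week (cut-offs at multiples of 5 fractions), giving
   predictors `<feature>_fx1_<X>`.  Mean contra-lateral dose is
   appended.  Predictors are z-scored with the population (divisor *n*)
   SD.  The standardisation population defaults to all patients —
   replicating the published procedure, which is mildly leakage-prone —
   and the stored transform supports the train-only alternative.
   Missing slopes (fewer than two usable fractions) are imputed by the
   column median, with a logged count.
4. **Selection.**  Three stages: (i) of each predictor pair with
   |Pearson r| > 0.8 (pairs processed in descending |r|), the member
   with the weaker two-sided Wilcoxon rank-sum association with the
   endpoint is dropped; (ii) predictors with rank-sum p > 0.051 are
   excluded (the threshold is kept verbatim from the procedure being
   replicated; no multiplicity correction); (iii) floating
   forward/backward stepwise search over logistic models scored by BIC
   on the deviance.  The rank-sum test enumerates the exact null when
   both groups have ≤ 10 observations and no ties; otherwise the
   tie-corrected normal approximation with continuity correction.  Mean
   dose is a structural model term, exempt from all three stages.
5. **Evaluation.**  Three logistic model types (dose only, radiomics
   only, radiomics + dose) fitted by IRLS (relative log-likelihood
   tolerance 1e-8, 100 iterations; perfect separation stabilised by a
   weak L2 penalty, λ = 1e-6, with a warning).  Stratified 3-fold CV
   with the fold allocation redrawn 200 times (bootstrap); within each
   allocation and rotation the three-stage selection is re-run on the
   training two-folds — which are exactly the two-thirds subsamples of
   the resampled selection — so the held-out fold never informs
   selection.  The classification threshold minimises
   3·FN + FP on the training folds (a missed future toxicity case costs
   three times a spurious flag) and is applied unchanged to the test
   fold.  AUC is the Mann–Whitney concordance probability with ties
   counted ½.  Every metric is summarised by its median and 5th–95th
   percentile interval over the bootstrap × fold values.
6. **Weekly sweep and final model.**  The whole selection + evaluation
   cell is repeated per endpoint (6/12/24 months) and per complete-week
   cut-off.  The final model per type maximises median test AUC subject
   to the slopes coming from the first three weeks (fractions ≤ 15),
   leaving at least half the course for treatment adaptation; ties
   break to the earliest week.  The combination fitted as the final
   model is the modal combination of the per-training-set tally (ties:
   smallest set, then lexicographic).

## Synthetic cohorts

Two generators share one outcome model.  Patient dose is
N(27, 12²) Gy truncated at 0 (matching the emulated cohort's reported
quartiles); outcome per endpoint follows a logistic model on the
standardised dose (default 0.5 log-odds/SD) and a patient-level latent
frailty (0.8 log-odds/SD) shared across endpoints, with the intercept
solved by Gauss–Hermite quadrature so the marginal prevalence equals
the configured values (defaults 0.46/0.33/0.26 at 6/12/24 months, 117
patients, 30 fractions).

*Trajectory level:* each feature's series is
`baseline + slope·fraction + N(0, noise_sd)` with per-patient slopes
`slope_scale·(ε + d·y)`, ε ~ N(0,1) — so an informative feature's
class-conditional slope means differ by exactly `d` within-class SDs,
and the binormal closed form Φ(d/√2) is the reference AUC for that
predictor.  Noise defaults to 0.5 feature units; the true slopes are
recorded, so a noiseless cohort is recovered exactly by OLS.

*Image level:* 32×32×16-voxel phantoms at 2 mm isotropic spacing with
an ellipsoidal "parotid" mask.  Texture mixes two HU populations (0 and
120 HU) by thresholding a patient-fixed smoothed Gaussian field at the
quantile of a mixing weight that grows linearly with fraction (default
0.01/fraction, twice as fast in outcome-positive patients) — yielding
spatially clustered texture, strictly monotone drift per patient, and a
mean-HU trajectory that is linear in the mixing weight by construction.
Machine offsets (default B = +30 HU) are added whole-volume; dental
artefacts are 3500 HU voxel blocks injected per slice with the
configured probability and recorded in the ground truth; optional mask
shrinkage emulates gland volume loss.

What the phantoms do **not** emulate: anatomical parotid shape,
MVCT noise spectra and reconstruction artefacts, registration error in
contour propagation, or dose gradients beyond a scalar mean dose.
Passing tests therefore demonstrate the correctness and calibration of
the *procedure* (no manufactured discrimination under the null, correct
recovery when a kinetic signal exists), not clinical performance on
real MVCTs.

## Numerical choices

- Discretisation: fixed bin number, `level = min(Ng, 1 + ⌊Ng(x−min)/(max−min)⌋)`;
  fixed bin size: `1 + ⌊(x−min)/w⌋`.  A constant region collapses to
  one level.
- Quartiles and percentile CIs use linear interpolation between order
  statistics.
- Histogram gradients are central differences in the interior and
  one-sided at the first/last grey level; gradient-extremum intensities
  are reported as the HU centre of the discretisation bin.
- Threshold search candidates are midpoints between consecutive sorted
  unique probabilities plus sentinels beyond both extremes; ties break
  to the highest sensitivity, then the lowest threshold.
- Stepwise ties break to the lower column index; the search is
  deterministic given column order and strictly decreases BIC, which
  guarantees termination.
- Fold allocations are shared across week cut-offs of one endpoint, so
  the dose-only reference is exactly week-independent.
- All randomness derives from a single integer seed via independent
  spawned generators; whole-pipeline outputs are byte-reproducible
  (fixed matplotlib SVG hash salt, no timestamps in artefacts).

## Design choices where the procedure was open

- The stepwise criterion is BIC on the logistic deviance: the search
  direction ("sequential backward/forward") is prescribed by the
  replicated procedure but its criterion is not, and BIC's strong
  penalty matches the procedure's emphasis on robustness.
- The per-training-set selections inside the evaluation are tallied as
  the selection-frequency record (3 fold rotations × bootstrap
  reallocations entries); a standalone subsample-based
  `robust_select` is retained for exploratory use.
- Metrics are aggregated by the median (mean is a one-line change).
- Imputation of missing slope predictors uses the column median.
- The correlation between feature kinetics and gland-volume kinetics is
  Pearson by default, Spearman by flag.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run cohorts of 40–500
patients, 50 bootstrap reallocations and 200 selection repeats — large
enough for the stochastic bands they assert (binomial/CLT tolerances
are stated next to each check) while keeping a full run in minutes.

## Known limitations

- The 123-feature default bank is a documented stand-in: it spans the
  same families but is not guaranteed to be the exact published list,
  and wavelet/filtered-image and advanced shape features are absent.
- `normalize_hu` shifts masked voxels only; whether whole-volume
  shifting was intended in the emulated procedure is ambiguous.
- No deformable contour propagation: masks are assumed given per
  fraction.
- No NTCP-style dose-response modelling, survival-time analysis or
  external validation machinery.
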