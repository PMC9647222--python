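# radkinetics

Daily-image radiomics **kinetics** for predicting radiation-induced
xerostomia (dry mouth) in head-and-neck radiotherapy.

Helical radiotherapy platforms acquire a mega-voltage CT (MVCT)
guidance scan before every one of the ~30 daily treatment fractions.
Those images are normally discarded after positioning, yet the texture
of the spared (contra-lateral) parotid gland changes during treatment,
and the *rate* of that change carries patient-specific response
information that pre-treatment dose metrics do not.  `radkinetics`
implements the full analysis chain for exploiting it:

1. **preprocess** — inter-machine HU normalisation of organ voxels,
   dental-artefact slice exclusion, contra-lateral gland identification
   (minimum mean dose);
2. **features** — an IBSI-style bank of 123 radiomics features per
   fraction (GLCM, GLRLM, intensity statistics, intensity histogram; 2-D
   slice-averaged and 3-D texture aggregation);
3. **kinetics** — for every feature, the OLS slope of value on fraction
   number from fraction 1 to each complete week X (predictors
   `<feature>_fx1_X`), standardised, with mean parotid dose appended;
4. **select** — a three-stage predictor selection (correlation pruning
   at |r| > 0.8 with the weaker Wilcoxon association dropped,
   univariable rank-sum filter at p ≤ 0.051, floating
   forward/backward stepwise search under BIC), repeated on resampled
   two-thirds subsets and tallied;
5. **model** — dose-only, radiomics-only and radiomics+dose logistic
   models under stratified 3-fold cross-validation with 200 bootstrap
   fold reallocations, cost-sensitive thresholds (a missed toxicity
   case costs 3× a false alarm) and 5th–95th percentile CIs, swept over
   weekly cut-offs, with the final model constrained to slopes from the
   first three weeks so treatment can still be adapted;
6. **report** — selection-frequency tables, performance grids, ROC and
   calibration curves, and the correlation of feature kinetics with
   simple gland-volume change.

Because the clinical MVCT cohorts such studies use are not publicly
deposited, the package includes a first-class **synthetic** module that
generates cohorts at two levels — feature trajectories with known true
slopes, and textured 3-D phantoms whose parotid texture drifts at an
outcome-dependent rate — so every stage is testable against ground
truth.  See `docs/methods.md` for the model details and design
decisions.

## Worked example

```python
import radkinetics as rk

cfg = rk.SyntheticConfig(n_patients=117, n_fractions=30, n_features=123,
                         prevalence={"6m": 0.46},
                         informative_features=[(0, 1.5)], seed=7)
coh = rk.generate_trajectory_cohort(cfg)
sweep = rk.weekly_sweep(coh.to_feature_table(), coh.outcomes, coh.doses,
                        eval_config=rk.EvalConfig(n_bootstrap=50, seed=7),
                        weeks=[5, 10, 15])
for (ep, wk), rep in sorted(sweep.reports.items()):
    row = {mt: round(rep.median(mt, "auc", "test"), 3)
           for mt in ("dose_only", "radiomics_only", "radiomics_plus_dose")}
    print(f"week {wk:2d}  AUC_test {row}")
fm = rk.select_final_model(sweep, coh.outcomes, "6m")["radiomics_only"]
print(f"final radiomics model: week {fm.week}, predictors {fm.spec.predictors}, "
      f"median AUC_test {fm.auc_test_median:.3f}")
```

Output:

```
week  5  AUC_test {'dose_only': 0.693, 'radiomics_only': 0.567, 'radiomics_plus_dose': 0.636}
week 10  AUC_test {'dose_only': 0.693, 'radiomics_only': 0.719, 'radiomics_plus_dose': 0.767}
week 15  AUC_test {'dose_only': 0.693, 'radiomics_only': 0.818, 'radiomics_plus_dose': 0.853}
final radiomics model: week 15, predictors ['feature_000_fx1_15', 'feature_039_fx1_15'], median AUC_test 0.818
```

The cohort contains one informative feature (index 0) whose slope
separates future toxicity cases by 1.5 within-class SDs.  Early slopes
(week 5) are too noisy to beat the dose baseline; by week 15 — still
within the three-week adaptation window — the kinetic predictor is
picked up by the in-fold selection and the radiomics model clearly
outperforms the dose-only reference (median test AUC 0.818 vs 0.693).
The selection occasionally admits a spurious companion predictor
(`feature_039`), visible in the tally and its frequency table.

## Command line

```sh
radkinetics simulate --mode image --n-patients 20 --seed 1 --outdir sim/
radkinetics extract  --indir sim/ --out features.csv
radkinetics kinetics --features features.csv --patients sim/patients.csv --out slopes.csv
radkinetics select   --slopes slopes.csv --patients sim/patients.csv --endpoint 6m --out tally.json
radkinetics sweep    --features features.csv --patients sim/patients.csv --outdir out/
radkinetics report   --indir sim/ --slopes slopes.csv --out corr.csv
radkinetics pipeline --mode trajectory --seed 1 --outdir run/   # end-to-end
```

All commands take `--seed`; identical seeds reproduce every artefact
byte-for-byte.

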