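# oxaqsar

QSAR activity modeling for a series of 33 dihydropteridone derivatives
bearing an oxadiazole moiety, inhibitors of MCF-7 breast-cancer cells.
The package is aimed at computational medicinal chemists who want the
complete, reproducible modeling chain behind this compound series:
descriptor-based activity regression, cross-validation, external
validation, applicability-domain analysis, and drug-likeness screening of
newly designed analogues — with the study's entire dataset embedded as
validated fixtures.

## The models

Activity is expressed as pIC50 = 6 − log₁₀(IC50/µM). Six molecular
descriptors drive the models: stretch energy *S*, torsion energy *Tor*
(kcal/mol), melting point *MP*, rotatable-bond count *NRB*, repulsion
energy *repul*, and global hardness η = (E_LUMO − E_HOMO)/2 (Hartree).

* **Linear (MLR)** — ordinary least squares,
  pIC50 = a₀ + Σᵢ aᵢXᵢ, fitted on 25 training compounds
  (`LinearQSAR`). The published equation
  pIC50 = −10.59993 + 0.81144·S − 0.09127·Tor + 0.00643·MP
  − 0.24116·NRB − 0.00086·repul + 191.40275·η
  ships as a prediction-ready model (`published_mlr_model()`), kept
  distinct from fresh refits.
* **Polynomial (MNLR)** — OLS with one squared term per descriptor
  (`QuadraticQSAR`), no cross terms.
* **Neural network (ANN)** — a deterministic 6-3-1 feed-forward net with
  sigmoid hidden layer (`ANNQSAR`); with 25 free parameters on 25 training
  compounds it near-interpolates by design.

Validation: leave-one-out Q² = 1 − PRESS/SS (`loo_q2`), the
Golbraikh–Tropsha external battery (r², through-origin r₀²/r′₀², slopes
k/k′ with their thresholds; `golbraikh_tropsha`), and a hat-matrix
applicability domain hᵢ = xᵢ(XᵀX)⁻¹xᵢᵀ with warning leverage
h\* = 3(p+1)/n (`LeverageAD`). Drug-likeness screening applies the
Lipinski, Veber, Egan and Muegge rule sets. A synthetic-data generator
(`generate_dataset`, `recovery_experiment`) produces QSAR-like datasets
with known ground truth for calibration and recovery studies.

All estimators follow the scikit-learn fit/predict conventions and compose
with its model-selection tools.

## Worked example

```python
from oxaqsar import (load_study_dataset, LinearQSAR, loo_q2,
                     golbraikh_tropsha, published_mlr_model,
                     LeverageAD, screen_candidates)

ds = load_study_dataset()
train = ds.training()

model = LinearQSAR().fit(train, train["pIC50_obs"])
s = model.stats_
print(f"R2={s.r2:.3f}  adjR2={s.r2_adjusted:.3f}  MSE={s.mse:.4f}  F={s.f_statistic:.2f}")

cv = loo_q2(train)
print(f"Q2={cv.q2:.3f}  MSE_cv={cv.mse_cv:.4f}")

test = ds.test()
gt = golbraikh_tropsha(test["pIC50_obs"], model.predict(test))
print(f"r2={gt.r2:.4f}  k={gt.k:.4f}  k'={gt.k_prime:.4f}  all_pass={gt.all_pass}")

ranking = screen_candidates(published_mlr_model(), ds.candidates,
                            ds.candidate_properties,
                            baseline=ds.max_observed_activity,
                            domain=LeverageAD().fit(ds.modeling))
print(ranking[["candidate_id", "predicted_pIC50", "improvement_vs_best",
               "in_domain", "lipinski_violations"]].to_string(index=False))
```

prints

```
R2=0.909  adjR2=0.879  MSE=0.0207  F=29.98
Q2=0.831  MSE_cv=0.0277
r2=0.7053  k=1.0065  k'=0.9919  all_pass=True
candidate_id  predicted_pIC50  improvement_vs_best  in_domain  lipinski_violations
          M5         9.575053             1.515053      False                    0
          M2         9.528710             1.468710      False                    0
          M4         9.423883             1.363883      False                    0
          M3         9.384416             1.324416      False                    0
          M1         9.276724             1.216724      False                    0
```

Reading this: the refitted linear model explains ~91% of the training
variance with a leave-one-out Q² of 0.83; the external test set passes
every Golbraikh–Tropsha criterion; and all five designed candidates are
predicted 1.2–1.5 log units more potent than the best training compound
(pIC50 8.06) while passing every drug-likeness screen. Note the
`in_domain` flags: the candidates' descriptors (lower stretch energy,
higher hardness) lie at or beyond the modeling compounds' ranges, so their
high leverage marks those predictions as extrapolations — the impressive
predicted gains should be read with that caveat.

A command-line interface mirrors the library:

```sh
oxaqsar fit --data fixtures --model mlr
oxaqsar validate
oxaqsar ad --williams-csv williams.csv
oxaqsar predict --model published
oxaqsar simulate --n-compounds 31 --replicates 100
```

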