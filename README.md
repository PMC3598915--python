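# survtransfer

Predictability and cross-center reproducibility of survival risk
prediction models.

## The problem

Prognostic models built on one hospital's patients — from clinical
covariates, gene-expression signatures, or both — often travel poorly:
a model fitted at center *i* may rank center *j*'s patients quite
differently than center *j*'s own model would. `survtransfer` implements
a complete framework for quantifying this, aimed at biostatisticians
evaluating multi-center survival studies:

* **Eight risk prediction models** fitted per center:

  | kind | design entering the Cox fit |
  |------|-----------------------------|
  | A | clinical covariates (age, gender, stage, histology) |
  | B | leaf incidence rate of a clinical survival tree |
  | C | first *k* = 5 principal-component meta-genes of the selected genes |
  | D | the *k* = 10 smallest-p genes from univariate Cox screening |
  | E–H | additive combinations A+C, A+D, B+C, B+D (one joint Cox refit) |

  Every model yields a risk score, the linear predictor
  H<sub>j</sub> = β̂ᵀx<sub>j</sub>; higher score = higher predicted hazard.

* **Predictive-performance measures** of a score vector on a test cohort:
  Somers' rank correlation D<sub>xy</sub> between score and survival time
  (negative for a good model; D<sub>xy</sub> = 2c − 1 with the concordance
  index c), the hazard ratio e^β̂ with Wald p and the explained variation
  R² = 1 − exp(−LR/n) from a univariate Cox fit of the scores, the
  time-dependent ROC(t) curve for censored data (cases: events by t;
  controls: followed beyond t; censored-before-t excluded), and the
  two-group comparison that splits the test cohort at the **median of the
  training scores** (degenerate splits report NA, not errors).

* **Cross-center reproducibility** via Pearson correlations of predicted
  scores: transferability Tran<sub>ij</sub> = ρ(β̂<sub>i</sub>ᵀX<sub>j</sub>, β̂<sub>j</sub>ᵀX<sub>j</sub>)
  and consistency Cons<sub>ij|k</sub> = ρ(β̂<sub>i</sub>ᵀX<sub>k</sub>, β̂<sub>j</sub>ᵀX<sub>k</sub>)
  (which reduces to transferability when k = j), tabulated for all center
  pairs; plus a resampling procedure that repeatedly splits one center
  into train/test halves and compares a foreign model (*vmc*), a local
  model (*mcc1*) and a local refit borrowing the foreign gene signature
  (*mcc2*), producing the draws ρ₁ = ρ(vmc, mcc1), ρ₂ = ρ(vmc, mcc2),
  ρ₃ = ρ(mcc1, mcc2).

* **A synthetic multi-center generator** with known ground truth:
  censored survival times from an exponential proportional-hazards model,
  clinical covariates with genuine prognostic effects, a large noise gene
  panel with a small planted prognostic subset, per-center batch shifts
  and a controllable censoring fraction.

The survival estimators underneath (Kaplan–Meier, k-sample log-rank, Cox
partial likelihood with Efron ties via Newton–Raphson, log-rank-split
survival tree) are implemented from scratch in `survtransfer.survival` and
cross-checked against independent oracles in the test suite.

## Worked example

```python
from survtransfer import (SimConfig, ModelConfig, generate_multicenter,
                          fit_risk_model, predict_risk,
                          resample_signature_transfer)
from survtransfer.metrics import predictability_report

cfg = SimConfig(n_centers=2, n_patients_per_center=(200, 200),
                n_genes=200, n_prognostic_genes=10, gene_effects=0.1, seed=42)
(train, test), truth = generate_multicenter(cfg)

mcfg = ModelConfig(selection_threshold=0.01)
for kind in ("A", "D"):
    model = fit_risk_model(kind, train, mcfg)
    report = predictability_report(kind, predict_risk(model, train),
                                   predict_risk(model, test), test.outcomes,
                                   evaluation_times=(36.0,))
    tg = report.twogroup
    print(f"model {kind}: Dxy={report.dxy:+.3f}  HR={report.hr:.2f} "
          f"(p={report.hr_p:.2g})  R2={report.r2:.3f}  "
          f"two-group HR={tg.hr:.2f} (log-rank p={tg.logrank_p:.2g})  "
          f"AUC(36)={report.roc[0].auc:.3f}")

res = resample_signature_transfer(train, test, "D", n_train=55, n_reps=100,
                                  seed=7, config=mcfg)
s = res.summary()
print("model D resampling: rho1 median=%.3f  rho2 median=%.3f  rho3 median=%.3f"
      % (s["rho1"]["median"], s["rho2"]["median"], s["rho3"]["median"]))
```

prints

```
model A: Dxy=-0.306  HR=2.20 (p=1.3e-08)  R2=0.149  two-group HR=2.93 (log-rank p=1.6e-07)  AUC(36)=0.729
model D: Dxy=-0.452  HR=2.02 (p=3.3e-14)  R2=0.257  two-group HR=2.76 (log-rank p=5.5e-06)  AUC(36)=0.785
model D resampling: rho1 median=0.760  rho2 median=0.780  rho3 median=1.000
```

Reading the numbers: both models rank the external cohort well (negative
D<sub>xy</sub>; a unit increase in risk score roughly doubles the hazard,
with tiny p-values), and the two-group split at the training median
separates survival cleanly. Under resampling, the model trained at the
foreign center agrees with local models at ρ ≈ 0.76 — good but visibly
below the within-center agreement of 1 — and sharing the foreign gene
signature (ρ₂) helps slightly. ρ₃ = 1 whenever both 55-patient training
splits select the same top genes; it drops once the gene signal is weak
and diffuse enough that signatures become unstable.

## Command line

A run is driven by one YAML config (see `survtransfer.pipeline.RunConfig`):

```bash
survtransfer crosscenter --config run.yaml   # Table-6-style correlation table
survtransfer evaluate    --config run.yaml   # 12-way pairwise predictions
survtransfer resample    --config run.yaml   # rho1/rho2/rho3 draws + summary
survtransfer report      --config run.yaml   # print the run manifest
```

Artifacts are CSV/JSON files plus a `run_manifest.json` (config hash,
seed, versions) that makes every number reproducible; identical config
and seed produce byte-identical reports.

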