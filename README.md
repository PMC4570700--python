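# autoqsar-select

Automated regression model selection for QSAR-style numeric tables.

## The problem

In QSAR and related predictive-modelling work (chemical descriptors →
activity, protein abundances → cell association, nano-descriptors →
toxicity), the modeller's choices — how to split the data, which
cross-validation scheme to use, which filters and scaling to apply, which
of many regression families to try, and how to declare a winner — all
affect the reported model and make results hard to reproduce or compare.
This package standardizes that whole procedure behind one call: it cleans
a numeric table, runs up to ten regression methods under one
cross-validation recipe across repeated random train/test splits, records
a uniform 17-value statistics row per method × split × CV type, selects a
best model by an explicit criterion, and validates it with
Y-randomization and applicability-domain diagnostics.

It is for modellers who want a reproducible first pass over the model
space of a numeric endpoint, irrespective of their statistics background.

## The methodology

Input is a delimited table whose **first column is the response** and the
rest are features; non-numeric columns are dropped, rows with missing
values removed. Then:

1. **Filters** — near-zero-variance removal (a feature goes if it is
   constant, or its most-frequent/second-most-frequent count ratio ≥ 95/5
   while its unique-value percentage ≤ 10%), feature scaling
   (standardize or min–max normalize; the response is never scaled), and
   greedy correlated-feature removal until no retained pair has
   |Pearson r| ≥ 0.9.
2. **Splits** — 10 random 75%/25% train/test splits (seeded,
   reproducible).
3. **Methods** — LM, GLM (stepwise-AIC linear model), PLS, LASSO, ENET,
   SVRM (radial SVM), NN (single-hidden-layer), RF, RF-RFE and SVM-RFE.
   Hyperparameters are tuned by minimum mean RMSE over repeated 10-fold
   CV (10 repeats; the RFE methods use 5-fold/3-fold single-repeat
   internal CV); leave-one-out CV is additionally available for all but
   the three most expensive methods (RF, RF-RFE, SVM-RFE).
4. **Statistics** — per method × split × CV type, a fixed 17-value
   record: CV RMSE and R² (R² as squared Pearson correlation), test
   RMSE/R²/correlation, training fit RMSE/R² (coefficient of
   determination)/correlation, adjusted R² on both sets, standardized
   RMSE (RMSE divided by sd of the observed values), plus the selected
   feature list.
5. **Selection** — average each method's statistics over splits; among
   methods within 0.005 of the best mean R²_test, pick the one with the
   lowest mean RMSE_test.
6. **Validation** — Y-randomization: refit the winner 100 times (default)
   with permuted training responses and report the fraction of permuted
   runs reaching the observed R²_test. Applicability domain: hat values
   h_ii of the winning design with the leverage threshold 3m/n, and
   Cook's distances D_i = e_i²h_i / (m s² (1−h_i)²) with a 4/n cutoff.

Everything is deterministic given the base seed, including parallel runs
(task seeds derive from task identity, not scheduling order).

## Worked example

`python examples/01_model_selection.py` builds a 200-case synthetic
dataset whose response is a linear function of 3 of its 10 descriptors
(population R² = 0.9) and runs four methods over 3 splits:

```
mean statistics over splits (repeated 10-fold CV):
method     R2_cv  RMSE_cv  R2_test  RMSE_test
ENET       0.905    0.534    0.892      0.592
LASSO      0.909    0.539    0.891      0.587
LM         0.901    0.549    0.886      0.601
PLS        0.912    0.538    0.886      0.602

selected best model: LASSO
selection rationale:
best mean R2_test = 0.891581; tolerance band 0.005
candidates (method/cv, R2_test, RMSE_test, margin to best):
  LASSO/repeated_kfold: R2=0.891127 RMSE=0.587354 margin=0.00045438
  ENET/repeated_kfold: R2=0.891581 RMSE=0.591582 margin=0
selected LASSO (repeated_kfold) by minimal RMSE_test within the band
```

All four methods sit near the population R² of 0.9 — the pipeline
neither overfits nor leaves signal behind. ENET has the best mean
R²_test, but LASSO lies within the 0.005 tolerance band and has the
lower RMSE_test, so the rule selects LASSO. The other examples
demonstrate Y-randomization (`02_y_randomization.py`) and the
leverage/Cook applicability-domain report (`03_applicability_domain.py`).

## Command line

```bash
autoqsar-select run --data MyDataSet.csv --out results/ \
    --methods lm,pls,lasso,enet --splits 10 --seed 1
```

writes `statistics.csv` (all 17-value records), `summary.csv`
(split-averaged per method × CV type), `best_model.csv` (winner,
rationale, Y-randomization digest), `applicability_domain.csv`,
`filters.csv`, `splits.csv`, a manifest, and — with `--detailed` —
per-method prediction/importance files ready for observed-vs-predicted
and importance plots.

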