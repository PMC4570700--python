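# Methods

This note documents the modelling procedure, its defaults, the synthetic
data used to exercise it, and the numerical and design choices that were
genuinely open.

## The procedure

The pipeline treats model selection itself as the experiment: every
candidate regression family is subjected to the same data cleaning, the
same resampling plan and the same scoring, so that the only degree of
freedom left is the family's own capacity.

**Cleaning.** The response is the first column by convention. Non-numeric
feature columns are dropped before row filtering, so text-coded missing
markers in columns that are about to be discarded cannot delete rows.
Rows with any remaining missing value (tokens: empty field, `NA`, `NaN`,
case-insensitive; configurable) are removed — complete-case analysis, no
imputation.

**Filters.** Three dataset-level steps, in a fixed order:

1. *Near-zero variance*: a feature is removed iff it has a single unique
   value, or (count of most frequent level)/(count of second most
   frequent) ≥ `freq_cut` **and** 100·distinct/n ≤ `unique_cut`.
   Defaults `freq_cut = 95/5`, `unique_cut = 10` — the long-standing
   convention for this filter in the R modelling ecosystem.
2. *Scaling*: standardize (z-score, sample sd) by default; min–max
   normalization and "none" are first-class. The response is never
   scaled. Scaling is fitted on the full pre-split dataset, matching the
   procedure's step order (scale before split); a leak-free variant that
   fits scaling per training partition is a documented possible
   extension, not the default, because fidelity to the standard step
   order was preferred.
3. *Correlation filter*: while any pair has |Pearson r| ≥ `cutoff`
   (default 0.9), take the worst pair (largest |r|; ties toward earlier
   column indices) and remove the member with the larger mean absolute
   correlation to all remaining features (tie: the later column goes).
   Deterministic given column order; afterwards no retained pair reaches
   the cutoff.

**Resampling.** `n_splits` (default 10) random train/test splits with
train fraction 0.75. |train| = round(0.75·n). Within a training
partition, repeated k-fold CV deals the cases into k blocks whose sizes
differ by at most one, re-shuffled per repeat; defaults are 10 folds ×
10 repeats. Leave-one-out produces n singleton blocks. One base seed
governs the run: split i uses `base_seed + i`; each (method, split, CV
type) task derives its own seed from a CRC32 hash of the task identity,
so results are independent of worker count and scheduling order.

**Methods and tuning.** Ten families behind one adapter contract
(fit/predict, selected features, importances):

| method | estimator | tuned over |
|---|---|---|
| LM | ordinary least squares | — |
| GLM | OLS + bidirectional stepwise AIC | — |
| PLS | partial least squares | ncomp 1..min(p, 10) |
| LASSO | L1 linear model | 10 log-spaced penalties in [λ_max·10⁻⁴, λ_max] |
| ENET | L1+L2 linear model | same penalties × mixing 0.1..1.0 |
| SVRM | radial-kernel SVR | cost 2⁻²..2⁷ × kernel width (median heuristic ± one octave) |
| NN | 1-hidden-layer perceptron (LBFGS) | size {1,3,5,7} × weight decay {0, .001, .01, .1} |
| RF | random forest, 500 trees | mtry {⌊p/3⌋, ⌊√p⌋, p} |
| RF-RFE | RF + recursive feature elimination | subset size, 5-fold × 1 internal CV |
| SVM-RFE | linear SVR + RFE (w² importance) | subset size, 3-fold × 1 internal CV |

For each grid point, the mean RMSE over all held-out resamples is
computed; the argmin is refit on the full training partition, and that
point's per-resample metrics populate the CV columns of the statistics
record. Grid points that fail to fit are skipped with a warning (NN gets
up to 3 seeded restarts first) and can never be reported as best.
RF, RF-RFE and SVM-RFE are restricted to repeated k-fold (LOO is
disproportionately expensive for them). Stepwise AIC uses
AIC = n·ln(RSS/n) + 2(k+1), starts from the full model (aliased columns
dropped; if n is too small, from the empty model), takes the best
single add/drop per step, and stops when no move improves; GLM's
cross-validation honestly refits the stepwise selection inside every
resample. On a pure-noise response GLM may select nothing; the model
then predicts the training mean and records 0 features.

**Statistics.** The 17-value record per method × split × CV type, in
fixed column order: method, split, CV type, number and names of selected
features, training adjusted R², RMSE_CV, R²_CV, standardized training
RMSE, test adjusted R², RMSE_test, R²_test, test correlation, training
fit RMSE, training fit R², training correlation, standardized test RMSE.
Conventions: CV/test R² is the squared Pearson correlation (bounded,
affine-invariant — the resampling convention); the training *fit* R² is
the coefficient of determination 1 − RSS/TSS; both appear in the record.
"Standardized RMSE" is RMSE divided by the sample sd (n−1) of the
observed values. LOO pools the singleton residuals for RMSE and the
pooled observed/predicted pairs for R², since per-singleton R² is
undefined. Undefined quantities (zero-variance vectors, n ≤ p+1 for the
adjustment) are recorded as NaN with a warning and excluded from means.

**Selection.** Per (method, CV type), all numeric record fields are
averaged over splits (non-missing entries only). Candidates are the
summaries within `tolerance` (default 0.005) of the best mean R²_test;
the winner has the lowest mean RMSE_test, with ties broken by fewer mean
features, then method-name order.

**Y-randomization.** For the last data split and the selected model:
permute the training responses (seeded per run), re-tune and refit, and
score R²_test on the untouched test partition; report the full permuted
distribution and the exceedance fraction (share of runs ≥ the observed
R²_test). Re-tuning per run is the default because the permuted fit
should enjoy every advantage the real fit had; a flag freezes the
observed hyperparameters instead. A permuted run whose model predicts a
constant (e.g. a fully shrunk lasso) records R² = 0 — it demonstrates
the absence of association rather than a failed computation. Default
100 runs.

**Applicability domain.** On the training design of the winning split
(the split where the selected method scored its best R²_test), restricted
to the model's selected features plus an intercept: hat values as the
diagonal of X(XᵀX)⁻¹Xᵀ (computed via QR; the trace identity
Σh_ii = m is asserted), leverage threshold 3m/n, Cook's distances
D_i = e_i²h_i/(m·s²·(1−h_i)²) with s² = RSS/(n−m), cutoff 4/n
(configurable; a conventional choice, as no single standard exists).
For non-linear winners the diagnostics use the linear design of the
selected features: leverage is a property of descriptor-space geometry,
not of the fitted predictor. Rank-deficient designs drop aliased columns
with a warning; a numerically perfect fit (RSS ≤ 10⁻²⁴·‖y‖²) reports all
distances as zero rather than amplifying rounding noise.

## Synthetic data

The generators provide known ground truth for every stage:

* **linear** — X i.i.d. standard normal, y = Xβ + ε; the metadata
  records the population R² = βᵀβ/(βᵀβ+σ²). Defaults n = 200, 3
  informative features with β = (1, 1, 1), 7 pure-noise features,
  σ = 0.577, giving population R² ≈ 0.9 — strong but not trivial signal.
* **collinear** — a linear response plus planted filter fodder: one
  constant column, one 95/5 two-level column (frequency ratio exactly
  19), one exact duplicate pair, and independent survivors; the manifest
  names them so tests can assert *exact* filter behaviour.
* **nonlinear** — the canonical curved benchmark surface
  y = 10·sin(π·x₁x₂) + 20·(x₃−0.5)² + 10·x₄ + 5·x₅ + ε on ten
  Uniform(0,1) inputs (five informative), where interactions and
  curvature separate flexible learners from linear ones.
* **null** — y independent of X, for null-consistency checks.

All are pure functions of their spec (bit-reproducible). What they do
*not* emulate: real descriptor distributions (heavy tails, discreteness,
block correlation), measurement error in X, and dataset sizes in the
thousands — so passing tests demonstrate the machinery's correctness and
the expected qualitative orderings, not performance claims about any
particular chemical series.

## Numerical choices

* λ_max for the L1 grid is max|X_cᵀ(y−ȳ)|/n, the smallest penalty that
  zeroes all coefficients for an intercept model.
* The RBF width's median heuristic uses the median pairwise squared
  distance of (at most 200 subsampled) training rows; γ = 1/(2·median).
* Lasso/elastic-net "selected features" are the coefficients with
  |β| > 10⁻¹²; if everything is shrunk away the largest-|β| slot is kept
  so the model contract (non-empty selection) holds for real fits.
* Grid ties (equal mean CV RMSE) resolve to the earlier grid point;
  RFE subset-size ties resolve to fewer features.
* Stepwise accepts a move only if it improves AIC by more than 10⁻¹⁰,
  guarding against float-noise cycling.

## Test and verification sizes

The shipped tests and the acceptance script exercise the pipeline at
deliberately modest sizes — n between 100 and 300, 2–10 splits, 1–3 CV
repeats, RF at 25–100 trees — chosen so the full suite runs in a few
minutes while still separating the behaviours under test (support
recovery, method ordering, null collapse) by wide margins. Package
defaults (10×10 CV, 500 trees, 10 splits, 100 Y-randomization runs)
reflect the standard recipe and are what `RunConfig()` gives you.

Key independent oracles used by the tests: metric primitives against
explicit-loop recomputation; the generic LOO loop against the hat-matrix
closed form obs − e/(1−h) for OLS; Cook's formula against brute-force
leave-one-out refits; stepwise AIC against exhaustive subset enumeration;
filter behaviour against planted pathologies with known manifests.

## Known limitations

* The squared-correlation R² convention can flatter models with
  systematic bias (it is affine-invariant); the coefficient-of-
  determination fit statistic in the same record exposes this.
* A permuted-trained unregularized LM retains a chance test R² of order
  1/p (its predictions live in the descriptor column space, which also
  carries the signal); Y-randomization digests are therefore most
  informative for the selected, typically regularized, winner.
* Scaling before splitting leaks mild distributional information from
  test to train; kept for fidelity to the standard step order (see
  Filters above).
* The applicability-domain analysis is leverage-based only; distance-to-
  model metrics and Williams-plot rendering are out of scope, though the
  emitted CSVs contain everything needed to draw them.
* No stratification of splits on the response; heavily skewed endpoints
  may occasionally produce unlucky test partitions, which the multi-split
  averaging is designed to absorb.
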