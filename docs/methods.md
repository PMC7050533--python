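# Methods

## Model and assumptions

The package treats a phenotypic screen as a two-layer generative chain:
a compound's descriptor vector `d` determines a vector of binary target
activities `t = (t_1, …, t_K)` over a fixed protein panel, and the
phenotype outcome `p` depends on the compound only through `t`. Both
conditionals are linear logistic models. Three assumptions are built in:

1. **Factorized targets.** `P(t|d) = Π_k P(t_k|d)`: target activities
   are conditionally independent given the compound. This is implicit in
   training one logistic model per target/family; the exact
   marginalization (`predict_phenotype_exact`) makes it explicit by
   weighting each configuration with the product of Bernoulli marginals.
2. **Mean-field chaining.** `P(p|d) = E_{t|d} P(p|t)` is approximated by
   `P(p|t̄)` with `t̄_k = E[t_k|d]`. The approximation is exact when all
   marginals are degenerate (0/1) and when the phenotype weights are
   small enough that σ is locally linear; it overshoots when a large
   weight multiplies an uncertain target (the K=1, marginal 0.5, weight
   10 instance: exact 0.7500 vs mean-field 0.9933).
3. **Linearity within a family.** One interaction model per protein
   family scores all of that family's proteins from the concatenated
   [compound ; protein] descriptor vector. A per-protein alternative is
   available (`TrainingConfig.per_protein`) but off by default, since
   family-wise pooling is how interaction corpora are organized and
   shares statistical strength across related proteins.

Training the mean-field phenotype model minimizes regularized
cross-entropy on (profile, label) pairs; the KL divergence to the
empirical label distribution differs from the cross-entropy only by the
label entropy, a constant in the parameters, so it is never computed.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `affinity_threshold_uM` | 30 | potency cutoff (μM); a pair is active iff its most potent measurement is *strictly* below the cutoff. The boundary value itself is inactive. |
| `c_grid` | 1e-4 … 1e4, decade steps | inverse regularization strengths searched by CV AUC; ties go to the smallest C (strongest regularization), which makes selection deterministic. |
| `cv_folds` | 5 | folds for every AUC estimate; stratified by label because association tables are heavily imbalanced. |
| `threshold_step` | 0.02 | per-cycle increment of the selection weight threshold τ. |
| `retention` | 0.95 | fraction of the full-panel CV AUC a restricted model must keep. |
| `standardize` | stage 1: on; stage 2: off | descriptors are z-scaled with training-fold statistics (liblinear is scale-sensitive and penalties are scale-dependent); profiles already live in [0,1] and are left alone. |
| `tol`, `max_iter` | 1e-4, 1000 | liblinear convergence; L1 fits at large C dominate runtime, and these values match standard solver practice. |

All randomness (fold shuffling, the solver's coordinate order, corpus
generation) flows from explicit seeds; identical inputs and seed give
byte-identical selection traces.

## Selection procedure: semantics chosen where the loop was open

* The threshold at cycle *i* is applied to the weights of the
  *immediately preceding retrained model* (cycle *i−1*; the full-panel
  model before cycle 0), so the surviving sets shrink monotonically by
  construction.
* Only strictly positive weights survive any τ ≥ 0; negative-weight
  proteins are never selectable.
* The returned set is the **last cycle that still met the retention
  gate** — the failing cycle is kept in the trace but not returned. This
  reading preserves the procedure's purpose (maximal reduction while
  maintaining accuracy). If even cycle 0 fails the gate the full panel
  is returned and the trace is flagged; if the full model has no
  positive weights the empty set is returned, also flagged.
* The C grid is re-run in every cycle by default (each cycle is a full
  model construction); `freeze_c` reuses the full model's C instead.
* When consecutive cycles select the same protein set, the retrained
  model is reused rather than refit — the procedure is deterministic, so
  the refit would be identical; this caps the number of distinct fits at
  K+1 regardless of how many threshold increments pass.

## Synthetic benchmark: what it emulates, what it does not

The generator plants the exact structure the method assumes: i.i.d.
standard-normal compound descriptors; per-family sparse compound-side
weight vectors (5 nonzeros, norm 3.0) with per-protein biases
(N(−1, 0.25), giving ≈35–40% active pairs); target activities drawn
Bernoulli(σ(w·d + b)); and phenotype labels drawn from the TRUE binary
activities through 3 planted relevant targets with effect weight 3.0 and
a centring bias −(effect·|S_p|)/2. Half of all compound–protein pairs
are "measured" into the interaction table (emulating the partial
coverage of bioactivity databases); the rest must be imputed by stage-1
predictions when hybrid profiles are built, so the end-to-end benchmark
genuinely exercises the prediction stage.

Weight vectors are shared within a family (with per-protein biases)
because the family-level linear model on [compound ; protein] features
cannot represent protein-specific compound slopes; sharing makes stage 1
well-specified, which is the regime the benchmark is meant to probe.

What the generator does **not** emulate: real chemistry (scaffold
similarity, correlated descriptor blocks beyond an optional
equicorrelation knob, assay-type heterogeneity), panel-scale class
imbalance (real association tables are far sparser in positives), or
measurement bias in which pairs get assayed. Passing the recovery
benchmark therefore shows the machinery is correct and the procedure
recovers planted causal structure under its own assumptions — not that
it will reach the same precision/recall on real corpora.

Default problem sizes (2,000 compounds, 20-protein panel, 10 phenotypes,
10 seeds) were chosen so the full recovery experiment runs in minutes on
a single CPU while leaving each family model thousands of training
pairs.

## Numerical choices and degenerate inputs

* AUC is the Mann–Whitney rank statistic (average ranks ⇒ ties count
  1/2); the ROC curve sweeps all unique score thresholds and its
  trapezoidal area equals the rank AUC to ~1e-12. Single-class inputs
  are errors, not NaNs.
* The exact marginalization enumerates states in blocks of 2^16 and
  refuses K > 20 (≈10^6 states) with advice to use the mean-field path.
* Duplicate activity measurements resolve to the minimum micromolar
  value (most potent evidence); label-only duplicates resolve active-wins.
  Unknown units reject the row with a warning; a row with neither label
  nor value is a hard error naming its line.
* Constant descriptor columns get unit scale during standardization
  (center-only) to avoid division by zero.
* Model files are structured JSON text: diffable, portable, and floats
  round-trip exactly through repr.

## Known limitations

* The mean-field phenotype probability is biased away from 0.5 whenever
  large weights meet uncertain targets; rankings (and hence AUC) are
  affected less than calibrated probabilities.
* The selection procedure inherits CV noise: with ~0.02-wide AUC
  fluctuations, the stopping cycle can shift between seeds, and a
  genuinely relevant target whose removal costs less than 5% of the AUC
  will be dropped — with three planted targets of equal effect this
  occasionally trims recall to 2/3 for a given phenotype.
* No multiple-testing correction is applied across phenotypes, matching
  the procedure as specified.
* Per-assay-type modelling (Ki vs IC50), nonlinear models, and joint
  (non-factorized) target distributions are out of scope.
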