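# Methods

## Problem setting

The package targets early prediction of type-2 diabetes from small tabular
clinical records of the PIMA Indian Diabetes shape: eight numeric risk
factors per patient (pregnancy count, 2-h plasma glucose, diastolic blood
pressure, triceps skinfold, 2-h serum insulin, BMI, diabetes pedigree
function, age) and a binary outcome, with a roughly 65:35 class imbalance
in favour of non-diabetic patients. Two components do the work:

1. **Associative Kruskal–Wallis (AKW) feature selection** — a filter-style
   attribute ranking combining a variance/magnitude term with a rank-based
   class-separation term; and
2. **a polynomial-kernel soft-margin SVM executed under a local
   map/shuffle/reduce engine** that emulates cluster-style partitioned
   prediction without any Hadoop dependency.

## The AKW score

For each attribute column a₁ … a_N:

- **Associative value** AV = (a_N − Σᵢ aᵢ)², the squared gap between the
  column's last observation and its running total. AV is a magnitude
  (squared-units) term; it enters the ranking only through the total
  variance below.
- **Population variance** σ² = Σ (a − μ)² / N (denominator N). The
  variance is routed through the attribute's declared kind: for a
  continuous attribute Va(C) = Σ_v (v − μ)² f(v) over distinct observed
  values v with empirical frequencies f(v) (numerically equal to σ²), and
  Va(D) takes the same form for a discrete (count-valued) attribute. One
  of Va(C), Va(D) is always zero.
- **Total variance** Va(T) = Va(C) + Va(D) + AV.
- **Rank factor**: pooled midranks of all N observations are grouped by
  class; with AR_g the mean rank of class g, OR = (N+1)/2 the overall mean
  rank, the factor is

      (N − 1) · Σ_g n_g (AR_g − OR)² / Σ_j (rank_j − OR)².

  This is algebraically identical to the classical Kruskal–Wallis
  statistic with the standard tie correction (verified against an
  independent implementation to ~1e-14 relative error). A fully tied
  column has factor 0. An alternative N multiplier is available behind
  `use_n_multiplier`.

The composite score is **H = Va(T) × rank factor**; attributes are ranked
by H descending (ties broken by column order) and the lowest `n_drop`
(default 2, shrinking the PIMA table from eight attributes to six) are
discarded. H is a ranking score, not a calibrated test statistic: AV makes
it scale-dependent, which is why the pipeline normalizes attributes to
[0, 1] before selection so that no column dominates purely through its
units.

Known formula wrinkle: the AV definition admits no reading that is
simultaneously consistent with its accompanying prose; the implementation
uses the literal formula with a_N read as the column's last observation,
and documents the consequence ([100, 120, 130] → (130 − 350)² = 48400).

## Class-imbalance preprocessing

Three mutually exclusive strategies, all seeded and deterministic:

- **SMOTE-style oversampling**: each synthetic minority row is
  p + λ(q − p) for a random minority sample p, one of its k nearest
  minority neighbours q (Euclidean, k default 5), and λ ~ U(0, 1) (or a
  forced λ for reproducing a specific row). Synthetic rows therefore lie
  componentwise inside their parents' bounding box. The synthetic count is
  ceil(target_ratio × n_majority) − n_minority, making the post-balance
  ratio exact.
- **Undersampling**: a uniform seeded subsample of majority rows without
  replacement; minority rows untouched; requesting a ratio below the
  current one errors rather than inventing rows.
- **Class weighting**: w_c = N / (2 N_c), so the weighted class masses
  agree exactly. Weights enter the SVM as per-sample box bounds
  C_i = RP · w_class(i) — the standard weighted soft margin.

## The classifier and the map/reduce engine

The SVM solves the usual dual

    max  Σαᵢ − ½ Σᵢⱼ αᵢαⱼ qᵢqⱼ K(pᵢ, pⱼ)   s.t. 0 ≤ αᵢ ≤ Cᵢ, Σ αᵢqᵢ = 0

with K(a, b) = (⟨a, b⟩ + r)^d. The solver is sequential minimal
optimization with maximal-violating-pair working-set selection on a
precomputed Gram matrix: deterministic, dependency-free, and on the small
problems this package targets it reaches the dual optimum (measured
objective gaps ≤ 2e-10 against a generic SLSQP quadratic-programming
solve on random instances up to 40 points). Stopping rule: maximal KKT
violation ≤ `tol` (default 1e-3) or `max_passes × n` pair updates, after
which the model carries `converged=False` and a warning rather than
failing. The bias is the mean of −qᵢ∇ᵢ over free support vectors, or the
KKT-interval midpoint if none are free. sign(0) → +1 by convention, so
outputs are deterministic.

The engine shards **test** instances round-robin by ascending key over N
mappers; every mapper trains its own SVM **on the full training set** with
identical settings, so all mappers hold the same model and the final
predictions are invariant to the number of mappers — the engine's central
correctness property, asserted for 1–5 mappers over 50 seeded datasets.
Shuffle is a stable ascending sort by key; a single reducer resolves
duplicate keys (defensive — shards are disjoint in normal operation) by
majority vote with exact ties going to +1, and renders `key<TAB>{+1|-1}`
lines, emulating a reducer part file. Backends: `serial` (in-process) and
`process` (one OS process per mapper), contractually byte-identical.

## Tuning and metrics

Grid search over RP ∈ {1e-3, 1e-2, 1e-1, 1, 10}, d ∈ {2..5},
r ∈ {0, 0.5, 1} by stratified k-fold cross-validation (default 5 folds),
scored by mean fold accuracy — accuracy is the package's only calibrated
metric, so it is also the model-selection criterion. Ties prefer smaller
d, then smaller RP, then smaller r, making the result invariant to grid
enumeration order. Folds are fixed once per search so every triple sees
identical splits.

Metrics: accuracy A = 100·correct/total (%), computational time CT = sum
of per-patient prediction times (ms), speedup = single-node CT / cluster
CT. CT and speedup are measured wall-clock quantities — hardware-dependent
— and are reported only, never asserted against reference values.

## Pipeline and data handling

`run_pipeline` executes load → normalize → split → balance → select →
(optional tune) → classify → metrics, failing with a stage-named error.
The spec-level ordering (balance before selection before classification)
is preserved, with one deliberate placement choice: a stratified train/test
split (default 70/30, seeded) is drawn immediately after normalization and
balancing/selection see **training rows only**, so synthetic minority rows
never leak into the held-out evaluation. Normalization maps each attribute
affinely to [0, 1] (constant columns to 0) and the fitted (min, max) pairs
are reusable on new data. PIMA zero-codes (0 meaning "not measured" in
glucose, blood pressure, skinfold, insulin, BMI) are kept as-is by
default; `impute_zero_codes` median-imputes them over the nonzero entries.

## Synthetic data

The generator emulates the PIMA shape: 768 rows by default with exactly
round(n × minority_fraction) diabetic rows for every seed (default
fraction 268/768), eight attributes whose location/scale approximate the
published PIMA summary statistics (e.g. glucose ~ N(112, 30²), BMI ~
N(32, 7²), pregnancies ~ Poisson(3.4), count-valued columns rounded), and
a configurable class signal: each attribute in `signal_attributes`
(default glucose and BMI, the two attributes a clinician would expect to
separate classes) is shifted additively in the diabetic class by
effect_size × within-class s.d. (default effect 1.0; recovery experiments
use 2.0). What it does **not** emulate: attribute correlations, the
zero-code missingness pattern, skew/heteroscedasticity of the real
insulin and pedigree columns, or label noise. Passing tests therefore
demonstrate algorithmic correctness and signal recovery under clean
conditions, not clinical performance on real PIMA data.

## Numerical choices and limitations

- Midranks for ties; rank factor invariance under strictly monotone
  transforms is property-tested.
- SMO curvature floor 1e-12 for numerically flat pairs; dual feasibility
  (box + equality) holds to ~1e-12 at convergence.
- r < 0 is rejected by default (indefinite Gram risk) behind an explicit
  override flag.
- Problem sizes: partition-invariance runs use n = 200 with a 70/30
  split; solver-against-oracle checks use ≤ 40 training points, where a
  generic QP solve is exact and cheap. These sizes exercise every code
  path of the engine; the design (full Gram matrix in memory, single
  reducer) targets desk-scale data, not true big-data volumes.
- Binary outcomes only; multi-class ranking and p-value calibration of H
  are out of scope.
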