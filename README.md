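# akw-mrpk

Early diabetes prediction on PIMA-style clinical tables, in two stages:
**Associative Kruskal–Wallis (AKW) feature selection** followed by a
**polynomial-kernel soft-margin SVM executed under a local
map/shuffle/reduce engine** (MRPK). It is aimed at practitioners who want
a transparent, fully seeded reference implementation of this
filter-then-classify workflow — including its class-imbalance
preprocessing (SMOTE-style oversampling, undersampling, class weighting)
and its cross-validated hyperparameter tuning — without standing up a
Hadoop cluster.

## The method

For each attribute column a₁…a_N with mean μ, AKW scores

- AV = (a_N − Σᵢ aᵢ)²  (associative value),
- Va(C) or Va(D) = Σ_v (v − μ)² f(v)  (variance routed by the attribute's
  continuous/discrete kind, f the empirical frequency),
- Va(T) = Va(C) + Va(D) + AV,
- H = Va(T) · (N−1) Σ_g n_g(AR_g − OR)² / Σ_j (r_j − OR)²,

where the last factor is the tie-corrected Kruskal–Wallis statistic of
the attribute's midranks grouped by outcome (AR_g = mean rank of class g,
OR = (N+1)/2). Attributes are ranked by H and the lowest two dropped by
default. The classifier then solves the standard SVM dual with kernel
K(a, b) = (⟨a, b⟩ + r)^d under box bounds 0 ≤ αᵢ ≤ RP·w_class(i)
(sequential minimal optimization, maximal-violating-pair selection), and
prediction is q(p) = sign(Σᵢ qᵢαᵢ K(p, pᵢ) + b). Test instances are
sharded round-robin across N mappers, each mapper trains on the full
training set and predicts its shard, a shuffle stage sorts the
⟨key, prediction⟩ pairs, and a single reducer emits one `key<TAB>{+1|-1}`
line per patient — so predictions are provably independent of the mapper
count. See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Simulate a 768-patient PIMA-shaped cohort with a 2-s.d. diabetic shift on
glucose and BMI, then run the full pipeline (weights-balanced, degree-2
kernel, three mappers):

```sh
akw-mrpk simulate --n 768 --effect-size 2.0 --seed 7 --out cohort.csv
akw-mrpk run --data cohort.csv --balance weights --mappers 3 \
             --rp 1.0 --degree 2 --coef 1.0 --seed 7 --outdir run1
```

prints

```
selected attributes: Pregnancies, Glucose, SkinThickness, Insulin, BMI, DiabetesPedigreeFunction
dropped attributes:  BloodPressure, Age
kernel: (x.y + 1.0)^2, RP=1.0
test accuracy: 92.61% (213/230)
computational time: 47.439 ms for 230 patients
artifacts written to run1
```

Reading: of the 768 rows, a stratified 30% (230 patients) is held out;
the AKW ranking keeps six of eight attributes (the two planted signal
attributes, glucose and BMI, rank at the top); the polynomial-kernel
classifier then labels 213 of the 230 held-out patients correctly. The
per-patient predictions land in `run1/predictions.tsv` as
`row-index<TAB>{+1|-1}` lines (+1 = diabetic), alongside the selection
report, metrics and a run log; reruns with the same seed reproduce these
files byte for byte. `akw-mrpk tune` grid-searches RP ∈ {10⁻³…10},
d ∈ {2…5}, r ∈ {0, 0.5, 1} by stratified cross-validation, and
`akw-mrpk evaluate` scores a prediction file against labeled data,
optionally per batch of patients.

The library mirrors the CLI one-to-one (`generate_synthetic`,
`select_features`, `train_svm`, `run_mrpk`, `grid_search`,
`run_pipeline`, …) for use from Python.

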