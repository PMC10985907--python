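# Methods

## Scope and shape

The package implements the analysis chain as a library of estimator-style
classes (`PairedPermutationDMP`, `SignatureNMF`, `TwoStageLeastSquares`
follow the scikit-learn fit/transform idiom with trailing-underscore fitted
attributes) plus plain functions for procedures that are not
fit/transform-shaped (QC, threshold derivation, association statistics).
A thin click CLI exposes one subcommand per stage; every output is plain
TSV/JSON written with a fixed `%.10g` float format so reruns are
byte-identical.

## Probe-level model and permutation null

Each probe's beta values are fit by ordinary least squares to tissue type
(TY, tumor = 1), cancer-type dummies (CY), their interaction, and the
patient pair as a fixed blocking factor. In a matched design the patient
factor aliases CY's main effects, so the fitted design is
`[patient dummies | TY | TY:CY]`; if a tested column is itself aliased the
fit errors rather than silently dropping it. The test statistic is the
joint F for all tissue columns — the model names no single statistic that
covers a differential appearing in only one cancer type, and the joint F
does. Perfect fits (zero residual) return a large finite sentinel
(`1e12`) so permutation comparisons remain well defined.

The null swaps the tumor/normal roles of each pair independently with
probability 1/2 per round; the same relabeling is shared by all probes in a
round, which preserves inter-probe correlation and matches a matrix-level
shuffle. Each round costs one thin QR of the design plus one matrix
product against the sample × probe matrix, so 1,000 rounds on 2,000 probes
× 80 samples take a few seconds. The empirical P uses the add-one
estimator `(1 + #{perm ≥ obs}) / (1 + n_perm)`: it is never zero and its
minimum, `1/(1 + n_perm)`, is 1/1001 < 0.001 at the production setting of
1,000 rounds, so the poised cutoff P < 0.001 is attainable exactly at the
minimum.

## Delta-beta thresholds

Poised DMPs split by the sign of the per-probe median Δβ (tumor − normal
over pairs); a median of exactly 0 falls to the hypo branch and can never
be conserved. Thresholds mirror the opposite tail of each direction's
pooled per-pair Δβ values: hyper threshold = |5th percentile of the poised
hyper pool|, hypo threshold = −(95th percentile of the poised hypo pool),
with linear-interpolation quantiles. Pooling per-pair values (rather than
the median-Δβ distribution) is the implemented default because a low
percentile of strictly positive medians could never be negative, which the
mirror construction presupposes; a `threshold_pool="median"` switch exposes
the other reading. When the hyper pool's lower quantile is nonnegative
(common at low noise, where no per-pair Δβ of a true hyper probe is
negative) the rule degenerates; the absolute value is still returned with a
warning.

## Signature factorization and rank choice

NMF is implemented in-package as Lee–Seung multiplicative updates under
generalized Kullback–Leibler divergence (default) or squared Frobenius
loss, because the pipeline needs per-iteration objective traces,
best-of-n-runs semantics with named sub-seeds, and a consensus survey over
restarts; scikit-learn's `NMF` (mu solver) is used in the test suite as an
independent cross-check of the attained objective. Defaults: 30 restarts,
200 iterations, relative-change tolerance 1e-6 checked every 20
iterations. The best run is column-normalized (E columns sum to one, scale
moved into H), which leaves E·H unchanged and is idempotent.

Rank selection builds, per candidate k, a consensus matrix over restarts
(samples co-cluster when argmax activity agrees), then computes the
cophenetic correlation of the consensus distances against their
average-linkage dendrogram and the average silhouette of the k-cut.
Candidates must exceed floors of 0.95 (cophenetic) and 0.80 (silhouette).
If the cophenetic profile shows a sustained drop (> 0.05, never
recovering), the largest candidate before the drop is chosen — the
classical consensus heuristic. When no drop occurs within the surveyed
range (consensus can remain stable both below and above the true rank,
because merges and splits happen consistently across restarts), the
candidate with the highest silhouette is chosen, ties toward the smaller
rank; empirically the silhouette peaks at the planted rank in this regime.
k = 1 has no silhouette and is excluded from selection.

Projection onto fixed weights solves per-sample nonnegative least squares
(`scipy.optimize.nnls`) after intersecting probe universes; fewer than 50%
of the weight matrix's probes present is an error (configurable).

## Orientation equivalence

Factorizing beta and 1 − beta at the same rank should yield matching
activities. The mathematical condition is compositional activities: if H's
column sums are (near) constant s, then `1 − E·H = ((1/s)·11ᵀ − E)·H`
shares H exactly, and the complement weight matrix is nonnegative iff
`max(E) ≤ 1/s`. Signatures across orientations are therefore matched by
the absolute Spearman correlation of their activity rows — raw cosine of
activity rows is dominated by the shared positive offset and pairs
signatures arbitrarily — and the signed correlation is reported, since
complement-derived activities may mirror with flipped sign. The
complement-side factorization converges more slowly (the flat offset
dominates the objective), so the comparison uses a deeper iteration budget
(500) than a single factorization.

## Instrumental-variable stage

2SLS, the Wu–Hausman augmented-regression endogeneity test, and the
heteroscedasticity-robust (HC0) first-stage Wald F are written directly as
linear algebra (they are the analytical core of the stage); the
`statsmodels` sandbox IV2SLS serves as the numerical oracle in tests. With
one instrument and one exposure, the robust first-stage F is the standard
equivalent of the rank-based weak-instrument statistic. The 2SLS standard
error uses structural residuals (actual exposure, not its first-stage
fit). Cancer type enters both stages as dummy covariates, reference level
first alphabetically. BH correction is applied separately within each
p-value family across the screened genes of one signature; a determinant
gene clears all three families at FDR < 0.05.

## Clinical and immune associations

Median splits send ties to the low group and are computed within whatever
stratum the caller passes (per cancer type in the canonical use). Cox
models fit via lifelines (Breslow ties); a brute-force partial-likelihood
grid search is the oracle on a 4-subject fixture. Wilcoxon rank-sum tests
use the exact null for combined n ≤ 20 without ties and the tie-corrected
normal approximation otherwise. Meta-effects across cancer types combine
per-stratum Spearman correlations by inverse-variance weights (n − 3) on
the Fisher-z scale; a single usable stratum is returned as-is and flagged.
Variance attribution is the one-way between/total sum-of-squares ratio.
The ICI response model is logistic (IRLS) reporting odds ratios, with a
linear-probability option for parity with the Gaussian-error formulation;
constant predictors are dropped with a warning.

The GES (gene-expression surrogate) ranks genes by |Spearman| with
activity on a training split (default two thirds of cells), keeps the top
n (the selection size, e.g. 156, is a parameter), and scores a cell as the
mean z-scored expression over positively correlated genes minus the mean
over negatively correlated ones; the held-out AUC against the median
split of activity is reported. The exact published construction is not
specified in the accessible text; this scheme is the package's declared
surrogate, and z-scoring makes the score invariant to per-gene affine
rescaling (asserted in tests).

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes; it
is not calibrated to any real cohort.

- **Paired cohort** (defaults: 40 pairs, 2,000 probes, 3 cancer types):
  per-probe baseline means U(0.05, 0.95) shared by tumor and normal; 5%
  hyper (Δβ = +0.3) and 5% hypo (−0.3) planted probes shift the tumor
  mean, clipped to (0.01, 0.99). Observations are Beta(μc, (1 − μ)c) with
  concentration c = 100 (sd ≈ 0.03–0.05 mid-range) — the natural
  heteroscedastic family on [0, 1]; c = ∞ emits the means exactly. A small
  additive cancer-type offset (sd 0.02, shared within pair) exercises the
  CY covariate without inducing a tissue effect. Purity is drawn in
  (0.601, 1] so QC passes; a contamination mode mixes tumor toward normal
  by 1 − purity to test the filter.
- **Signature cohort**: E is dense with signature-specific enriched probe
  blocks (2–3× boost over a gamma baseline), column-normalized; H is
  nonnegative with a dominant signature per sample (round robin, cancer
  type derived from it so signatures are cancer-type enriched) and
  near-constant column sums (2% jitter) — the conserved-methylation-budget
  regime in which orientation equivalence holds. V = clip(E·H + N(0,
  0.02), 0, 1) scaled to peak at 0.9.
- **Causal chain**: per determinant gene, mutation ~ Bernoulli(0.15–0.3),
  expression = 1 + a1·mutation + u + noise, designated activity =
  causal_beta·expression (+ u + noise) with shared confounder u ~ N(0, 1):
  expression is endogenous, mutation a valid instrument. Genes with < 2
  mutants after one resample are flagged unusable.
- **Outcomes**: exponential survival with rate λ0·exp(log HR · standardized
  activity) and independent exponential censoring tuned to the target
  censored fraction; age/stage/immune features at Gaussian-copula Spearman
  level 0.4 to activity; ICI response Bernoulli(logistic(c0 + c1·z +
  c2·TP53 + c3·FOXA1)).

One integer seed drives a named sub-stream per operation
(`SeedSequence(seed, spawn_key=(stage,))`), so stages are individually
reproducible and insensitive to each other.

What passing tests on these cohorts do **not** show: behavior under probe
cross-reactivity, batch effects, cell-type composition shifts, non-beta
noise, copy-number contamination, or cohort sizes and effect spectra of
real consortium data.

## Problem sizes and tolerances

The test and acceptance workloads are sized for a single CPU: calibration
and recovery at 2,000 probes × 40 pairs × 1,000 permutations; rank/weight
recovery at 1,500 × 300 (k = 4, 30 restarts) in the test suite and
800 × 200 (15 restarts) in the acceptance script; orientation at 600 × 200;
IV at n = 1,000 per replicate. Numerical tolerances: NNLS recovery 1e-6 on
consistent systems, quantile oracle 1e-12, Cox grid oracle 1e-3 on the
coefficient, BH oracle 1e-12.

## Known limitations

- No region-level (DMR) calling, cell-type deconvolution, IDAT parsing,
  batch correction, motif enrichment, or pathway analysis.
- Single-instrument 2SLS only; no LIML/GMM, no multi-SNP designs.
- The probe model assumes one normal per patient; multi-normal designs are
  not supported.
- Rank selection is heuristic; on data whose consensus never destabilizes
  the silhouette-peak fallback decides, and very flat silhouette profiles
  resolve to the smallest stable rank.
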