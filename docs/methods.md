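# Methods

## Problem setting

Each sample is measured on two platforms — a gene-expression profile (GEP)
and a DNA-methylation profile (DMP) — and annotated with a binary membership
vector over molecular subtypes. Memberships overlap: a sample positive for
one abnormality may also carry others, so classification is multi-label and
is decomposed into independent one-vs-all tasks (positives = samples carrying
the subtype, negatives = everything else). The scientific question is whether
combining the platforms improves subtype prediction, and if so, whether the
combination is better done in feature space (early) or in decision space
(late).

## Penalized logistic core

For a task with response y ∈ {0,1}ᵐ and standardized design X, the model
minimizes

    f(β₀, β) = (1/m) Σᵢ [log(1 + exp(ηᵢ)) − yᵢ ηᵢ] + λ‖β‖₁,   η = β₀ + Xβ

with an unpenalized intercept.

**Standardization.** Each feature is centered and scaled to *unit second
central moment*: scale = sqrt(mean squared deviation) with denominator m, not
m − 1. This puts every feature on the same penalty scale. Constant columns
get scale 1 and are flagged; their transformed values are identically zero so
they can never be selected. Standardization parameters are always estimated
on the training portion of a split only and applied unchanged to held-out
samples — validation data never influence the transform.

**Solver.** Outer iteratively-reweighted least squares around cyclic
coordinate descent with soft-thresholding on the weighted quadratic
approximation (probabilities clipped to [1e−5, 1−1e−5] for the weights).
Three safeguards make the solver exact and robust:

* a *full* Karush–Kuhn–Tucker sweep over all p features before each outer
  iteration pulls violating coordinates into the active set, so active-set /
  strong-rule screening can never change the solution;
* a backtracking step on the true composite objective after each inner solve
  guarantees a monotone objective trace (plain IRLS does not);
* convergence requires both max |Δβ| < tol and a clean KKT check.

Defaults: tol 1e−7 on the maximum coefficient change, at most 1e5 coordinate
sweeps; on exhausting the budget the current iterate is returned with a
warning and a `converged=False` flag. On random small instances the solution
matches an L-BFGS-B oracle on the split formulation (β = β⁺ − β⁻, box
constraints) to ~1e−16 in objective; the test suite asserts 1e−5. The inner
coordinate loop is JIT-compiled (numba) with a semantically identical numpy
fallback.

**Regularization path.** λ_max = max_j |Xⱼᵀ(y − ȳ)|/m is the smallest penalty
whose solution is the all-zero vector; the grid is 50 log-spaced values from
λ_max down to λ_max·1e−3 (both configurable), fitted warm-started with
sequential strong-rule screening. λ is selected by k-fold inner
cross-validation on pooled per-sample binomial deviance; ties break toward
the larger (sparser) λ, implemented by ordering the grid decreasing and
taking the first minimizer. The selection criterion, grid shape and solver
were design choices here — they are standard practice but not forced by the
problem. Inner folds whose removal would leave a single-class training set
are merged into a neighbor (with a warning) while more than two folds remain;
a fold that still cannot be used is skipped and contributes no deviance.
Within each inner split, standardization is refit on the held-in portion.

## Double-loop cross-validation

The outer loop splits the n samples into five (near-)equal subsets at random
— **one** assignment shared by every task and every strategy, so that
strategy comparisons are paired on identical validation sets. Outer folds are
not stratified: simultaneous stratification on 15 overlapping labels is
impossible, and tasks that end up with fewer than two training positives in
some outer iteration are skipped for that fold and flagged in the report.
Inner folds are stratified on the task response (positives dealt round-robin,
so fewer positives than folds are never co-located; negatives fill folds to
balanced sizes). Inner-fold seeds derive deterministically from
(master seed, outer fold index, task index) via `numpy.random.SeedSequence`,
giving independent streams and bit-reproducible runs.

Within one outer iteration: per-platform paths are fitted on the four
training subsets, λ chosen by the inner loop, and the selected-λ model from
the full-training-data path is the platform model (this is the "refit at the
selected penalty"). Validation samples are never touched during
standardization, λ selection, or second-layer training; the test suite
asserts byte-identical serialized models when the validation rows are
physically removed before training.

## Integration strategies

* **gep / dmp** — the platform model alone; posterior ≥ 0.5 calls a positive.
* **early** — column-wise concatenation (GEP first, feature ids prefixed by
  platform tag to keep the id space collision-free), standardization refit on
  the concatenated training matrix so all 2p columns carry equal weight, then
  one lasso path on the combined space. Selected features are counted per
  origin tag.
* **late** — the two platform models' posteriors form points
  (p_GEP, p_DMP) ∈ [0,1]²; a nearest-mean classifier (unweighted class means,
  decision boundary = perpendicular bisector) is trained on the
  outer-training samples' posteriors and scores validation points by
  ‖x − μ₋‖² − ‖x − μ₊‖², an affine function of x, so ROC analysis on the
  score equals ROC on signed boundary distance. Ties on the boundary go to
  the positive class, mirroring the ≥ 0.5 posterior rule.

Two genuinely open design points, resolved as follows: the NMC is trained by
default on *in-sample* posteriors of the refit first-layer models (the
two-layer flow reads most naturally this way); an `out_of_fold` option
computes per-inner-fold refit posteriors instead, which is less optimistic.
And the NMC uses plain unweighted class means despite class imbalance — the
textbook nearest-mean definition; a prior-weighted variant is out of scope.
Under a common fold assignment the late strategy's first-layer models are
identical to the single-platform models, and the implementation shares them.

## Evaluation

* **F-score** at the fixed 0.5 posterior threshold (the NMC's learned
  boundary for late), F = 2PR/(P+R), defined as 0 whenever P + R = 0. A
  posterior of exactly 0.5 is a positive call.
* **AUC** in the Mann–Whitney form P(s⁺ > s⁻) + ½P(s⁺ = s⁻); single-class
  validation folds are flagged and excluded from the AUC mean only.
* **Global test**: Q = (y − ȳ)ᵀXXᵀ(y − ȳ)/p on column-standardized features —
  the score statistic for the null that the variance of all regression
  coefficients is zero. The p-value is by label permutation (default 10⁴)
  with the add-one correction, so its floor is 1/(B+1); this was preferred to
  the asymptotic mixture-of-χ² form because it is exact under exchangeability
  and simple to verify. Per subtype and strategy the test is applied to the
  features the strategy selects on the *full* sample set (inner-CV λ on all
  samples; for late, the union of the two platform selections), against the
  task labels. Raw p-values are reported with no multiplicity correction.
* **Aggregation**: arithmetic means over the valid outer folds, with skipped
  folds flagged and excluded; serialized per-fold detail allows exact
  recomputation of every mean. Cross-subtype Pearson correlations summarize
  platform balance: per strategy, the GEP-side vs DMP-side selected-feature
  counts across subtypes, and per strategy pair, the GEP-count proportion
  profiles.

## Synthetic data

The generator emulates the *structure* the pipeline assumes, not any real
cohort: i.i.d. Gaussian background N(0, noise_sd²) on both platforms and an
additive mean shift (in background-SD units) on disjoint planted feature
sets per subtype. Placement modes: `gep_only`, `dmp_only`, `redundant` (same
positives shifted on both platforms) and `split` (positives partitioned
~50/50, each carrying signal on exactly one platform — the regime where a
decision-space combination can beat both platforms and their concatenation
in principle). Labels are independent Bernoulli draws at the stated
prevalences; an optional overlap matrix is interpreted as a Gaussian-copula
latent correlation matrix thresholded at the prevalence quantiles. All draws
flow from one seed through a documented four-way `SeedSequence` split
(labels, GEP background, DMP background, signal placement).

Defaults mirror the motivating study at reduced scale: 200 samples,
2000 + 2000 features, 6 subtypes spanning all modes plus a signal-free null
subtype. Effect sizes are free parameters of the generator, not estimates of
any real cohort — the source study reports no per-subtype effect-size
characterization. Feasibility is validated against the default 5-fold outer
protocol: expected positives (and negatives) must reach 2 × 5 = 10, since the
generator cannot know the fold count the downstream run will use.

What the generator does **not** emulate: platform-specific preprocessing
(RMA-style normalization, methylation-assay quantile behavior), feature
correlation structure, batch effects, missing values, or bimodal methylation
distributions. Passing tests therefore demonstrate correctness of the
machinery and the qualitative integration phenomena under the assumed linear
additive model — not performance claims about real cohorts.

## Problem sizes and numerical choices

Experiment batteries (`omicstack.experiments`, used by the tests and the
acceptance script) run at 200 samples and 500 features per platform for the
strategy comparisons, 1000 features for recovery, and 60 × 40 for the
null-calibration datasets with 400 permutations each — sizes chosen so the
full battery completes on a single CPU in minutes while staying in the
p ≫ n regime that motivates the lasso. The split-signal synergy experiment
uses the spec of its planted subtype (prevalence 0.25, 30 features per
platform, 2.5 SD effect) and counts how often the late strategy's mean
validation AUC beats the better single platform across 10 seeded repeats;
the redundant-signal control checks the paired per-fold AUC difference
between late and the better single platform stays within noise
(|mean| ≤ max(3·SE, 0.01)).

Degenerate inputs are handled explicitly: single-class responses raise with
the task/fold named; empty feature selections make the global test degenerate
to Q = 0, p = 1; all-zero label columns are skipped as tasks with a warning.
Floats are serialized with shortest round-trip representation, so every
artifact (reports, fold files, model JSON) is byte-stable under reruns —
run logs carry timestamps and are excluded from that guarantee.

## Known limitations

* Two platforms only; no kernel/intermediate integration or learned fusion
  weights.
* The lasso grid's lower terminus λ_max·10⁻³ can sit in a near-separable
  regime on strong-signal tasks, where the solver may hit its sweep budget
  and return a flagged iterate; the selected λ in practice sits well above
  the terminus.
* The global test's feature-selection step reuses the full sample set, so its
  p-values describe association of the selected signature, not an unbiased
  test of a pre-registered feature set.
* Outer folds are unstratified; very rare subtypes can lose folds to the
  <2-positives rule, and their means then average fewer than five folds.
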