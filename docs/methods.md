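# Methods

## Problem and model

`bdaselect` implements wrapper feature selection for binary classification
on tabular questionnaire-style data (bounded integer scale scores plus
encoded demographics). The motivating application is identifying which
psychological instruments separate clinical groups — adolescents with a
mood disorder from typically developing peers, and, among the clinical
group, those with non-suicidal self-injury (NSSI) from those without.

The base classifier is the soft-margin SVM with labels y_i ∈ {−1, +1}:

    min_{w,b}  ||w||²/2 + C · Σ_i max(0, 1 − y_i (wᵀx_i + b))

A candidate feature subset S ⊆ O (the universe of |O| candidate features)
is scored by

    O(S, data) = [ (1/K) Σ_k Err(S, data_k) ] · exp(sign · |S|/|O|)

where Err(S, data_k) is the SVM error on the k-th of K stratified
cross-validation folds using only the features in S. With `sign = +1`
(the default) the exponential factor penalizes larger subsets, matching
the design goal of selecting as few features as possible. The source
formulation prints the factor with a negative sign, which *rewards* larger
subsets; that literal form is available via `penalty_sign = -1` and every
report records which was used. An empty subset is valued +∞ so the
optimizer can never prefer it.

## Binary dragonfly search

The subset optimizer is a binary dragonfly algorithm: each swarm member
carries a 0/1 mask over O. Per iteration, a real-valued step vector is
assembled from five behaviours — separation, alignment, cohesion,
attraction toward the best-ever mask ("food") and the current best member
("leader"), and distraction involving the worst-ever mask ("enemy") and
the current worst member — weighted by α₁..α₅ (defaults all 0.2). Each bit
then flips independently with probability TF(Δx) = |Δx|/√(Δx²+1).

Fidelity choices, all configuration-exposed and echoed into reports:

* **Cohesion / distraction conventions.** The source prints
  C = (1/M) Σ (X − X_j) and E = ½[(X_pw + X) + (X_f − X_e)], whose signs
  differ from the original dragonfly algorithm. Both are implemented; the
  printed forms are the default (`cohesion_convention` /
  `distraction_convention` = `"printed"`, `"standard"` selects the
  conventional signs). Neither is silently "corrected".
* **Personal/group learning rates.** The reference settings name a
  personal learning rate of 0.4 and a group learning rate of 0.7 that do
  not appear in the printed update equation. They are applied as
  multipliers on the leader and food components of the attraction term
  (the most direct reading) and can be disabled with
  `use_learning_rates=False`.
* **Neighbourhood.** The whole swarm (10 members by default); the source
  never defines a neighbourhood radius, and whole-swarm neighbourhoods are
  the standard simplification at this swarm size.
* **Leader/laggard.** "Closest to the food/enemy" is measured in objective
  value (current best / worst member), consistent with food and enemy
  themselves being objective extremes.
* **Initialization and stopping.** Bits start i.i.d. Bernoulli(0.5), steps
  at zero. The loop runs up to `max_iter` (default 150) iterations and
  stops early when the best objective reaches `objective_threshold`
  (default 0, i.e. effectively disabled, since no threshold value is
  specified by the source).
* **Tie-breaking.** Equal-objective masks prefer fewer selected features,
  then the lexicographically smallest mask, making reports deterministic.

### Known limitation: diversity collapse

The printed update has no inertia term and fixed behaviour weights. Once
the swarm collapses onto the food position, a bit that is 0 in the food,
the enemy, and every member can never switch on (its step component, hence
its flip probability, is exactly zero). On benign objectives — bit-count,
hidden-target Hamming distance, classifier-error landscapes with multiple
good subsets — best-of-a-few-seeds search still matches exhaustive
enumeration essentially always (see the oracle-equivalence tests). On
adversarial separable objectives with a unique optimum (random linear
weights per bit), the single-run hit rate drops to roughly half: restarts,
not within-run exploration, are the method's effective diversity
mechanism. This is a property of the published update rule, preserved
deliberately.

## Ensemble selection

The outer loop draws `m` stratified bootstrap replicates (default 100;
sampling with replacement within each class keeps class counts exact and
protects small minority groups), runs one full swarm search per replicate,
and scores each replicate's best mask S̄_m by fresh K-fold CV accuracy
Sc_m on the replicate's own sub-dataset. Scoring on the in-bag data
follows the stated procedure and is optimistically biased; an out-of-bag
scoring variant (`oob_accuracy=True`) is provided. Votes are
SV = Σ_m Sc_m · S̄_m, and the final selection keeps the M top-voted
features with M = round(mean_m |S̄_m|) (round-half-away-from-zero, so a
mean of 7.17 selects 7; floor/ceil available). Boundary vote ties go to
the smaller feature index.

One master generator expands the run seed into named sub-seeds (bootstrap
draw; per replicate: swarm init, objective CV folds, scoring CV folds), so
identical configurations produce byte-identical reports and each stage is
independently reproducible. Objective evaluations are memoized per mask
within a replicate; the CV-fold seed is fixed per replicate, so caching is
exact. Whether scoring reuses the objective's folds is unspecified in the
source; fresh folds from a derived seed are drawn and recorded.

## Cross-validation protocol

Stratified K folds (default K = 10), shuffled deterministically by seed.
K is capped at the minority-class count (with a warning) so every training
split contains both classes. Selected features are z-scored per fold with
statistics fit on the training fold only — SVMs are scale-sensitive and
the source does not state a scaling protocol. The default kernel is RBF
with bandwidth 1/(p · Var(X)) over the p selected features
(scikit-learn's `gamma='scale'`, ≈ 1/p after standardization); a linear
kernel is available. Both choices are recorded in run records because the
source names neither.

## Univariate statistics

Categorical demographics: Pearson chi-square on the groups × categories
contingency table, no continuity correction — the published
mother-education statistic (3.206, p 0.524) matches the uncorrected
Pearson value computed from its printed counts, which fixes the
convention. Scale scores: Kruskal-Wallis with midranks and tie
correction (all-tied input returns H = 0, p = 1 rather than dividing by
zero), followed by Dunn's pairwise z tests on pooled mean ranks with Holm
adjustment (Bonferroni by flag); direction is reported from the mean-rank
ordering and pairs with adjusted p ≥ α are flagged non-significant.

Several published demographic statistics (gender 9.936, ethnicity 10.316,
father-education 1.111) are inconsistent with Pearson chi-square on their
own printed counts (recomputation gives ≈7.94, ≈9.56, ≈0.96); the printed
counts are kept verbatim in the fixtures and those statistics are not
asserted. The published TD education column sums to 97 against a stated
group size of 96; the fixture keeps the printed counts.

## Synthetic cohorts

The generator emulates only the *shape* of the study data: three groups
(default sizes 137/49/96), ~25 bounded integer scales patterned on the
instruments (anxiety 0–21, depression 0–27, five personality-disorder
subscales, five childhood-trauma subscales, six emotion-regulation
subscales plus total, simple demographics). A single latent severity
factor with per-feature loadings induces inter-scale correlation; each
scale is a clipped, rounded affine map of (loading·latent + noise) into
its integer range; informative features carry per-group mean shifts
expressed in feature SDs, so a declared shift of 1.0 is a standardized
effect size of ≈1.0 (rounding and ±3σ clipping attenuate this by only a
few percent at the default range widths). Default shift magnitudes for
the study-shaped cohort are plausible clinical-vs-TD standardized
differences (largest for depression/anxiety/borderline traits, null for
sexual abuse and ethnicity), declared once in
`default_cohort_spec`.

What the generator does **not** model: item-level psychometrics, floor and
ceiling pile-ups, informative missingness, the study's real covariance
structure, or demographic confounding. Passing recovery tests therefore
demonstrates that the pipeline finds planted mean-shift signal in
correlated integer data — not that it would reproduce the study's selected
features on the real cohort.

## Problem sizes used in tests and the acceptance script

The reference defaults (swarm 10, 150 iterations, 100 replicates) are what
a real analysis would run and take hours on one core: each objective
evaluation is a 10-fold SVM cross-validation (~tens of milliseconds).
Automated checks therefore use deliberately reduced sizes, chosen once:

* Oracle equivalence runs at full settings (150 iterations, swarm 10,
  best of 5 seeds, 20 trials) because its objective — nearest-centroid
  training error × exp(|S|/|O|) on a synthetic 8-feature table — is cheap
  and exhaustively enumerable (255 masks).
* The planted-recovery experiment keeps the cohort and ensemble at full
  size (n=300, 25 features, 5 informative at 1.0 SD, m=20 replicates,
  median over 20 generator seeds; the acceptance script uses 5 seeds) but
  shortens each replicate's swarm search to 6 iterations: recovery is
  driven by the accuracy-weighted vote across replicates, which separates
  consistently-selected informative features from sporadically-selected
  noise long before each individual search converges.
* Smaller property tests (determinism, effect-size monotonicity,
  out-of-bag scoring) use cohorts of 60–100 subjects, 6–8 features, and
  2–5 replicates.

## Numerical choices and degenerate inputs

* Constant feature columns pass through scaling untouched (SD treated
  as 1) and are retained with a warning at load time — no published
  filtering rule exists.
* Rows with any missing value are rejected at load (and counted); silent
  imputation would change the method.
* Ordered categoricals are integer-encoded by declared rank, unordered
  binaries as 0/1; the encoding is recorded with the table.
* Accuracies, votes, and objective values are plain float64; vote
  conservation Σ_i SV_i = Σ_m Sc_m|S̄_m| holds to machine precision.
* Sub-seeds drawn from the master generator stay below 2³¹.
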