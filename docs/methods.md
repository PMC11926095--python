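# Methods

## The mixed-membership block model

Observed data are links (u, t, s) of a bipartite graph: student *u* scored
quintile *s* ∈ {1,…,5} on task *t*. The model posits K student groups and L
task groups; student memberships θ (U×K), task memberships η (T×L) and the
score tensor p (K×L×5) are row-stochastic, and the link law is the mixture
Pr[s_ut = s] = Σ_{k,l} θ_uk η_tl p_kl(s). Maximum-likelihood estimation uses
EM: the E-step computes per-link responsibilities ω_ut(k,l) ∝ θ_uk η_tl
p_kl(s_ut); the M-step sets θ_uk to the responsibility mass of user *u* in
group *k* divided by the user's degree d_u, symmetrically for η, and
p_kl(s) to the share of (k,l)-responsibility carried by links with score
*s*. These are the stationary points of the Lagrangian with simplex
constraints, and make the log-likelihood non-decreasing — the fitter
asserts this per iteration (tolerance 1e-9).

Numerical choices:

- **Initialization** draws every row uniform on [0.1, 1] before
  normalization. Strict positivity matters: a zero entry is absorbing under
  the multiplicative updates.
- **Convergence** is declared when the maximum absolute parameter change
  falls below `tol` (default 1e-6), capped at `max_iter` = 500; the default
  run uses 10 random restarts and keeps the highest final log-likelihood.
  No convergence threshold is canonical for this model; the defaults were
  chosen so that doubling `max_iter` does not change the recovered
  parameters at the reported precision.
- **Degenerate rows.** Users or tasks with zero links in a (sparse holdout)
  training set receive uniform memberships, and (k,l) cells with zero total
  responsibility a uniform score law, each with a warning — fitting never
  aborts on sparse splits.
- **Label identifiability.** The likelihood is invariant to relabeling
  groups. `align_labels` resolves it against a reference by minimizing the
  L1 distance between score tensors (exhaustive over permutation pairs for
  K, L ≤ 5). After fitting, user groups are additionally permuted into a
  canonical achievement order — column 0 = highest expected quintile,
  column 1 = lowest, column 2 = intermediate — which is the convention the
  profile/status analyses rely on.
- **Prediction** reports the full score distribution and the modal score;
  ties in the argmax break toward the lower quintile (deterministic and
  documented; ties are measure-zero except for hand-built tensors).

## Evaluation protocol

Holdout experiments hide 40/60/80% of links uniformly at random (20 splits
per fraction by default). Train and test tables share the full id universe,
so students stranded without training links fall under the degenerate-row
rule rather than crashing prediction. Reported metrics: exact accuracy and
one-off accuracy (within one quintile). The comparison baseline predicts
each task's most frequent training score (ties toward the lower score,
global mode for unseen tasks).

Model dimensions are selected by exhaustive grid search over (K, L) with
mean exact accuracy on 40%-holdout splits as the criterion and a
one-standard-error parsimony rule: among grid points within one SE of the
grid maximum, the smallest K+L wins (ties toward smaller K, then L). The
selection default uses 5 splits and 2 restarts per grid point — enough for
the SE rule to separate the plateau from the under-fitted models while
keeping a 25-point grid tractable.

The discrepancy profile counts, per student, the observed tasks where the
model's modal prediction misses by at least 2 quintiles (the threshold is a
parameter; no canonical definition exists, so it is exposed and documented
rather than hard-coded).

## Sociogram statistics and their nulls

Nominations are directed (nominator → nominee) and analyzed as such; edge
overlap between two layers of one classroom is the Jaccard index over
directed edge pairs, defined as 0 when both layers are empty. Its null
rewires both layers independently by directed double-edge swaps (10·|E|
attempted swaps), which preserves every node's in- and out-degree exactly —
the null therefore measures the overlap that degrees alone produce. Layers
admitting no feasible swap are returned unchanged with a warning.

Gender homophily is the fraction of same-gender edges; edges touching a
student with undisclosed gender ("no-answer"/"other") are excluded from
numerator and denominator since same-gender is undefined for them. The null
shuffles gender labels within the classroom.

Cognitive assortativity of a layer is log(d_connected / d_all), where
d_connected averages the profile distance over edges and d_all over all
unordered within-class pairs (connected pairs included). The distance is
Euclidean on the membership simplex by default (L1 and cosine are exposed;
nothing in the analysis depends on the choice beyond monotone rescaling of
typical distances). Negative values mean connected students are more
similar than chance. The null permutes profile vectors among the
classroom's students, leaving edges — and hence d_all — untouched.
Degenerate cases are flagged, never silently dropped: an all-identical
classroom yields NaN; a layer whose every edge joins profile-identical
students yields −inf; per-age aggregation excludes non-finite values and
reports the exclusion count.

Social status is PageRank (damping 0.85, the standard default, exposed as a
parameter) on the nomination graph with all roster students included;
receiving nominations raises status and isolates hold teleport mass only.
The status statistic is the Spearman correlation between PageRank and the
membership to the high (or low) achievement group, computed per classroom
and then averaged within age; its null permutes membership vectors among
students.

Hypothesis tests follow the nonparametric route throughout: Shapiro–Wilk at
α = 0.05 as the gate (the pipeline's dependent variables are not normal),
two-sided Mann–Whitney U with exact small-sample p-values, Spearman for
continuous predictors, and the Hodges–Lehmann estimator (median of all
pairwise differences) with the classical distribution-free CI from the
order statistics of the pairwise-difference set at the Mann–Whitney 95%
critical rank. No multiple-testing correction is applied; every p-value is
per-comparison.

## The synthetic-data generator

The generator emulates the statistical structure of a multi-school study:
classrooms of 20–30 students, ages 6–15, ~10 tasks scored in quintiles, and
five nomination layers per classroom with an out-degree cap of 3.

**Cognitive side.** The planted membership pattern mirrors the empirical
one: students are either (almost) purely low-achieving, or mix low with
average achievement, or high with average, with the mixing weight uniform;
high and low are never mixed. Tasks are 0.95-dominated by one of three task
groups. Score laws are discretized Gaussians on the quintile scale with
group centers 4.6 (high), 1.4 (low), 3.0 (average), task-group shifts of
±0.4, and SD 0.30 — each group's scores concentrate on a couple of adjacent
quintiles, i.e. clearly separated achievement groups. The concentration is
a deliberate identifiability choice: with only ~10 ordinal observations per
student, recovering an edge student's mixing weight to ±0.07 (mean θ row L1
≈ 0.14) is only possible when the score laws are close to fully
discriminative; diffuse laws put the target beyond the information limit
regardless of estimator.

**Social side.** Each student draws 1–3 distinct nominees (uniform count;
"up to three" fixes only the cap) without replacement with weight
∝ exp(−λ·d_cog(u,v) + γ·1[same gender] + β·θ_v,high). The exponential link
is the simplest monotone map from planted coefficients to the estimands the
pipeline measures. Negative layers flip the sign of λ (rejection targets
dissimilar profiles). Cross-layer edge overlap between work and play layers
of the same sign is planted by copying each work nomination into the play
layer with a configurable probability before the play layer fills the rest
of its budget; the default age series decreases this probability with age
(0.6 → 0.2 for positive layers, flat 0.3 for negative ones), makes gender
homophily weaken at age 12, and raises the work-layer preference for high
achievers with age.

**Reference effect sizes.** Planted effects are calibrated on the estimand
scale, because the softmax coefficient itself has no natural units: λ = 2
induces a work-layer assortativity log-ratio ≈ −0.7 and β = 4 a status
Spearman ≈ 0.6. With 25-student classrooms the 2-null-sd detection
threshold for a Spearman correlation is ≈ 0.4, so a planted status effect
detectable in ≥90% of classrooms is necessarily of this magnitude.

**What the generator does not emulate.** Psychometric task content and
timing, longitudinal within-child dynamics, school-level clustering beyond
the classroom, and any feedback from network position to achievement.
Passing recovery and calibration tests therefore shows the estimators are
correct and well-calibrated under the planted mechanism — not that the
mechanism is the one generating real classroom data.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run the recovery analysis at 500
students × 10 tasks (full coverage, 5 restarts), prediction at 300 students
× 20 splits, selection over the full 1..5 × 1..5 grid, and the
calibration/power analyses over 200/100 simulated classrooms with 200
permutation draws per null — sizes at which every Monte-Carlo tolerance in
the tests is several times its standard error. Every stochastic stage
derives its stream from the single top-level seed plus a stage tag
(SHA-256 of the tag tuple), so whole runs are bit-reproducible while stages
remain statistically independent.

## Known limitations

- The EM fitter finds local optima; restarts mitigate but do not guarantee
  the global maximum. The recovery tests measure the whole procedure,
  restarts included.
- The degree-preserving rewiring null conditions on the empirical degree
  sequences; for very small or very dense layers few swaps are feasible and
  the null concentrates near the observed graph (flagged, not hidden).
- The Hodges–Lehmann CI uses the normal approximation to the critical rank;
  for very small samples it falls back to the full range of pairwise
  differences.
- Students tested twice (separate waves) are treated as distinct user
  records; the model sees no within-child coupling across waves.
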