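# cogsoc

Mixed-membership block models of children's cognitive profiles, and the
statistics linking those profiles to multilayer classroom sociograms.

## What this package is for

Studies that collect both cognitive testing data and peer-nomination
("sociogram") data from the same school children face two coupled analysis
problems:

1. **Cognitive profiles.** Each child completes a battery of tasks scored as
   achievement quintiles 1–5. Treating the scores as links of a bipartite
   student×task graph, a *mixed-membership stochastic block model* (MMSBM)
   assumes K latent groups of students and L latent groups of tasks, with

   Pr[s_ut = s] = Σ_{k,l} θ_uk · η_tl · p_kl(s),

   where θ_u is student *u*'s membership simplex vector (their cognitive
   profile), η_t the task's membership vector, and p_kl(·) a categorical
   score law per group pair. Parameters are estimated by
   expectation-maximization with random restarts; missing scores are
   predicted from the fitted law.

2. **Sociogram structure and its link to achievement.** Each child names up
   to three classmates per question (work with / not work with / play with /
   not play with / friends), giving five directed nomination layers per
   classroom. The package computes:
   - Jaccard edge overlap between layers against a degree-preserving
     rewiring null,
   - same-gender edge fractions against a gender-shuffling null,
   - cognitive-distance assortativity log(d_connected/d_all) against a
     profile-shuffling null (negative = assortative),
   - Spearman correlations between PageRank social status and membership to
     the high/low achievement groups against a membership-shuffling null,
   all aggregated per school age.

Because classroom-level school data cannot be redistributed, the
`cogsoc.synthetic` module generates populations with planted ground truth
(three achievement groups, tunable homophily / gender mixing / preference
for high achievers) so the whole pipeline is testable and reproducible.

## Worked example

```python
from cogsoc import MixedMembershipSBM, synthetic
from cogsoc.evaluation import make_holdout_splits, exact_accuracy

pop = synthetic.make_planted_params(500, 10, seed=2)   # planted 3x3 truth
ratings = synthetic.sample_ratings(pop, coverage=1.0, seed=2)

split = make_holdout_splits(ratings, hide_fraction=0.4, n_splits=1, seed=0)[0]
model = MixedMembershipSBM(n_user_groups=3, n_task_groups=3,
                           n_restarts=5, random_state=2).fit(split.train)
print(f"log-likelihood {model.result_.loglik:.1f}")
print(f"exact accuracy {exact_accuracy(model.predict(split.test), split.test.s):.3f}")
print(model.profiles().head(3).round(3))
```

prints

```
log-likelihood -1892.1
exact accuracy 0.681
         group_0  group_1  group_2
user_id
s00000     0.624      0.0    0.376
s00001     0.000      0.0    1.000
s00002     0.000      1.0    0.000
```

`group_0` is the high-achievement group, `group_1` the low, `group_2` the
average (columns are ordered by expected score after fitting): student
`s00000` mixes high and average achievement, `s00001` is purely average,
`s00002` purely low — and no student mixes high with low. About two thirds
of predicted quintiles on the 40% held-out links are exactly right, versus
~0.45 for a per-task-mode baseline.

The same pipeline is available from the shell:

```bash
cogsoc simulate --seed 1 --out-dir runs/sim
cogsoc fit --ratings runs/sim/ratings.csv --seed 1 --out-dir runs/fit
cogsoc overlap --edges runs/sim/edges.csv --roster runs/sim/roster.csv
cogsoc status --edges runs/sim/edges.csv --roster runs/sim/roster.csv \
              --model runs/fit/model.json
```

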