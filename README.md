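# sretddm

Hierarchical drift-diffusion and mixed-logistic analysis of the
self-referential encoding task (SRET) under light manipulations.

## What this is for

In the SRET, people answer yes/no whether positive ("good") and negative
("terrible") adjectives describe them; endorsement of negative words and
rejection of positive ones track depressive self-schemata. A within-subject
light study administers the task twice — once under blue-enriched, once
under blue-depleted light of matched visual brightness — to ask whether
melanopsin-driven photoreception changes how easily people reject negative
self-descriptors. This package implements that study's full analysis chain
for researchers who want to run, check or extend it:

- a **Wiener diffusion core**: exact first-passage densities via the
  small-/large-time series expansions, the closed-form absorption
  probability, and Euler–Maruyama path simulation;
- a **synthetic-data generator** reproducing the design (33 participants,
  2 counterbalanced sessions, 26+26 adjectives × 3 blocks = 156 trials per
  session) from a hierarchical diffusion truth or a logistic
  random-intercept truth, so the whole pipeline is testable without the
  undeposited study data;
- **hierarchical Bayesian estimation** of the model family
  `parameter ~ 0 + C(condition):C(stimulus)` — variants letting drift `v`,
  start point `z` and/or non-decision time `t` vary over the four
  condition × valence cells (boundary separation `a` never varies) — by
  adaptive Metropolis-within-Gibbs, with split-chain R-hat,
  autocorrelation profiles and DIC model comparison;
- **posterior analysis**: the "<5% overlap of posterior density mass"
  significance rule (KDE overlap coefficient), drift contrasts, and
  posterior-predictive RT-quantile checks at the 10/30/50/70/90th
  percentiles;
- **trial-level mixed logistic models** of positive self-evaluation
  (random intercept per participant, adaptive Gauss–Hermite quadrature
  ML), with odds ratios, Wald CIs, ICC, marginal/conditional R² and BIC
  model ranking;
- **descriptive summaries** and paired one-tailed t-tests on
  per-participant proportions.

## The model

Choice and RT come from a diffusion between boundaries 0 and `a`
(upper = "no, doesn't describe me"), starting at `z·a`, drift `v`,
unit diffusion, plus non-decision time `t`:

    P(upper) = (1 − e^{−2vaz}) / (1 − e^{−2va}),   v ≠ 0

Group-level cell drifts and participant-level (a, z, t) are estimated
jointly; two condition cells differ when their posteriors overlap by less
than 5% of density mass. Trial-level responses are alternatively modelled
as `logit P(reject) = β₀ + b_i + β_cond·1[enriched] + β_rt·RT`,
`b_i ~ N(0, τ₀₀)`.

## Worked example

```python
from sretddm import GroupTruth, StudyDesign, generate_dataset, HierarchicalDDM
from sretddm.posterior import drift_contrasts

trials = generate_dataset(GroupTruth(), StudyDesign(), seed=101)  # 10,296 rows
model = HierarchicalDDM(varying=("v",), n_samples=6000, burn_in=1000,
                        thin=5, n_chains=3, seed=101).fit(trials)
print({k: round(v, 4) for k, v in model.group_means_.items()})
print(round(model.dic_, 1), round(model.result_.max_rhat, 4))
print(drift_contrasts(model.result_)[["contrast", "mean_diff",
                                      "overlap_mass", "significant"]]
      .round(4).to_string())
```

prints (about four minutes on one core):

```
{'v[positive:blue_depleted]': -0.7176, 'v[positive:blue_enriched]': -0.6347,
 'v[negative:blue_depleted]': 1.0791, 'v[negative:blue_enriched]': 1.2988,
 'a': 1.4375, 'z': 0.4833, 't': 0.4414,
 'sigma_a': 0.1848, 'sigma_z': 0.0417, 'sigma_t': 0.0536}
11199.2 1.003
                                 contrast  mean_diff  overlap_mass  significant
0           negative: enriched - depleted     0.2197        0.0004         True
1           positive: enriched - depleted     0.0829        0.1894        False
2  blue_enriched: |negative| - |positive|     0.6641        0.0000         True
3  blue_depleted: |negative| - |positive|     0.3615        0.0000         True
```

Read: the generator planted group drifts (−0.73, −0.71, 1.13, 1.36) with
boundary 1.42, bias 0.49 and non-decision time 0.46 s; the fit recovers
every group mean well within posterior uncertainty (all split R-hats ≤
1.003). The negative-word drift contrast — rejecting "terrible" faster
under blue-enriched light — leaves only 0.04% of posterior mass
overlapping and is flagged significant; the positive-word contrast (19%
overlap) is not. Negative-word drifts are faster than positive-word ones
in both conditions.

The same pipeline is scriptable from a shell:

```bash
sretddm simulate --out-dir run --seed 1
sretddm fit-hddm run/trials.csv --out-dir run --seed 1
sretddm fit-glmm run/trials.csv --out-dir run
sretddm report run
```

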