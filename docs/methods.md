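# Methods

This note documents the statistical and algorithmic choices in
`boxnet`: what each component computes, the generator's parameters and
why their defaults are what they are, and the numerical details of the
model fitting.

## 1. Data model and observation windows

The primitive observation is a visit: `(individual_id, box_id, section,
entry, exit)` with times in seconds and half-open occupancy
`[entry, exit)`. A study is divided into contiguous observation windows
(`boxnet.windows.build_schedule`): `n_pre_windows` before the
catastrophe and `n_post_windows` after it, each `window_days` long
(default 5), separated by an `event_gap_days` gap (default 2) that
contains the event itself and is excluded from analysis. Windows are
validated to be non-overlapping, contiguous within each phase, and to
never contain the event time.

## 2. Association networks

Edge weights are a duration-based simple ratio index. For a dyad
(i, j) within one window,

SRI(i, j) = x / (t_i + t_j − x),

where x is the total time i and j spent simultaneously in the same box
and t_i, t_j are each individual's total in-box time, all clipped to
the window. SRI is 1 when two animals are always in a box together and
0 when they never overlap.

Overlaps are computed exactly by a sweep over box-occupancy change
points: within each box, entries are +1 events and exits −1 events;
between consecutive change points every currently co-present pair
accrues the segment length. At time ties, exits are processed before
entries (via `np.lexsort((deltas, times))`), which makes touching
intervals (`[a,b)` then `[b,c)`) contribute zero overlap, consistent
with half-open semantics. The unit tests verify this sweep against a
brute-force per-second discretization oracle.

Two network stacks are built per dataset: *full* (each window's network
over everyone recorded in it) and *survivor-only* (node set restricted
to individuals present in every window), the latter being the basis
for change scores, so that composition changes cannot masquerade as
behavioural change.

## 3. Metrics and change scores

Per node and window: degree (partner count), strength (sum of SRI),
weighted betweenness with edge lengths 1/weight, and weighted
clustering. Change scores (`delta_from_baseline`) subtract each
individual's value in the baseline window — by default the last
pre-event window — from its value in every other window. Community
summaries (`group_stats`) report size, within-community density, and
missing-member proportions.

## 4. Permutation null

The null model is a synchronized node-swap (node-label) permutation.
One chain of uniformly random transpositions over the analysis pool is
generated (`generate_swap_chain`; default 1000 burn-in swaps, then 1000
emissions of 10 swaps each — 11000 total), and each emitted permutation
is applied to **every** window of the stack simultaneously
(`apply_swaps_synchronized`). This preserves, exactly:

- every network's topology and weights (degree/strength sequences are
  invariant by construction), and
- each individual's *set* of network positions across windows moving as
  a unit,

while breaking the association between an individual's attributes
(pre-event sociality, loss of associates) and its positions. Identity
attributes travel with the identity, not the position. Because the
permutation is identical in all windows, within-individual longitudinal
structure in the response is preserved under the null.

Empirical p-values use the add-one estimator
p = (1 + #{|stat_r| ≥ |stat_obs|}) / (R + 1), which can never be zero.
An acceptance test confirms calibration: on data generated with both
response effects set to zero, the sociality × loss interaction is
rejected at α = 0.05 in an acceptably small fraction of 200 datasets.

## 5. Dynamic communities

Detection optimizes either weighted Newman–Girvan modularity or a
two-level map-equation codelength over hard partitions, by
single-node label moves with simulated annealing and multiple seeded
restarts (deterministic given `seed`). For the map objective the
codelength is the standard two-level form with stationary visit rates
proportional to node strength; unit tests pin it to closed forms (two
disconnected unit-weight triangles: log2(6) − 1 for the true partition,
log2(6) for the one-module partition) and cross-check partitions
against python-igraph's Infomap.

Windows are linked into a dynamic community map by **reciprocal strict
majority**: community B in window t+1 inherits the persistent id of
community A in window t iff their intersection exceeds half of |A| and
half of |B| (computed over individuals present in both windows).
Unmatched communities get fresh ids. Movement events are groups of
individuals that leave one persistent community for another between
consecutive windows, with a cross-section flag; alluvial tables give
exact flow counts (conserved by construction).

## 6. Response models

### Individual level

The response is a change score (Δdegree, Δstrength, or Δbetweenness)
for each survivor in each non-baseline window. Predictors:
standardized pre-event sociality (strength in the last pre-event
window), standardized proportion of pre-event associates lost, window
dummies (reference: first post-event window), and — in the
`interaction` variant — all two- and three-way products of window ×
sociality × loss.

The model is a hierarchical Gaussian **location-scale** model:

y_k = x_kᵀβ + u_{g(k)} + ε_k,  u_g ~ N(0, τ²),
ε_k ~ N(0, exp(z_kᵀγ)²),

with a random intercept per individual and a log-linear model for the
residual standard deviation (scale terms: intercept, sociality, loss,
and their product by default), so the model captures effects on both
the mean and the *variability* of social change. It is fitted by full
maximum likelihood with analytic gradients; `LocationScaleModel.fit()`
returns a `LocationScaleResults` object with `params`, `bse`,
`conf_int()`, `summary()`, `llf`, in the style of statsmodels. With a
constant scale the model reduces exactly to a random-intercept LMM, and
a unit test pins estimates and log-likelihood to
`statsmodels.MixedLM(reml=False)`.

Numerical details:

- The per-group covariance σ²I + τ²11ᵀ is inverted via the rank-one
  Woodbury identity, so each likelihood/gradient evaluation is linear
  in the data size.
- Scale parameters are optimized as logs with L-BFGS-B box bounds
  (−12, 12) to prevent σ → 0 divergence on degenerate resamples.
- Standard errors come from a numerical Hessian of the negative
  log-likelihood; `fit(se=False)` skips it.
- `permutation_effect_test` refits the model once per emitted
  permutation. Because permuting identities while attributes travel
  with them is equivalent to permuting the attribute columns of the
  design matrix, the fast route does exactly that; a unit test verifies
  it coefficient-by-coefficient against the faithful route that
  rebuilds networks from the relabelled stack. Randomized refits are
  warm-started at the observed optimum with `se=False`.

### Community level

`build_community_table` turns per-window community summaries into
change scores of community size (or density) against standardized
pre-event size and missing-member proportion; `fit_community_model`
fits the same location-scale machinery with a random intercept per
community (falling back, with a warning, to no random effect when only
one community exists).

## 7. Synthetic-data generator

### Baseline process

Each individual alternates exponential in-box bouts (mean
`mean_in_box_minutes`, default 30) and out-of-box intervals (mean
`mean_out_of_box_minutes`, default 240), a duty cycle of ~11%. Bouts
target the individual's home-group box cluster with probability
1 − `between_group_rate` (default 0.9 within). This calibration puts
pre-event edge density at the reference scale near 0.07–0.1, a
realistic range for nest-box SRI networks; with shorter out-times the
networks saturate and group structure washes out. All randomness is
drawn from `np.random.default_rng([seed, tag, ...])` streams, so every
component is independently reproducible and the full scenario is
byte-identical across runs.

### Catastrophe

Fates are assigned at rates `dead_rate`/`disappeared_rate`
(defaults 85/478 and 107/478) with exact rounded counts, optionally
weighted per group. Dead and disappeared individuals emit no events
after the event time.

### Survivor response channels

Both channels ramp in linearly over the post-event windows (factor
j/n_post in post window j) and are gated by a logistic weight in the
individual's pre-event sociality z-score (slope ±2):

- **Prospecting** (weight logistic(−2·soc_z), strength
  `response_effect_low_social`, default 6): extra weak 5-minute visits
  to boxes outside the home cluster, with target boxes drawn
  proportionally to the owning group's survivor share raised to the 4th
  power — prospectors preferentially join intact groups, not emptied
  ones.
- **Insularity** (weight logistic(+2·soc_z), strength
  `response_effect_high_social`, default 6): a fraction
  min(0.95, insularity) of bouts is redirected to one per-individual
  favourite box within the home cluster (individuals spread over the
  cluster's boxes), and bout durations stretch by 1 + insularity. The
  per-individual favourite is essential: a shared group-wide favourite
  box would *increase* within-group co-occupancy and hence degree.

Both channels scale with the individual's loss proportion. With both
effect sizes at 0 the post-event process is bit-identical to the
baseline process (tested), which is what makes honest null-calibration
datasets possible.

### Default effect sizes

The defaults (6/6, logistic slope 2, survivor-share exponent 4) were
chosen so that, at moderate scale, the fitted interaction model
reproduces the intended qualitative pattern — rising degree for
low-sociality/high-loss survivors and a late decline for
high-sociality/high-loss survivors — robustly across seeds, while
densities stay in a realistic range. They are generator parameters,
not fitted quantities, and can be set freely in `ScenarioConfig`.

## 8. Limitations

- The generator's bout process is memoryless within windows; it does
  not model diurnal rhythm, weather, or seasonal drift.
- SRI is computed from durations, not visit counts; sampling-time
  corrections (e.g., for unequal detection) are out of scope.
- The location-scale model assumes Gaussian responses; heavy-tailed
  change scores are handled only through the scale submodel.
- Community detection is stochastic annealing, not an exhaustive
  optimizer; determinism holds for a fixed seed and restart count, and
  global optimality is only verified on closed-form cases.
- The permutation null preserves network structure exactly but, like
  all node-label nulls, tests the attribute–position association only.
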