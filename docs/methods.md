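# Methods

This note documents the models, numerical conventions and design choices
behind `bwsnorms`, and what the synthetic-data generator does and does not
emulate.

## Balanced tuple design

Words are partitioned into part-of-speech pools (noun / verb / adjective,
plus a separate pool for POS-ambiguous "mixed" words, which never enter the
single-POS pools). Within a pool of *N* words, the designer emits
`factor × N` tuples of *k* distinct words (defaults k = 4, factor = 2) under
two balance contracts:

* **appearance balance** — every word appears exactly `factor × k` times.
  This is exact by construction: the generator deals a multiset containing
  each word `factor × k` times into rows, then repairs within-row
  duplicates with count-preserving swaps;
* **pair balance** — the max−min spread of pair co-occurrence counts within
  a pool is at most 2 (configurable). Large sparse pools (where most pairs
  never co-occur) only need a targeted eviction pass over the handful of
  over-represented pairs; small dense pools additionally run a seeded
  hill-climb on the sum of squared pair counts, which — the total being
  fixed — flattens the co-occurrence distribution. The ≤ 2 tolerance is
  this package's convention for "approximately equal"; published BWS
  designs state the goal qualitatively rather than as a hard bound.

Questionnaires hold at most `max_per_list` tuples (default 40) from a
single pool, so the list count is the sum over pools of
`ceil(pool_tuples / max_per_list)`. Each list receives `n_checks`
attention-check tuples (default 2) at seeded random non-adjacent positions.
A check is a hypernym chain (e.g. *object > food > baked-goods > muffin*)
stored with ranks 1..k from most generic to most specific and presented in
shuffled order.

All randomness flows from numpy `default_rng(seed)`; identical inputs and
seed reproduce identical designs.

## Synthetic world

The generator provides a known ground truth so recovery can be measured.

* **Latent scales.** Specificity and eight covariates (concreteness,
  valence, arousal, dominance, imageability, familiarity, age of
  acquisition, log frequency) are drawn from a Gaussian copula. Correlation
  targets are given on the Spearman scale and converted with
  `r = 2·sin(π·ρ/6)`; marginals are mapped to [0, 1] by the empirical rank
  transform, which preserves ranks exactly and attains both bounds. The
  default target matrix encodes the correlation structure reported for
  ANEW-based norms (specificity–concreteness 0.552, specificity–frequency
  −0.475, concreteness–imageability 0.88, valence–dominance 0.833, …);
  entries not reported anywhere are modest values consistent with published
  norm sets, chosen once and fixed. Realized correlations land within about
  ±0.1 of targets for n ≥ 500.
* **Raters (Thurstonian choice).** On each trial an attentive rater
  perceives `u(w) = specificity(w) + Normal(0, noise_sd)` and picks
  argmax/argmin as best/worst; ties (possible only at noise 0) break by a
  seeded random preference. A Thurstonian model was preferred over
  Plackett–Luce because its argmax/argmin semantics match the best–worst
  task directly and its noiseless limit is exact. A *careless* rater picks
  an ordered (best, worst) pair uniformly among the k(k−1) possibilities,
  on checks and ordinary trials alike — so the pass probability of one
  4-word check is exactly 1/2 and of two independent checks 1/4, making the
  exclusion rule's power measurable. Default utility noise is 0.05 on the
  unit latent scale (the demo's "attentive" condition); human response
  noise for this task is not published, so values in 0.05–0.2 should be
  read as conventions.
* **Reaction times.** `RT(w) = intercept + Σ coeff_v · value_v(w) + noise`.
  Default coefficients follow the full lexical-decision regression pattern
  of a large university-lab megastudy (strong positive age-of-acquisition,
  strong negative frequency/familiarity, small specificity and concreteness
  effects; intercept 650 ms, residual sd 50 ms).
* **Synthetic taxonomy.** A single root-to-leaf chain of 20 nodes; each
  word's sense depth grows with the *square* of its latent specificity plus
  integer noise (±2 levels), mimicking the left-skew of expert-taxonomy
  depths relative to behavioural scales while preserving rank order up to
  noise.
* **Second population.** Cross-language norms are emulated by adding a
  per-variable systematic shift plus Gaussian noise (sd 0.05) and clipping
  to [0, 1]. The default shifts follow the mean rating differences observed
  between the Italian and English ANEW norm sets (arousal +0.154,
  specificity −0.068, …).

What the generator does *not* emulate: rater fatigue and order effects,
per-rater ability differences beyond a single noise level, item polysemy,
non-linear RT generation, and translation-pair asymmetries beyond an
additive shift. Passing recovery tests therefore show the pipeline's
statistics are implemented correctly, not that real raters behave this way.

## Scoring and reliability

Sessions failing *any* assigned attention check are excluded; verification
is non-strict — the picked best must merely outrank the picked worst on the
chain, not be the extremes. Missing check answers count as failures and are
logged. The exclusion rate is reported as a percentage to two decimals.

Raw scores are `(#best − #worst)/#appearances`; published scores are the
min–max rescaling of raw scores over the scored vocabulary (default: all
pools jointly, configurable), under which the extreme items attain exactly
0 and 1. Min–max (rather than `(raw+1)/2`) is used because norm releases in
this area show attained bounds. Words with zero appearances are dropped and
logged; constant score vectors are rejected rather than silently rescaled.

Split-half reliability partitions each tuple's sessions (not raters or
lists — this guarantees both halves cover every tuple) into two halves per
iteration, scores each half, and correlates the half-scores; with an odd
session count the extra record lands in either half with equal probability.
Means and standard deviations of Pearson and Spearman correlations are
reported over `n_iter` iterations (default 100), overall and per pool.
Report tables round correlations to 2 decimals; full precision is retained
internally.

## Taxonomy specificity

`WNspecificity = (1 + d)/max_depth` with `max_depth = 20` by default, where
*d* is the **shortest** hypernym-path length from the word's **first
listed** sense to a root (deterministic; no disambiguation is attempted —
sense order is whatever the sense file provides). The score is strictly
increasing in depth; one extra edge adds exactly `1/max_depth`. Words
absent from the taxonomy are skipped and logged; comparisons use the shared
vocabulary only, with both columns min–max rescaled over it. Distribution
divergence uses a two-sided Mann–Whitney U test: exact enumeration for
pooled n ≤ 8 (valid under ties), otherwise the normal approximation with
tie and continuity corrections.

## Regression battery

All fits are ordinary least squares — the identity-covariance special case
of generalized least squares, since no correlation or heteroscedasticity
structure is specified for data of this kind. Conventions:

* predictors are already on [0, 1] and are **not** centred; the quadratic
  form is `y ~ 1 + x + x²` per flagged predictor. BIC (lower wins) selects
  between linear and quadratic; both fits are retained in every report so
  either reading is recoverable. BIC selection is invariant to affine
  predictor rescaling;
* VIF_j = 1/(1 − R²_j) from regressing predictor j on the others;
  iterative pruning removes the max-VIF variable (alphabetical tie-break;
  exact collinearity reported as ∞ and removed first) until all VIFs are at
  or below the cutoff (default 4);
* missing data are handled by listwise deletion within each model, with n
  reported; significance stars follow * p < 0.05, ** p < 0.01, two-sided;
* the ablation refits the full model's leave-one-out sub-models **on the
  full model's row set** (enforced, to prevent silent missing-data drift),
  so every delta `r²(full) − r²(full minus j)` is non-negative; under
  exactly orthogonal predictors each delta equals that predictor's marginal
  r²;
* abstract/concrete subset models drop concreteness (the stimuli are
  pre-labelled by it) and re-check VIF within each subset;
* no multiple-comparison correction is applied across the battery, by
  design of the analysis template it mirrors;
* the correlation cluster map orders variables by average-linkage
  hierarchical clustering on `1 − |ρ|` — purely presentational and
  deterministic. Constant columns are excluded and logged.

## Cross-lingual comparison

Norm tables are inner-joined through a translation mapping (duplicates
rejected, unmatched pairs dropped and logged). Deltas are absolute
differences with the signed difference retained. Scale use is compared with
a **paired** Wilcoxon signed-rank test: although the classical presentation
of such comparisons is often labelled "rank sum", translation equivalents
are matched pairs, and the paired test fits the design; an unpaired
rank-sum mode is exposed for completeness. Zero differences are dropped
from the signed-rank statistic (standard convention) but counted as ½ in
CLES; with all-zero differences the test is reported as undefined rather
than forced. RBC and CLES are oriented toward language b; swapping the
languages negates RBC and maps CLES to 1 − CLES.

## Pipeline defaults and problem sizes

The demo configuration is 100 words, k = 4, factor = 2, 10 sessions per
tuple, utility noise 0.05, no careless raters, 100 reliability splits —
small enough to run in seconds while leaving every statistic comfortably
estimable. Under these conditions Spearman(latent, recovered score) ≥ 0.95
and mean split-half Spearman ≥ 0.9; both are asserted by the test suite.
The full-scale design (1,034 words → 2,068 tuples) runs in well under a
second. POS shares default to 60/20/20 noun/verb/adjective; lexicons too
small to give every pool k words fall back to a single noun pool.

## Known limitations

* The pair-balance tolerance and the hill-climb budget are heuristics; for
  adversarial pool sizes the search raises rather than silently returning
  an unbalanced design.
* Recovery of the latent scale saturates below 1.0 even at zero noise:
  with `factor × k` appearances per word the counting statistic is
  granular. More sessions or a larger factor, not less noise, is the lever.
* The scorer is the classical counting estimator; item-response-theory or
  Bayesian BWS models and per-rater ability estimation are out of scope.
* `wn_specificity` uses the first listed sense only; with polysemous words
  the metric inherits whatever sense ordering the taxonomy file provides.
* Only two languages are compared at a time, and translation-pair discovery
  is the caller's responsibility.
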