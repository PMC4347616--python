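# Methods

## The model

`grainforest` trains an ensemble of `t` unpruned binary CART trees (Gini
impurity, grown to purity, `m_try` random candidate features per split) and
scores by an unweighted hard vote: the score of an example is the fraction
of trees predicting class 1, a multiple of `1/t`. Classification uses a 0.5
threshold with ties assigned to class 1 — a fixed, documented rule chosen
because a prioritization tool prefers recall at its default operating point.

What distinguishes the three variants is solely how each tree's in-bag
sample is drawn from the training partitioning `D = {P₁ … P_p}`, where a
partition collects all examples sharing the coarsest-grain feature value
(the gene, in a variant-prioritization table):

* **standard** — the classical bootstrap, `n` uniform draws with
  replacement from the pooled training set;
* **stratified** — each partition bootstrapped separately at its own size,
  so every partition is represented in every bag (the classical use of
  stratification, here a control: it *guarantees* the repeated presence of
  each grain value in every tree and therefore does not fix the bias);
* **hierarchical** — exactly one example drawn uniformly from each
  partition, bag size `p`. A single tree can never observe the same grain
  value twice, so a split on the grain feature cannot isolate a training
  group; resampling before every tree keeps the ensemble's coverage of the
  data complete.

The trees are wrapped scikit-learn `DecisionTreeClassifier` instances fitted
on exactly the drawn bag (the learner performs no internal resampling).
Determinism: one master `SeedSequence` spawns an independent child stream
per tree for both the bag draw and the tree's split randomness, so results
are bit-identical for a given (table, config, seed) and independent of
execution order. Split ties are resolved by the wrapped learner under that
fixed per-tree seed.

Assumptions: binary labels, fully numeric features, no missing values; the
grain column must be identified by the user (domain knowledge — the grain
can even be a latent grouping not present as a column, in which case the
`grain_id` vector carries it).

## Key parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `n_trees` (t) | 1000 | ensemble size; large enough that every partition is well represented across bags under hierarchical sampling |
| `m_try` (M) | ⌊√d⌋ | candidate features per split, the customary classification default; ⌊√7⌋ = 2 for the synthetic table |
| `scheme` | standard | in-bag sampling scheme |
| `seed` | 0 | master seed for bags and split randomness |

## Out-of-bag permutation importance

For each tree, the examples absent from its bag form its OOB set; the
importance of feature f is the mean over trees of (OOB misclassification
error after permuting f's values within the OOB set − unpermuted OOB error),
optionally averaged over `n_perm` permutations (default 1, as the estimate
is already averaged over trees). An example that is never OOB triggers a
warning; trees with empty OOB sets are skipped. Under hierarchical sampling
with small `p` almost everything is OOB, which is legitimate but makes the
per-tree error estimates noisier.

## Synthetic benchmark

The generator emulates a prioritization table in which one column is a
coarse-grained group identifier:

* `u1..u3` ~ Uniform(0,1), independent of the class (non-informative);
* `g1..g3` ~ Normal(mean_class, sd) with means 0.4 (class 0) / 0.6
  (class 1) and sds 0.05, 0.10, 0.20 — three overlap levels from nearly
  separable to heavily overlapping. These parameter values are this
  package's defaults, chosen to give strong/medium/weak informative signal;
  they are exposed in `SyntheticConfig.informative_params`;
* `grain`: per class, `n_per_class / |P|` distinct Uniform(0,1) values, each
  assigned to exactly |P| examples of that class. Distinctness is enforced
  by redrawing on collision, since a duplicated value would merge
  partitions. The value doubles as the example's grain identifier.

The default table has 2000 examples per class (4000 total). Grain-level
label noise pairs class-0 partitions 1:1 with class-1 partitions uniformly
at random and swaps `k = round(x·|P|)` grain values each way per pair
(half-up rounding; with the canonical grids — |P| ≥ 20, noise in steps of
0.05 — all counts are integral). Labels are untouched; each grain value then
covers a `1−x` majority of its original class. Swaps are drawn without
replacement within a partition. Noise requires `k ≥ 1`, hence the |P| ≥ 20
floor used in the noise experiment.

What the generator deliberately does **not** emulate: correlated features,
the empirical distributions of real deleteriousness/conservation scores,
multiple simultaneous granularity levels, or class imbalance (the table is
balanced; imbalance is introduced at evaluation time by
`undersample_positives`). Passing benchmarks on this data therefore
demonstrates the sampling schemes' behaviour when grain structure is the
*only* confound, not performance on any real cohort.

## Experiments

Both experiments generate the six base feature columns once per grid (they
are not part of the manipulated structure) and regenerate the grain feature
and the train/test split in every repetition.

* **Partition-size experiment**: for each |P| in the grid and each
  repetition, attach a fresh grain feature, split 50/50 along grain values,
  train all three schemes on the same split, evaluate on the common test
  set, and harvest OOB importance from the standard-scheme forest (a flag
  extends harvesting to all schemes).
* **Noise experiment**: the same protocol with an added noise axis; only
  partition sizes ≥ 20 are accepted.

The train/test split is made along distinct grain values — all examples of
a value travel together — stratified by the majority class of the partition
(ties count as class 1) with `floor(fraction · count)` values per stratum
going to the training side and a guard moving one value if either side
would be empty. Class stratification is used so both classes appear on both
sides; for synthetic runs the split is 50/50, for real gene-level variant
tables the conventional 2/3–1/3.

Scheme comparison pairs records by repetition and applies the two-sided
Wilcoxon signed-rank test per metric (sensitivity, specificity, precision,
NPV, MCC, AUC-ROC, AUC-PR) with Bonferroni correction, m = number of
metrics tested per scenario.

## Evaluation conventions

* Curves are swept over distinct score thresholds with predicate
  `score ≥ t`. AUC is trapezoidal; AUC-ROC then equals the normalised
  Mann–Whitney U (ties counted ½).
* PR precision at zero recall is anchored at the precision of the
  top-scored threshold, avoiding the undefined 0/0 corner; with constant
  scores the PR curve is flat at the prevalence.
* Threshold averaging aligns repetitions on a shared threshold grid — the
  natural choice for a t-tree ensemble is the vote lattice {0, 1/t, …, 1},
  making alignment exact — and records the per-threshold mean point and
  empirical 2.5/97.5 percentile band over runs. The same score-threshold
  alignment is applied to ROC and PR curves.
* MCC returns 0 when any confusion marginal is zero.
* Prevalence adjustment subsamples positives without replacement to
  `floor(rate · n_neg / (1 − rate))` (≥ 1) kept positives.
* Wilcoxon signed-rank: zero differences dropped, average ranks on ties;
  the exact null distribution (dynamic programming over doubled ranks,
  equivalent to enumerating all 2ⁿ sign assignments) for ≤ 25 informative
  pairs, the normal approximation with tie correction above — 100-repetition
  comparisons sit in the approximation regime, small tests are exact.

## Problem sizes

The shipped scaled preset (`SCALED_GRID`: |P| ∈ {1, 100, 500}, 10
repetitions, 200 trees; noise ∈ {0.05, 0.25, 0.45} at |P| = 500) is the
package's default for trend verification and completes in minutes on one
CPU while reproducing the full benchmark's qualitative pattern: standard
and stratified accuracy collapse at large |P|, hierarchical accuracy stays
within its own repetition band, grain-feature importance rises monotonically
while informative features decline, and noise walks the standard scheme's
bias back. `FULL_GRID` (all ten sizes, 100 repetitions, 1000 trees) is the
full-fidelity configuration.

## Known limitations

* Hierarchical sampling at |P| close to `n_per_class` is degenerate — with
  two partitions per class and a 50/50 split each tree trains on ~2
  examples; performance drops for lack of data, not because of grain bias.
* The bias at large |P| is high-variance across single repetitions (a
  forest either locks onto the grain feature on a given split or it does
  not), which is why all trend checks aggregate over repetitions.
* Hard 0/1 tree votes are assumed (matching an unweighted ensemble vote);
  averaging leaf probabilities instead would change score granularity.
* One grain column per table; multi-level hierarchies must be reduced to
  their coarsest level by the caller.
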