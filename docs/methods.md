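# Methods

## Problem setting

Given a samples × features table `X` with labels `y` (categorical or real),
feature selection seeks an index subset `S ⊆ {1..n}` maximizing the
cross-validated performance of a learner trained on `X[:, S]`.  The problem
is combinatorial (2ⁿ − 1 non-empty subsets), so `gawcc` searches with a
two-stage population metaheuristic and treats the learner as a black-box
scoring oracle (a *wrapper* approach), in contrast to *filter* methods that
score each feature by a statistic alone.

## Candidate encoding and its consequences

A candidate solution is a variable-length, duplicate-free, sorted tuple of
1-based feature indices.  All five search operators (mutation, window
crossover, attacking, transferring, passing) work by *overwriting positions*
and then repairing (sort + deduplicate).  Two consequences are worth
stating explicitly, because they shape everything downstream:

1. **Candidates can only shrink, never grow.**  An overwrite that collides
   with an existing index removes one position.  The feature count of any
   reachable subset is therefore bounded by the candidate's initial length.
2. **The initial GA length bounds the whole search.**  The default initial
   length is `min(n, max(2, round(sqrt(n))))` — small initial models on
   omics-scale `n`.  Users who need larger panels should raise
   `GaConfig.init_length`; benchmarks that compare against exhaustive
   enumeration must be constructed so the optimum fits within the bound,
   and the bundled oracle benchmark was built (and verified by full
   enumeration) to satisfy this.

## Scoring

Fitness is the mean held-out accuracy over a stratified k-fold plan
(default k = 5) for classification, and −RMSE for regression so both tasks
are maximized uniformly (the greedy "accept if the score increases" rule
then applies verbatim).  The default learner is an RBF support-vector
machine with `C = 1` and `gamma = 1/|S|`; the learner is a pluggable
`fit`/`predict`(/`decision_function`) contract, and no hyperparameter
search is performed.  The reported panel (SEN, SPC, PRE, FPR, ACC,
F-measure, Cohen's kappa, AUC; RMSE and Pearson r for regression) is pooled
over held-out predictions; multi-class metrics are macro one-vs-rest
averages, kappa is the standard `(p_o − p_e)/(1 − p_e)`, and AUC is the
rank-based (Mann–Whitney) statistic with ties counting ½.  Zero-denominator
panel cells are reported as 0 with a warning.  When a table has missing
values, mean imputation is re-fitted on each training fold inside the CV
loop to avoid leakage; the global `canonicalize` step exists for one-shot
fits and report output.

Scoring is deterministic given (table, fold plan, subset), so the
evaluator memoizes by index set.  The WCC operators call the cost function
far more often than the GA; caching is the mitigation, and cache hits are
free under evaluation budgets.

## Search stages and defaults

**GA** (stage 1): population 100; mutation and crossover rates 0.30,
interpreted as `rate·pop/2` random pairs producing children and `rate·pop`
random members producing mutants per generation, all competing with the
parents in one elitism pool (ties broken toward shorter candidates, then
lexicographic indices — a mild parsimony pressure); termination when the
best fitness is constant (within 1e−12) for 10 consecutive generations,
with a hard cap of 500 generations.

**WCC** (stage 2): population 20 and match time 2 standalone; seeded by the
GA's full terminal population with match time 1 in the two-step method;
fixed iteration budget (default 100); top-count 5 candidates feed the
transferring operator.  Within one attempt the three operators are applied
in the fixed order attacking → transferring → passing, each followed by a
greedy step that accepts the proposal only on a *strict* fitness increase
(ties keep the incumbent, preventing neutral drift).  The attacking and
transferring overwrite counts are drawn per application and bounded by the
candidate's current length.

**Budgeted comparisons.**  Methods are compared under identical
evaluation-count budgets rather than identical wall-clock time: the
evaluator counts cache-miss evaluations and the engines terminate
gracefully when a per-run budget is spent.  Evaluation counts are
hardware-independent and exactly reproducible, which wall-clock budgets are
not.

**EN_WCC** (filter–wrapper variant): the information-gain filter keeps the
top `filter_k` features, a standalone WCC searches the reduced space, and
selected indices are mapped back to original coordinates.

## Filter conventions

The five baselines use standard textbook forms: PC = |Pearson r(feature,
label)|; FI = class-size-weighted between-class variance of class means
over pooled within-class variance (a feature with zero pooled within-class
variance but separated means scores +inf); MI = plug-in mutual information
in bits between the equal-frequency-binned feature (default 10 bins) and
the label; EN = information gain, i.e. label entropy minus conditional
label entropy given the binned feature — numerically identical to MI at
equal bin counts, kept as a separately named method because the two are
exposed and configured independently; LA = Laplacian score on a
5-nearest-neighbour heat-kernel graph with width set to the median pairwise
distance (lower is better).  Constant features receive the method's null
value (0, or 1 for LA) with a degeneracy flag.  Top-k truncation breaks
ties by ascending index, which makes top-k sets nested in k.

## Synthetic benchmarks

The generator plants three feature classes.  *Positive* features are
class-conditional Gaussians whose adjacent class means sit
`effect_size · noise_sd` apart (regression: unit-coefficient contributors
to the target).  *Neutral* features are label-independent Gaussians.
*Negative* features apply the positive construction to a random permutation
of the labels (regression: correlate with a permuted target), so they carry
signal-shaped structure aligned with phantom classes — pure noise would
merely be neutral, whereas these actively mislead fold-level fits.  Column
positions are shuffled; the ground truth records the planted index sets so
selections can be scored for precision/recall.  An optional redundancy knob
appends noisy copies of positive features.

What the generator does *not* emulate: real marginal distributions, heavy
tails, batch effects, feature-scale heterogeneity, or correlated noise.
Passing benchmarks here demonstrates the search machinery and the planted
recovery behaviour, not parity with any published table computed on
external datasets.

A quantitative caveat documented here because it matters for benchmark
design: with independent positive features, the combined class separation
grows as `effect_size · sqrt(k)` over `k` selected positives, so CV
accuracy saturates at exactly 1.0 once a few strong features are selected.
Past that point the strict-improvement greedy rule (correctly) stops
changing candidates, so recall of the *full* planted set is not a
meaningful target under strong effects; benchmarks meant to exercise
recovery should use moderate effect sizes (≈1–2 SD) where every planted
feature still contributes measurable held-out gain.

## Numerical choices and degenerate inputs

- Stagnation tolerance 1e−12 on the best fitness; greedy acceptance uses a
  strict `>`.
- Elitism and top-list selection are fully deterministic (score, then
  length, then lexicographic indices), so runs are bit-reproducible from
  (config, seed); a single `numpy` Generator seeded from the pipeline seed
  drives all randomness.
- Zero-variance columns: z-scoring and min-max map them to zeros; filters
  assign null scores; Fisher with zero within-class variance returns +inf.
- Equal-frequency binning collapses duplicate quantile edges, so discrete
  features keep their natural levels and MI/EN are invariant under strictly
  monotone transforms.
- Empty candidates cannot arise (operators overwrite rather than delete;
  repair keeps at least one value), and a training fold missing a class
  raises rather than silently scoring.

## Benchmark scales

The bundled end-to-end tests and the acceptance script run at desk scale,
chosen as the package's own benchmark sizes: a 10-feature table (100
samples) for the exhaustive-oracle comparison, 24–50-feature tables
(120–200 samples) for recovery and method-ordering experiments, 10–20
executions per method with per-run budgets of 1000–2500 evaluations.  The
multi-execution statistics (mean, STD, t-based CI, Welch or rank-sum test
against a reference method) follow the standard protocol for stochastic
optimizers at any scale.

## Known limitations

- The shrink-only encoding cannot recover optima larger than the initial
  candidate length; this is a property of the published operator set, not
  an implementation artifact.
- Wrapper fitness inherits CV variance; on small tables many subsets tie,
  and tie-breaks (not fitness) decide among them.
- The Laplacian score is unsupervised; it ranks label-aligned features
  first only when the dominant cluster structure follows the labels.
- Multi-class averaging (macro one-vs-rest) and the stratified-CV choice
  are stated conventions; other conventions yield different panel values
  on the same predictions.
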