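# gawcc — two-step wrapper feature selection (GA + WCC)

`gawcc` selects feature (or gene) subsets for classification and regression
tables by a two-step *wrapper–wrapper* search: a variable-length **genetic
algorithm** first narrows the feature universe, then hands its terminal
population to a **world-competitive-contests (WCC)** optimizer that refines
it with three greedy operators.  Every candidate subset is scored by a
cross-validated support-vector machine, so the search optimizes exactly the
quantity practitioners care about — held-out predictive performance — rather
than a proxy statistic.  It is aimed at omics-scale problems (biomarker
panels, QSAR descriptor selection, expression signatures) where the feature
count dwarfs the sample count and features divide into *positive*
(informative), *neutral* (irrelevant) and *negative* (actively misleading)
classes.

## The method

A candidate solution (CS) is a variable-length, duplicate-free, sorted set
of feature indices drawn from `[1, n]`.  Its fitness is the k-fold
cross-validated score of an RBF SVM trained on those columns:

```
Score = Accuracy = (TP + TN) / (TP + TN + FP + FN)        (classification)
Score = -RMSE                                              (regression)
```

**Step 1 — GA.** A population of random candidates evolves by single-index
mutation, equal-length window crossover, and elitism selection; the run
stops once the best fitness has been constant for 10 consecutive
generations.  **Step 2 — WCC.** The GA's terminal population is refined for
a fixed number of iterations; per iteration each candidate gets
`match_time` attempts, each applying three operators with a greedy
accept-only-if-better rule after each:

- *attacking* — re-draw `k ~ U[1, len(CS)]` random positions from `[1, n]`;
- *transferring* — import randomly chosen values from the current
  top-scoring candidates;
- *passing* — re-draw a single position (the minimal move).

Repairs (sort + deduplicate) may shrink candidates, which is how the search
trims the selected-feature count; candidates can never grow beyond their
initial length.  Five filter baselines (Pearson correlation, Laplacian
score, entropy/information gain, mutual information, Fisher score), top-k
truncation, a filter–wrapper variant (entropy reduction + WCC), the
no-selection SVM baseline, and a multi-execution comparison protocol
(mean, STD, t-based CI, Welch/rank-sum tests) round out the toolbox.

## Worked example

```python
from gawcc import (SyntheticSpec, make_classification, make_cv_plan,
                   PipelineConfig, GaConfig, WccConfig,
                   run_ga_wcc, run_baseline_svm, recovery_metrics)

# 120 samples x 24 features: 4 informative, 16 irrelevant, 4 misleading
spec = SyntheticSpec(n_samples=120, n_positive=4, n_neutral=16,
                     n_negative=4, effect_size=1.2, seed=301)
table, truth = make_classification(spec)

baseline = run_baseline_svm(table, make_cv_plan(table, 5, 0))
cfg = PipelineConfig(method="GA_WCC", ga=GaConfig(pop_size=30),
                     wcc=WccConfig(iterations=500), eval_budget=1000, seed=1000)
report = run_ga_wcc(table, cfg)

print(f"baseline ACC {baseline.fitness:.4f}")
print(f"selected {report.nof} features: {report.best.indices}")
print(f"GA_WCC   ACC {report.panel.fitness:.4f}")
print(recovery_metrics(report.best, truth))
```

Output:

```
baseline ACC 0.8333
selected 4 features: (6, 14, 20, 22)
GA_WCC   ACC 0.9083
{'precision': 0.75, 'recall': 0.75}
```

The no-selection SVM reaches 83.3% held-out accuracy because 20 of the 24
features are noise; the two-step selector keeps 4 features — 3 of the 4
planted informative ones plus one extra — and lifts accuracy to 90.8%.

The same runs are available from the shell:

```bash
gawcc synth --samples 120 --positive 4 --neutral 16 --negative 4 \
      --effect-size 1.2 --seed 301 --out bench.csv
gawcc select bench.csv --method GA_WCC --label-column label \
      --seed 1000 --out report.json
```

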