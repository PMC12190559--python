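# hfsa

A three-layer diagnostic system for binary symptom–disease tables:

1. **Rejection layer** — a genetic algorithm evolves a binary *inlier mask*
   over training rows; rows left out of the best mask are dropped as
   outliers.  Fitness is the cross-validated naive-Bayes accuracy of the
   retained rows minus a penalty on the fraction removed, so deleting merely
   hard rows does not pay.
2. **Selection layer** — a hybrid filter–wrapper feature selector:
   - *Fast stage*: chi-square ranking of each feature against the disease
     label keeps the top `v` of `u` features.
   - *Accurate stage*: a hybrid search over binary feature masks that
     alternates one genetic-algorithm generation (roulette selection,
     one-point crossover, single-bit-flip mutation, elitism of one) with one
     Tiki-Taka generation (balls passed around a cyclic ring of players,
     players moving toward their ball and the key player, sigmoid-transfer
     binarization).  The GA output population is the Tiki-Taka input and vice
     versa.  `ga_only` and `tta_only` ablations and an exhaustive
     enumeration oracle are included.
3. **Diagnostic layer** — a Bernoulli naive-Bayes classifier with Laplace
   smoothing (a Hamming-distance KNN baseline is also provided).

A synthetic generator plants per-disease characteristic symptom sets and
optional outliers (label-shuffled or symptom-scrambled rows), so every stage
can be validated against known ground truth without any external data.

The end-to-end pipeline is linear in the training size times the feature
count, O(T·F), per fitness evaluation; the wrapper stage multiplies this by
population size and cycle count.

## CLI

```bash
hfsa generate --seed 1 --out data.csv                  # synthetic dataset
hfsa reject-outliers --data data.csv --out clean.csv   # rejection layer
hfsa filter --data clean.csv --v 66 --out reduced.csv  # chi-square fast stage
hfsa select --data clean.csv --v 66 --method hfsa --seed 1 --out features.txt
hfsa diagnose --train train.csv --test test.csv        # naive-Bayes metrics
hfsa evaluate --data data.csv --k 10                   # 10-fold CV table
hfsa run-all --data data.csv --seed 1 --out report.json
```

`run-all` executes split → outlier rejection (training rows only) →
chi-square filter → hybrid wrapper search → classifier fit → evaluation on
the untouched test partition, and writes a JSON report with per-stage seeds,
shapes and metrics.  Configuration files are plain YAML; defaults follow the
standard parameter set (`P_sel` 0.8, `P_cross` 0.9, `P_mut` 0.01, `C1` 1.2,
`C2` 2.5, `C3` 1.0, `ε` 0.2, `Max_it` 200, population 30, KNN `k` 7).

## Library layout

| module | contents |
|---|---|
| `hfsa.dataset` | `SymptomDataset`, `FeatureMask`, CSV I/O, stratified split, row/column filtering |
| `hfsa.synth` | synthetic generator with ground truth, outlier injection |
| `hfsa.naive_bayes` | Bernoulli NB fit/predict, cached CV-accuracy fitness |
| `hfsa.chi2_filter` | chi-square scores, fast-stage truncation |
| `hfsa.selector` | GA + Tiki-Taka wrapper search, ablations, exhaustive oracle |
| `hfsa.outliers` | GA inlier-mask outlier rejection |
| `hfsa.metrics` | confusion metrics, macro ROC-AUC, KNN, k-fold CV, multi-run summaries |
| `hfsa.pipeline` / `hfsa.cli` | orchestration, seed management, CLI |
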