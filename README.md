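# iefs — iterative ensemble feature selection for imbalanced multiclass expression data

Multiclass gene-expression classification is usually decomposed
one-versus-all (OVA): each class *k* gets a binary classifier separating
its samples from all the rest. In tumour-typing cohorts the classes are
strongly imbalanced, so inside each binary task the "rest" side swamps the
target class and filter feature selection drowns the genes that mark a
minority class under genes that merely describe the majority — the
*siren-pitfall*. `iefs` addresses this by **alternating balanced sampling
and filter feature selection** inside every binary task before the
classifier ever sees the data.

## The method

For each OVA task with majority size *S_M*, minority size *S_m*, *N_M*
genes and a target signature size *N_n*, the pipeline runs *T* steps. Step
*i* first moves the class sizes toward balance by the sample interval

  *M_i* = (*S_M* − *S_m*) / *T*

(random undersampling removes *M_i* majority samples; SMOTE adds *M_i*
synthetic minority samples `x + u·(x_nn − x)` interpolated toward one of
the *k* = 5 nearest minority neighbours), then eliminates the feature
interval

  *N_i* = (*N_M* − *N_n*) / *T*

genes using one of three filters, each recomputed on the freshly balanced
data:

* **Ranking** — mutual information *I(f; c)* between each (discretized)
  gene and the class label, top genes kept;
* **FCBF** — rank by symmetric uncertainty *SU(c; f) = 2·I/(H+H)*, drop
  genes below a threshold δ, then remove every gene *f_i* dominated by a
  better-ranked *f_j* with *SU(c; f_j) ≥ SU(c; f_i)* and
  *SU(f_i; f_j) ≥ SU(f_i; c)*;
* **mRMR** — greedy selection maximising
  *I(f_j; c) − (1/(m−1)) Σ_{f_i∈S} I(f_i; f_j)* over a window of the most
  relevant candidates.

After *T* steps each task is exactly balanced and holds exactly *N_n*
genes (FCBF may legitimately return fewer — the model is flagged *short*);
a per-class binary classifier (KNN with K = 3, or a linear SVM) is trained
on the filtered data, and the *K* classifiers predict by **majority vote**
with ties broken by confidence, then training class size, then class
order. Performance is measured by stratified cross-validated accuracy and
macro one-vs-rest AUC (both in %), the latter weighing minority classes
equally.

## Worked example

```python
from iefs import RunConfig, SyntheticSpec, generate, ova_fit, ova_predict, accuracy

dataset, truth = generate(SyntheticSpec(seed=42))   # 5 classes: 100,20,20,20,20 samples; 1000 genes
config = RunConfig(selector="ranking", sampler="oversample", T=4,
                   n_features=30, classifier="knn", seed=42)
model = ova_fit(dataset, config)
labels, conf = ova_predict(model, dataset.matrix, feature_ids=dataset.feature_ids)
print(accuracy(dataset.labels, labels))
```

Running `python examples/03_iefs_fit_predict.py` prints, per class, the
interval schedule and how much of the planted signal the 30-gene signature
recovers, e.g.

```
class_1: schedule M=(35, 35, 35, 35) N=(242, 242)..., signature of 30 genes recovers 15/15 planted
...
training-set accuracy: 100.0% (resubstitution; see 04 for honest cross-validation)
```

meaning the minority class (20 vs 160 samples) grows by 4×35 synthetic
samples while 970 genes are eliminated in four slices, and every planted
marker gene survives into the signature.
`examples/04_benchmark_sampling.py` runs the cross-validated comparison:
with 3-fold CV, SMOTE lifts macro AUC over the no-sampling baseline at
every signature size (e.g. 99.6% vs 97.1% at 30 genes) and both beat the
1000-gene no-selection baseline (85.3%).

The same machinery is scriptable from the shell:

```bash
iefs simulate -o data.tsv --class-sizes 100,20,20,20,20 --seed 1
iefs select data.tsv -o sigs/ --selector ranking --sampler oversample -T 4 --n-features 30
iefs fit data.tsv -o model.zip --sampler oversample --n-features 30
iefs predict model.zip data.tsv -o predictions.tsv
iefs benchmark data.tsv -o report.tsv --samplers none,oversample --folds 3
```

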