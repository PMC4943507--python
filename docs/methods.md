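# Methods

## Model and procedure

`iefs` implements one-versus-all (OVA) multiclass classification with
per-task correction of class imbalance. A K-class dataset yields K binary
tasks (target class positive, union of the rest negative). Each task runs
T alternating steps of balanced sampling and filter feature selection,
then trains a binary classifier; the K classifiers vote.

**Interval schedules.** With majority/minority sizes S_M / S_m, total
features N_M and target N_n, step i uses the sample interval
M_i = (S_M − S_m)/T and feature interval N_i = (N_M − N_n)/T. Both are in
general non-integer; they are realised as `floor(gap/T)` per step with the
entire remainder absorbed by the last step, so ΣM_i = S_M − S_m and
ΣN_i = N_M − N_n exactly. Within a step, sampling precedes selection, and
elimination applies to the working task, so SMOTE distances in later steps
are measured in the surviving feature space only (neighbours are
re-estimated every step, not frozen at step 1).

**Sampling.** Random undersampling removes M_i uniformly chosen majority
samples without replacement. SMOTE appends M_i synthetic minority samples
x + u·(x_nn − x) with u ~ U[0, 1), x chosen round-robin over the current
minority pool (per-base counts differ by ≤ 1) and x_nn one of its
k = 5 nearest minority neighbours by Euclidean distance (k capped at
minority size − 1). Synthetic samples carry a provenance tag and may serve
as bases in later steps — the pool is always the current minority class.
Sampling targets whichever side of the task is the minority; in OVA that
is normally the positive class, but a class holding more than half of all
samples is the task majority and is then the undersampling target instead.
Test folds are never resampled.

**Information measures.** Features are discretized per gene into
equal-width bins (default 10) spanning the observed range, the maximum
landing in the top bin and constant genes in a single bin; class labels
are categorical as-is. Entropy and mutual information use base-2 logs with
the p log p → 0 convention; symmetric uncertainty is SU = 2I/(H+H),
defined as 0 when both entropies vanish. The 10-bin equal-width choice
keeps the estimator deterministic and parameter-free; it is the classic
desktop-ML default for this family of filters.

**Selectors.** All three are deterministic; score ties always resolve to
the lower original feature index.

* *Ranking*: top-n genes by I(f; c).
* *FCBF*: rank by SU(c; f) descending, drop genes below δ, then walk the
  list removing every later f_i for which an earlier retained f_j
  satisfies SU(c; f_j) ≥ SU(c; f_i) and SU(f_i; f_j) ≥ SU(f_i; c).
  For a requested size n, note that any feature dominating f_i outranks
  f_i, so it survives every threshold that f_i survives; consequently the
  survivor set at threshold δ equals the δ = 0 survivor set restricted to
  SU ≥ δ. `fcbf_select_n` therefore runs the δ = 0 walk once and cuts the
  survivor list at the largest SU-boundary prefix not exceeding n. If even
  δ = 0 yields fewer than n survivors, the short set is returned and
  flagged; this propagates to a `short` flag on the fitted model.
* *mRMR*: candidates are restricted to the `window` (default 50) most
  relevant genes; the first pick maximises relevance, the m-th maximises
  I(f_j; c) − (1/(m−1)) Σ_{f_i∈S} I(f_i; f_j). The set-level redundancy
  R(S) = |S|⁻² Σ I(f_i; f_j) is available as a diagnostic
  (`subset_redundancy`) but is not what the greedy search optimises.
  Inside the iterative pipeline the pool is widened to
  max(window, target) so intermediate reductions larger than the window
  remain well-defined; a full search is available via window = N_M.

**Classifiers and voting.** KNN (K = 3) and a linear SVM (C = 1) stand
behind the model surface as scikit-learn estimators. Confidences are the
positive-neighbour fraction (KNN) or the logistic transform of the signed
decision value (SVM) — needed for AUC and tie-breaking. A member votes for
its class when it predicts positive; the class with most votes wins, ties
(including zero positive votes) broken by highest confidence, then larger
training class, then canonical (sorted) class order.

**Evaluation.** Stratified k-fold CV; `'auto'` picks 3 folds when the
smallest class has < 10 samples, else 10 — and falls back to leave-one-out
with a warning when the smallest class is below the fold count itself
(a 4-sample class cannot appear in every one of 3 folds). Accuracy and
macro one-vs-rest AUC (rank-based, ties counted half) are reported in
percent as unweighted means over folds; macro averaging weighs minority
classes equally, which is the point of the exercise. Per-class recall is
pooled over out-of-fold predictions.

## Reproducibility

Every random operation draws from `numpy.random.default_rng` seeded
through one hierarchical derivation (`derive_seed`, a multiply-add hash
kept below 2³¹): per class, per iteration step, per CV fold, per benchmark
cell. A cell of a benchmark grid is therefore reproducible in isolation,
and adding a class or a grid cell never perturbs the others.

## Synthetic data

The generator emulates imbalanced tumour-typing collections: Gaussian
log-intensity-like background (mean 0, SD `noise_sd`), K classes with
sizes given directly, and per class a disjoint block of
`n_informative_per_class` genes shifted by `effect_size · noise_sd` in
that class's samples. Optional equicorrelation within a block comes from a
shared Gaussian factor. The reference scenario — 5 classes of sizes
[100, 20, 20, 20, 20], 1000 genes, 15 informative per class, effect
1.5 SD, no correlation — is deliberately hard enough that selection
matters but solvable at desk scale; class-size presets mirror published
benchmark cohorts (14 × ~11-sample tumour types; 38/9/21/4; 58/28/40/42)
with the gene count scaled down to 2000 by default.

What the generator does **not** model: probe-level microarray noise,
intensity saturation, batch effects, heavy-tailed or skewed expression,
and cross-class marker overlap (blocks are disjoint unless requested).
Passing tests on this generator show the pipeline's mechanics and its
imbalance behaviour, not clinical performance on real cohorts.

## Numerical and design choices

* Equal-width discretization on the full current training split; no
  supervised (MDL) discretization — deliberately estimator-simple.
* Mutual information is clipped at 0 against float residue; SU symmetric
  to < 1e-12 by construction.
* FCBF on finely-binned continuous data is aggressive: with tens of
  samples and 10 bins, pairwise SU between high-cardinality features is
  upward-biased, so survivor sets are small and `short` results are
  common. This is inherent to the SU estimator at this sample size and is
  surfaced, not hidden.
* The loader rejects missing values by default; per-gene mean imputation
  is available behind an explicit flag. Duplicate identifiers and
  non-numeric cells are format errors naming the offender; classes with
  fewer than 2 samples are rejected (stratified CV and SMOTE both need 2).
* An optional per-gene z-score transform (`zscore`) is available for the
  distance-based steps and is off by default.
* Expression values round-trip through text formats at 8 significant
  digits.

## Problem sizes used by the test suite and acceptance script

Selector-vs-oracle comparisons run on 100 random 40 × 12 binary
instances; the reference-scenario experiment uses 10 replicate seeds with
3-fold stratified CV (valid since the smallest class has 20 samples) and
30-gene signatures. These sizes were chosen so the full suite documents
the method's behaviour in minutes on a laptop while keeping every
comparison statistically meaningful.

## Known limitations

* Signature sizes beyond the mRMR window require widening the window
  explicitly (the pipeline does this automatically; direct `mrmr_select`
  calls raise).
* Macro AUC is undefined under leave-one-out per-fold scoring; the report
  then carries NaN for AUC rather than a silently different estimator.
* The SVM confidence mapping (logistic of the decision value) is monotone
  but uncalibrated; votes and AUC ranks are unaffected, absolute
  confidence values should not be over-interpreted.
* GCT support targets the 1.2 dialect only, with labels in a two-column
  sidecar.
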