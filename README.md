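# threec — categorize–cluster–classify subtype discovery

`threec` implements the 3C procedure, a semi-unsupervised pipeline for
discovering severity subtypes in multi-domain clinical cohorts and
characterizing them with objective biomarkers. It was designed around the
setting of recent-trauma cohorts assessed for post-traumatic stress: a
clinician-administered severity score (CAPS total) anchors the analysis,
self-report clinical totals (PCL, BDI, BAI, CGI) define the subtypes, and
cognitive test scores, structural MRI volumes/thicknesses, and task-fMRI
activation/connectivity features serve as candidate biomarkers.

## The method

The pipeline runs in three stages plus evaluation:

1. **Categorize.** Every feature is assigned one of three roles: the
   *assigned diagnosis* (the field-standard severity score), *clinical
   measurements* (symptom scales describing the patient's condition), or
   *potential biomarkers* (objective measures not in clinical use),
   biomarkers carrying a domain tag (cognitive / structural / functional).
2. **Cluster.** Clinical measurements are screened supervised against the
   assigned diagnosis — Pearson correlation tests with Benjamini–Hochberg
   FDR control at the permissive level *q* = 0.2. The screened features
   (standardized) are clustered unsupervised by k-medoids (PAM: greedy
   BUILD initialization, deterministic SWAP local search) under the
   Manhattan metric; the number of clusters *k* is chosen by the gap
   statistic's one-standard-error rule,
   Gap(k) = E*[log W_k] − log W_k, with the mean silhouette width
   s(i) = (b−a)/max(a,b) as the second criterion.
3. **Classify.** Cluster membership is characterized through the
   biomarkers alone: random-forest variable importance (mean decrease
   Gini, optional out-of-bag permutation importance), a single CART
   classification tree with per-node counts and dominant-cluster
   proportions, and a marginal one-way ANOVA per biomarker with BH
   control at 0.05 across the whole biomarker family.
4. **Evaluate.** Cluster–diagnosis association by a pooled two-proportion
   Z test; cluster stability by repeated train/validate splits (train the
   screen + clustering + tree on a fraction *P* of subjects, classify the
   held-out subjects with the tree, score agreement with the full-data
   clusters after optimal label matching); bootstrap median profiles of
   the top biomarkers per cluster.

Preprocessing before stage 2: 5-nearest-neighbour imputation of missing
cells and per-feature monotone symmetrizing transforms (identity /
log-shift / square root / negative reciprocal, chosen to minimize |g1|
skewness).

A synthetic-cohort generator (`threec.synthetic`) emulates the target
study design — 101 subjects, 256 features (1 + 4 + 11 + 192 + 48), a
two-component latent severity mixture, planted informative biomarkers
among majority noise, ~1% missingness — so every stage is testable
without access to clinical data.

## Worked example

Run the full pipeline on a synthetic cohort from a YAML config:

```yaml
# cfg.yml
synthetic: {seed: 0}          # generate the default cohort (seed derived
seed: 3                       # from the master seed)
cluster: {gap_B: 100}
stability: {training_fractions: [0.2, 0.5, 0.9], iterations: 100}
```

```sh
threec run --config cfg.yml
```

prints (abridged):

```text
Clinical screening (vs assigned diagnosis):
  PCL          r=+0.714  p=5.29e-17  p_adj=2.12e-16  selected
  BDI          r=+0.639  p=6.32e-13  p_adj=6.32e-13  selected
  BAI          r=+0.675  p=1.03e-14  p_adj=1.37e-14  selected
  CGI          r=+0.680  p=5.55e-15  p_adj=1.11e-14  selected

Clustering: k=2 (metric=manhattan, mean silhouette=0.707)
  sizes: [59, 42]
  rationale: k=2 by gap one-SE rule (silhouette preferred 2)

Cluster-diagnosis association: Z=4.36 p=1.3e-05 (proportions 0.75 vs 0.31)

Top biomarkers by mean decrease Gini:
   1. structural:struct_002  importance=5.756
   2. structural:struct_001  importance=5.137
   3. cognitive:cog_02  importance=4.893
   ...

Classification tree:
HiClus (59/101 = 58%)
  struct_002 < 5.92651 -> HiClus (59/59 = 100%)
  struct_002 >= 5.92651 -> LoClus (42/42 = 100%)

Stability (train/validate cluster matching):
  P%   mean%   SD%   frac k=2
   20   95.9    2.6   fixed
   50   97.4    2.5   fixed
   90   98.1    3.9   fixed
```

Reading the output: all four clinical totals survive the *q* = 0.2
screen (correlations ≈ 0.64–0.71 with the severity score); gap and
silhouette agree on two clusters — a high- and a low-symptomatic subtype
(HiClus/LoClus, named by mean severity); the diagnosed proportion differs
sharply between clusters (0.75 vs 0.31, Z = 4.36); the forest ranks the
six planted biomarkers (here `struct_001/2`, `cog_01/2`, `func_01/2`)
above all 245 noise features; the tree recovers the subtype split from a
single planted structural feature; and trees trained on 20–90% subsamples
re-classify held-out subjects into their full-data clusters 96–98% of the
time.

Other entry points: `threec simulate --seed 1 --out dir` writes a
synthetic cohort as CSV + YAML category map; `threec stability` runs the
cross-validation grid only; `threec report saved/report.json` re-renders
a saved report. The same functionality is available as a library
(`threec.run_pipeline`, `threec.pam_cluster`, `threec.gap_curve`, …).

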