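# Methods

This note records the modelling assumptions, numerical choices, and known
limitations behind `threec`. It complements the README, which shows what
the pipeline does; here is why it does it that way.

## The 3C model and its assumptions

The pipeline assumes a cohort in which (i) a field-standard severity
score (the *assigned diagnosis*) is a noisy but informative proxy for the
clinical state, (ii) a small set of symptom scales (*clinical
measurements*) expresses that state more richly than the severity score
alone, and (iii) *potential biomarkers* — objective measurements — may
differ between latent sub-populations without being individually
diagnostic. Clusters are therefore built on the clinical scales (screened
against the severity score so irrelevant scales drop out), never on the
biomarkers; the biomarkers only *characterize* the clusters afterwards.
This ordering is the core design commitment: it keeps the subtype
definition clinically interpretable and leaves the biomarker analysis
honest (a biomarker that separates the clusters was not used to form
them).

## Preprocessing

**Imputation.** Missing cells are filled by the unweighted mean of the
feature's observed values among the 5 nearest subjects. Neighbour
distance is Euclidean over jointly observed columns after per-feature
standardization, rescaled by the number of jointly observed features so
subjects with different missingness patterns are comparable. Missingness
is assumed (and, in the generator, is) missing-completely-at-random; the
default rate is 1% of cells, and the implementation requires every
feature to be observed in at least k = 5 subjects. Imputation is
idempotent: a second pass is the identity.

**Symmetrizing transforms.** Each feature is transformed by the member
of the ordered family {identity, log(x+c), sqrt(x+c), −1/(x+c)} that
minimizes the absolute sample skewness g1 = m3/m2^{3/2} (biased central
moments), ties resolved toward the earlier member. The shift is
c = 1 − min(x) when min(x) ≤ 0 (c = −min(x) for the square root), else 0,
keeping arguments positive with minimal distortion. The reciprocal is
negated so every family member is strictly increasing: within-feature
rank order is preserved, and |g1| never increases. When a frozen
transform log is re-applied to new data (validation subjects in the
stability loop), arguments are clamped at a small positive floor, since
out-of-sample values can undershoot the fitted shift.

**Standardization.** The screened clinical features are centered and
scaled (SD, ddof = 1) before clustering; the four scales have
incommensurable ranges (e.g. a 17–85 checklist total vs a 1–7 global
impression), and unstandardized Manhattan distances would be dominated by
the widest scale. Zero-variance features are an error, not a silent
no-op.

## Cluster stage

**Screening.** Pearson correlation of each clinical feature with the
assigned-diagnosis score (Spearman available by config), BH-adjusted
within the clinical family, selected at adjusted p ≤ q = 0.2. The
permissive level is deliberate: the screen exists to drop clearly
irrelevant scales, not to control discovery. Zero-variance features are
flagged and excluded from the BH family.

**PAM.** k-medoids under the Manhattan metric, implemented as BUILD
(start from the 1-medoid optimum, greedily add the cost-minimizing
medoid) followed by steepest-descent SWAP over all single
medoid/non-medoid exchanges, ties always resolved toward the lowest row
index. The algorithm is fully deterministic — the pipeline's entire
stochasticity budget sits in the gap references, the forest, and the
resampling loops. Total cost never increases across SWAP steps, and on
small well-separated instances PAM attains the exhaustive-search optimum
(verified against complete medoid-subset enumeration in the validation
benchmarks). PAM is a local search: on non-separated or
effectively-degenerate instances (e.g. a nominal k above the number of
actual clusters) it can return a near-optimal rather than optimal
configuration.

**Gap statistic.** W_k is the total PAM cost; references are drawn
uniformly over each feature's observed range (the simpler of the two
published reference schemes), B = 100 by default;
s_k = SD_b(log W_k^ref) · sqrt(1 + 1/B). The curve is computed from
k = 1 so a "no cluster structure" outcome is visible in diagnostics, but
the default selection rule searches k ≥ 2 — the procedure presumes
subtypes exist, and k = 1 would make the downstream stages vacuous. The
selected k is the smallest with Gap(k) ≥ Gap(k+1) − s_{k+1}.

**k policy.** The default takes the gap one-SE choice and records
whether the silhouette argmax agrees; config can force
silhouette-priority or a fixed k. On cohorts with elongated, correlated
clusters the box-reference gap statistic is known to over-select (it
picks k = 3 on a minority of default synthetic cohorts, echoing the
~80% two-cluster rate the stability literature reports for such data);
the silhouette criterion is more conservative there, which is exactly why
both are computed and reported.

## Classify stage

**Forest importance.** scikit-learn random forest (500 trees,
sqrt-feature subsampling, bootstrap resamples of size n). Mean decrease
Gini is reported unnormalized and count-weighted (per-tree impurity
decrease × n, averaged over trees) so values are on the conventional
MeanDecreaseGini scale; rankings are identical to the normalized variant.
Out-of-bag permutation importance (per-tree OOB accuracy loss after
permuting one feature, averaged) is computed on request; Gini is the
primary index. No class reweighting is applied to the mild 57:44
imbalance.

**Tree.** CART with Gini impurity, midpoint split thresholds, minimum
node size 20, minimum leaf 7. The complexity penalty is implemented as
scikit-learn's `min_impurity_decrease` set to 0.01 × root impurity — an
analogue, not a replica, of relative-error pruning with cp = 0.01; both
stop splits whose improvement is below 1% of the root's. Nodes are
rendered as `feature < threshold -> dominant cluster (count/total = %)`.

**Marginal ANOVA.** One-way F per biomarker (vectorized sums of squares;
verified against `scipy.stats.f_oneway`), BH-adjusted jointly across all
251 biomarkers at q = 0.05. `anova_from_summary` evaluates the same F
from per-group means/SDs/ns — an exact algebraic identity with the
raw-data computation, useful for checking published summary tables.

## Evaluation

**Association.** Pooled two-proportion Z test,
Z = (p1 − p2)/sqrt(p̄(1−p̄)(1/n1 + 1/n2)), two-sided normal p, no
continuity correction — the variant that reproduces published values from
integer tables.

**Cluster matching.** Candidate labels are permuted to maximize
agreement with the reference: exhaustive over permutations for k ≤ 4,
Hungarian assignment on the contingency table beyond.

**Stability.** For each training fraction P ∈ {20%,…,90%} and
iteration: a simple random (unstratified) P-sample is drawn; imputation,
transforms, screening, clustering (k fixed at 2 by default — the study
practice — with re-estimation available to tally how often k = 2 is
chosen), and the tree are all re-fit on the training sample; validation
subjects are classified **by the training tree only** (not by distance to
medoids) and compared to the full-data clusters after label matching.
Preprocessing can be frozen to the full-data fit via
`refit_preprocess=False`. Iteration seeds derive deterministically from
(base seed, P, iteration index), so runs are reproducible and
parallelizable. Iterations whose training sample cannot be screened or
clustered are skipped and counted.

**Bootstrap profiles.** Subjects are resampled with replacement within
each cluster (B = 400); the statistic is the median; reported per
cluster/feature are the median of bootstrap medians and the 2.5/97.5
percentiles. Percentile intervals, no BCa correction.

## Synthetic cohort: what it emulates, and what it does not

The generator draws a latent subtype (high/low-symptomatic, expected mix
57:44) and, conditional on it, a severity score from a truncated normal
on [0, 136] with the published within-cluster moments (61.91 ± 18.16 vs
37.45 ± 23.12). Each clinical total is
`offset + shift·[high] + loading·severity + noise`: the subtype shifts
the self-report scales directly, beyond what severity explains — matching
the observed phenomenon that the clusters separate sharply on the
clinical scales while severity distributions overlap (including the
subgroup with high severity but low self-reports). The defaults place
~4 within-component SDs between subtypes on each clinical scale, which
keeps each scale's correlation with severity near 0.72 (the 0.6–0.8 band
in which all four scales survive the q = 0.2 screen essentially always)
and makes the clinical clusters track the latent subtype at agreement
0.98–1.0.

Biomarkers: 11 cognitive features on a z-score scale, 192 structural
features on a lognormal volume-like scale (feature-specific location,
log-SD 0.2 — these exercise the log transform), 48 functional features on
a correlation-like (−1, 1) scale via a tanh link. Six biomarkers (two per
domain) are planted with a standardized between-subtype difference of
3.5; the rest are independent noise. The planted effect is a
*validation* condition, calibrated so that the benchmarks the package
commits to are attainable — all six planted features in the forest's
top 10 of 251, and a training-half CART reproducing the full-data
clusters for ≥ 90% of held-out subjects. Real-cohort biomarker effects
are far weaker (in the target study, no biomarker survived FDR in the
marginal ANOVA); passing these benchmarks therefore shows the machinery
recovers signal **when it exists at clearly-separable strength**, not
that such signal exists in real data.

External diagnosis labels follow a threshold rule on severity
(default 45) with 15% label noise, yielding cluster-diagnosis
associations of the observed magnitude (Z ≈ 4–5) without being identical
to the clusters.

Other simplifications: features are conditionally independent given the
subtype (no biomarker–biomarker correlation structure, no site or age
effects); missingness is MCAR; clinical totals are Gaussian around their
conditional means rather than bounded integers.

## Benchmark protocol sizes

The validation benchmarks use: 200 random well-separated small instances
(n ≤ 8, k ≤ 3, center separation ≥ 5× within-cluster spread, every
cluster populated) for the PAM/exhaustive comparison; 1000 random
p-vectors for the BH step-up comparison; 100 separated two-component
cohorts for k-selection; 50 default cohorts for planted-biomarker
recovery; 100 all-null cohorts for the FDR null check; and a stability
grid of 8 training fractions × 60 iterations pooled over 3 independently
generated cohorts (pooling averages out cohort-level sampling luck in the
estimate; the across-cohort SD of the P = 50% mean is ≈ 1.4 points).

## Known limitations

* The gap statistic's box reference over-selects k on elongated
  correlated clusters; consensus or model-based alternatives are out of
  scope by design.
* The stability loop re-fits the screen but inherits the reference
  labels from one full-data clustering; if the full-data k is mis-chosen,
  matched percentages measure consistency with that choice, not truth.
* `anova_from_summary` is exact only for the one-way layout.
* The CLI's `simulate` writes the cohort with generated missingness;
  round-tripping through CSV preserves the missingness mask but not the
  latent ground truth, which is available only programmatically.
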