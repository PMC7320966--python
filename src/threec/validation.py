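"""Property-based validation benchmarks for the pipeline.

The study's exact importance values, tree thresholds, and stability
percentages depend on the original clinical dataset; what can be verified
on synthetic cohorts are the method's operating characteristics.  Each
function here measures one such characteristic from scratch under a
defined condition:

* PAM agrees with exhaustive medoid search on small separated instances;
* BH adjustment agrees with the direct step-up computation;
* gap + silhouette select k = 2 on well-separated two-component cohorts;
* the forest ranks all planted biomarkers in the top 10 of 251;
* with all-null biomarkers, BH at 0.05 yields no discoveries;
* the train/validate stability curve is high and rises with the
  training fraction.

These are the quantities reported by the acceptance script and asserted
by the acceptance tests.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .classify import ForestConfig, forest_importance, marginal_anova
from .cluster import (bh_adjust, choose_k, gap_curve, pam_cluster,
                      screen_clinical, silhouette_width)
from .preprocess import impute_knn, standardize, symmetrize
from .stability import StabilityConfig, _rank_clusters_by_severity, cross_validate
from .synthetic import SyntheticSpec, generate_dataset


def separated_cohort_spec(seed: int) -> SyntheticSpec:
    """A two-component cohort with component separation far above the
    within-component spread (>= 5x on every clinical scale): severity
    components 90 vs 20 (SD 7) and clinical totals driven by the subtype
    shift over isotropic noise."""
    return SyntheticSpec(
        seed=seed,
        component_means=(90.0, 20.0),
        component_sds=(7.0, 7.0),
        clinical_component_shifts=(40.0, 30.0, 30.0, 4.0),
        clinical_loadings=(0.0, 0.0, 0.0, 0.0),
        clinical_noise_sds=(3.5, 2.75, 2.75, 0.35),
    )


def null_cohort_spec(seed: int) -> SyntheticSpec:
    """Default cohort with every biomarker generated under the null."""
    return SyntheticSpec(seed=seed, effect_size=0.0, missingness=0.0)


def _screened_clinical_matrix(spec: SyntheticSpec):
    table, categories, _, truth = generate_dataset(spec)
    transformed, _ = symmetrize(impute_knn(table))
    screen = screen_clinical(transformed, categories)
    selected = screen.loc[screen["selected"], "feature"].tolist()
    X = standardize(transformed.subset_features(selected)).values
    return X, transformed, categories, truth


def brute_force_pam_cost(X: np.ndarray, k: int) -> float:
    """Exhaustive minimum total Manhattan cost over all medoid subsets."""
    D = cdist(X, X, metric="cityblock")
    return min(D[:, subset].min(axis=1).sum()
               for subset in itertools.combinations(range(len(X)), k))


def sample_separated_instance(rng: np.random.Generator,
                              k_max: int = 3, n_max: int = 8
                              ) -> tuple[np.ndarray, int]:
    """Small random instance whose cluster centers are >= 5x the unit
    within-cluster spread apart (the separation regime in which local
    search provably has an easy landscape)."""
    k = int(rng.integers(2, k_max + 1))
    n = int(rng.integers(max(4, 2 * k), n_max + 1))
    while True:
        centers = rng.uniform(-50.0, 50.0, size=(k, 2))
        pairdist = cdist(centers, centers, metric="cityblock")
        if (pairdist[np.triu_indices(k, 1)] >= 10.0).all():
            break
    # every cluster is populated (>= 2 points) so the instance truly has
    # k separated clusters rather than fewer
    assign = np.concatenate([np.repeat(np.arange(k), 2),
                             rng.integers(0, k, n - 2 * k)])
    X = centers[assign] + rng.normal(0.0, 1.0, size=(n, 2))
    return X, k


def pam_exhaustive_agreement(n_instances: int = 200, seed: int = 0) -> float:
    """Fraction of random small well-separated instances (n <= 8, k <= 3)
    on which PAM attains the exhaustive-search optimum."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_instances):
        X, k = sample_separated_instance(rng)
        hits += np.isclose(pam_cluster(X, k).cost,
                           brute_force_pam_cost(X, k))
    return hits / n_instances


def _stepup(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p, kind="stable")
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def bh_stepup_agreement(n_vectors: int = 1000, seed: int = 0) -> float:
    """Fraction of random p-vectors on which bh_adjust matches the direct
    step-up computation to 1e-12."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_vectors):
        m = int(rng.integers(1, 60))
        p = rng.random(m)
        adj, _ = bh_adjust(p)
        hits += bool(np.allclose(adj, _stepup(p), atol=1e-12))
    return hits / n_vectors


def k_selection_rate(n_seeds: int = 100, gap_B: int = 50,
                     seed: int = 0) -> float:
    """Fraction of well-separated two-component cohorts on which BOTH the
    gap one-SE rule and the silhouette argmax select k = 2."""
    hits = 0
    for i in range(n_seeds):
        X, *_ = _screened_clinical_matrix(
            separated_cohort_spec(seed * 100_003 + i))
        gap = gap_curve(X, k_max=6, B=gap_B, rng=seed * 7 + i + 1)
        D = cdist(X, X, metric="cityblock")
        sil = {k: silhouette_width(X, pam_cluster(X, k, D=D).labels)[1]
               for k in range(2, 7)}
        _, info = choose_k(gap, sil)
        hits += info["k_gap"] == 2 and info["k_silhouette"] == 2
    return hits / n_seeds


def _default_cohort_labels(spec: SyntheticSpec):
    X, transformed, categories, truth = _screened_clinical_matrix(spec)
    model = pam_cluster(X, 2)
    labels = _rank_clusters_by_severity(
        model.labels, transformed.column(categories.assigned_diagnosis_feature))
    return transformed, categories, truth, labels


def importance_recovery_rate(n_seeds: int = 50, n_trees: int = 500,
                             seed: int = 0) -> float:
    """Fraction of default cohorts on which every planted biomarker lands
    in the forest's top 10 of 251 (labels from two-cluster PAM on the
    screened clinical features)."""
    hits = 0
    for i in range(n_seeds):
        spec = SyntheticSpec(seed=seed * 99_991 + i)
        transformed, categories, truth, labels = _default_cohort_labels(spec)
        biomarkers = categories.biomarker_features
        Xb = transformed.subset_features(biomarkers).values
        imp = forest_importance(Xb, labels, biomarkers,
                                config=ForestConfig(n_trees=n_trees),
                                seed=seed + i)
        ranks = imp.set_index("feature")["rank"]
        hits += all(ranks[f] <= 10 for f in truth.planted_features)
    return hits / n_seeds


def anova_null_clean_rate(n_seeds: int = 100, q: float = 0.05,
                          seed: int = 0) -> float:
    """Fraction of all-null cohorts on which the BH-adjusted marginal
    ANOVA over all 251 biomarkers rejects nothing at the given level."""
    hits = 0
    for i in range(n_seeds):
        spec = null_cohort_spec(seed * 1_009 + i)
        table, categories, _, truth = generate_dataset(spec)
        biomarkers = categories.biomarker_features
        Xb = table.subset_features(biomarkers).values
        frame = marginal_anova(Xb, truth.component, biomarkers, q=q)
        hits += int(frame["significant"].sum()) == 0
    return hits / n_seeds


def stability_profile(seed: int = 0, iterations: int = 100,
                      fractions: tuple[float, ...] = (0.2, 0.3, 0.4, 0.5,
                                                      0.6, 0.7, 0.8, 0.9),
                      n_cohorts: int = 1) -> pd.DataFrame:
    """Train/validate matched-percentage curve on default cohorts with
    k fixed at 2 (the study's practice).

    With ``n_cohorts > 1`` the per-P statistics are pooled over
    independently generated cohorts, averaging out cohort-level luck in
    the estimate of the operating characteristic.
    """
    tables = []
    for c in range(n_cohorts):
        spec = SyntheticSpec(seed=seed * 31 + c)
        table, categories, _, _ = generate_dataset(spec)
        transformed, _ = symmetrize(impute_knn(table))
        screen = screen_clinical(transformed, categories)
        selected = screen.loc[screen["selected"], "feature"].tolist()
        X = standardize(transformed.subset_features(selected)).values
        labels = _rank_clusters_by_severity(
            pam_cluster(X, 2).labels,
            transformed.column(categories.assigned_diagnosis_feature))
        config = StabilityConfig(training_fractions=fractions,
                                 iterations=iterations,
                                 base_seed=seed * 31 + c, fixed_k=2)
        tables.append(cross_validate(table, categories, labels, config))
    if n_cohorts == 1:
        return tables[0]
    rows = []
    for i, p in enumerate(fractions):
        means = np.array([t.loc[i, "mean_matched_pct"] for t in tables])
        sds = np.array([t.loc[i, "sd_matched_pct"] for t in tables])
        rows.append({
            "p_train": p,
            "mean_matched_pct": float(means.mean()),
            # pooled spread: within-cohort variance plus cohort scatter
            "sd_matched_pct": float(np.sqrt(np.mean(sds**2)
                                            + means.var(ddof=0))),
            "frac_k2": None,
            "n_iterations": int(sum(t.loc[i, "n_iterations"]
                                    for t in tables)),
            "n_skipped": int(sum(t.loc[i, "n_skipped"] for t in tables)),
        })
    return pd.DataFrame(rows)
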