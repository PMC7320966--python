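"""Cluster-diagnosis association, label matching, cross-validated
stability, and bootstrap cluster profiles.

The stability procedure draws a training fraction P of subjects, reruns
screening + clustering + tree fitting on the training sample only,
classifies the held-out subjects with the training tree, and scores the
percentage that land in their full-data cluster after optimally matching
training cluster labels to the full-data ones.  Repeating over many
iterations and a grid of P values quantifies how much data the subtype
structure needs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment

from .classify import TreeConfig, fit_tree
from .cluster import (ClusterConfig, ScreeningConfig, cluster_clinical,
                      pam_cluster, screen_clinical)
from .datamodel import FeatureCategories, FeatureTable
from .preprocess import (PreprocessConfig, apply_transforms, impute_knn,
                         standardize, symmetrize)


@dataclass
class TwoByTwoTestResult:
    counts: np.ndarray          # rows: groups (clusters); cols: pos, neg
    p1: float
    p2: float
    pooled: float
    z: float
    p_value: float


@dataclass
class StabilityConfig:
    training_fractions: tuple[float, ...] = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7,
                                             0.8, 0.9)
    iterations: int = 1000
    base_seed: int = 0
    fixed_k: int | None = 2     # None -> re-estimate k each iteration
    refit_preprocess: bool = True

    def validate(self) -> None:
        if not all(0.0 < p < 1.0 for p in self.training_fractions):
            raise ValueError("training fractions must lie in (0, 1)")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class ProfileConfig:
    n_boot: int = 400
    percentiles: tuple[float, float] = (0.025, 0.975)

    def validate(self) -> None:
        if self.n_boot < 2:
            raise ValueError("n_boot must be >= 2")
        lo, hi = self.percentiles
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("percentiles must be ordered within (0, 1)")


def two_proportion_test(counts: np.ndarray | Sequence[Sequence[int]]
                        ) -> TwoByTwoTestResult:
    """Pooled two-sample Z test for equality of proportions.

    ``counts`` is 2x2 with rows = groups (by convention group 1 the
    higher-severity cluster) and columns = (positive, negative).
    Z = (p1 - p2) / sqrt(pbar (1 - pbar) (1/n1 + 1/n2)).
    """
    c = np.asarray(counts, dtype=float)
    if c.shape != (2, 2) or (c < 0).any():
        raise ValueError("counts must be a non-negative 2x2 table")
    n1, n2 = c.sum(axis=1)
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups must be non-empty")
    p1, p2 = c[0, 0] / n1, c[1, 0] / n2
    pooled = (c[0, 0] + c[1, 0]) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = 0.0 if se == 0 else (p1 - p2) / se
    p_value = 2 * stats.norm.sf(abs(z))
    return TwoByTwoTestResult(c.astype(int), float(p1), float(p2),
                              float(pooled), float(z), float(p_value))


def match_clusters(reference: Sequence[int], candidate: Sequence[int]
                   ) -> tuple[dict[int, int], float]:
    """Permute candidate labels to maximize agreement with the reference.

    Exhaustive over permutations for k <= 4; Hungarian assignment on the
    contingency table beyond.  Returns (candidate -> reference mapping,
    agreement fraction after relabeling).
    """
    ref = np.asarray(reference)
    cand = np.asarray(candidate)
    if ref.shape != cand.shape:
        raise ValueError("labelings must cover the same subjects")
    ref_levels = np.unique(ref)
    cand_levels = np.unique(cand)
    n = len(ref)
    # contingency[c, r] = #subjects with candidate level c and reference r
    cont = np.zeros((len(cand_levels), len(ref_levels)), dtype=int)
    for ci, c in enumerate(cand_levels):
        for ri, r in enumerate(ref_levels):
            cont[ci, ri] = int(((cand == c) & (ref == r)).sum())
    k = max(len(cand_levels), len(ref_levels))
    sq = np.zeros((k, k), dtype=int)
    sq[:cont.shape[0], :cont.shape[1]] = cont
    if k <= 4:
        best, best_perm = -1, None
        for perm in itertools.permutations(range(k)):
            agree = sum(sq[c, perm[c]] for c in range(k))
            if agree > best:
                best, best_perm = agree, perm
        col = list(best_perm)
    else:
        rows, cols = linear_sum_assignment(-sq)
        col = [0] * k
        for r_, c_ in zip(rows, cols):
            col[r_] = c_
        best = sq[rows, cols].sum()
    mapping = {}
    for ci in range(len(cand_levels)):
        ri = col[ci]
        mapping[int(cand_levels[ci])] = (int(ref_levels[ri])
                                         if ri < len(ref_levels)
                                         else int(cand_levels[ci]))
    return mapping, float(best) / n


def _rank_clusters_by_severity(labels: np.ndarray, severity: np.ndarray
                               ) -> np.ndarray:
    """Relabel clusters so 0 has the highest mean assigned-diagnosis score."""
    levels = np.unique(labels)
    order = sorted(levels, key=lambda c: -severity[labels == c].mean())
    remap = {c: i for i, c in enumerate(order)}
    return np.array([remap[c] for c in labels])


def cross_validate(table: FeatureTable, categories: FeatureCategories,
                   reference_labels: Sequence[int],
                   config: StabilityConfig | None = None,
                   screening: ScreeningConfig | None = None,
                   preprocess: PreprocessConfig | None = None,
                   cluster: ClusterConfig | None = None,
                   tree: TreeConfig | None = None) -> pd.DataFrame:
    """Train/validate cluster-matching stability over a grid of training
    fractions.

    ``table`` is the raw feature table (may contain missing cells);
    ``reference_labels`` are the full-data cluster labels.  Per fraction P
    and iteration: train the screen + PAM + tree on a simple random P
    sample, classify the validation subjects by the training tree, match
    training clusters to the reference, and record the matched percentage.
    Iterations whose training sample is too small to cluster or screen are
    skipped and counted.
    """
    config = config or StabilityConfig()
    config.validate()
    screening = screening or ScreeningConfig()
    preprocess_cfg = preprocess or PreprocessConfig()
    cluster_cfg = cluster or ClusterConfig()
    tree_cfg = tree or TreeConfig()
    ref = np.asarray(reference_labels)
    n = table.n_subjects
    severity_col = categories.assigned_diagnosis_feature
    biomarkers = categories.biomarker_features

    # full-table imputation computed once: validation subjects are always
    # completed from the whole cohort's neighbourhood structure
    full_imputed = impute_knn(table, preprocess_cfg)
    frozen = None
    if not config.refit_preprocess:
        frozen, _ = symmetrize(full_imputed, preprocess_cfg)

    rows = []
    for p_train in config.training_fractions:
        n_train = int(round(p_train * n))
        matched, k2, skipped = [], 0, 0
        for it in range(config.iterations):
            seed = _iteration_seed(config.base_seed, p_train, it)
            rng = np.random.default_rng(seed)
            train_idx = np.sort(rng.choice(n, size=n_train, replace=False))
            valid_idx = np.setdiff1d(np.arange(n), train_idx)
            try:
                if config.refit_preprocess:
                    sub_raw = table.subset_subjects(train_idx)
                    sub = impute_knn(sub_raw, preprocess_cfg)
                    sub, tlog = symmetrize(sub, preprocess_cfg)
                    val = apply_transforms(
                        full_imputed.subset_subjects(valid_idx), tlog)
                else:
                    sub = frozen.subset_subjects(train_idx)
                    val = frozen.subset_subjects(valid_idx)
                screen = screen_clinical(sub, categories, screening)
                sel = screen.loc[screen["selected"], "feature"].tolist()
                if not sel:
                    skipped += 1
                    continue
                Xc = standardize(sub.subset_features(sel)).values
                if config.fixed_k is not None:
                    k = config.fixed_k
                else:
                    k = cluster_clinical(Xc, cluster_cfg, rng).k
                if k == 2:
                    k2 += 1
                model = pam_cluster(Xc, k)
                train_labels = _rank_clusters_by_severity(
                    model.labels, sub.column(severity_col))
                Xb_train = sub.subset_features(biomarkers).values
                fitted = fit_tree(Xb_train, train_labels, biomarkers,
                                  tree_cfg)
                Xb_val = val.subset_features(biomarkers).values
                pred = fitted.predict(Xb_val)
            except ValueError:
                skipped += 1
                continue
            mapping, _ = match_clusters(ref[valid_idx], pred)
            relabeled = np.array([mapping[int(c)] for c in pred])
            matched.append(100.0 * (relabeled == ref[valid_idx]).mean())
        rows.append({
            "p_train": p_train,
            "mean_matched_pct": float(np.mean(matched)) if matched else np.nan,
            "sd_matched_pct": float(np.std(matched, ddof=1))
            if len(matched) > 1 else np.nan,
            "frac_k2": (k2 / max(len(matched), 1)
                        if config.fixed_k is None else None),
            "n_iterations": len(matched),
            "n_skipped": skipped,
        })
    return pd.DataFrame(rows)


def standardize_free_preprocess(table: FeatureTable,
                                config: PreprocessConfig) -> FeatureTable:
    """Impute and symmetrize once on the full table (frozen preprocessing)."""
    out = impute_knn(table, config)
    out, _ = symmetrize(out, config)
    return out


def _iteration_seed(base_seed: int, p_train: float, iteration: int) -> int:
    """Deterministic per-iteration seed from (base seed, P, index)."""
    return (base_seed * 1_000_003 + int(round(p_train * 100)) * 10_007
            + iteration) % (2**31 - 1)


def bootstrap_profile(X: np.ndarray, labels: Sequence[int],
                      feature_ids: Sequence[str],
                      config: ProfileConfig | None = None,
                      rng: np.random.Generator | int | None = None
                      ) -> pd.DataFrame:
    """Bootstrap median profiles per cluster and feature.

    Subjects are resampled with replacement within each cluster B times;
    the per-resample statistic is the median.  Reported per cluster and
    feature: the median of the bootstrap medians and the configured
    percentile interval.
    """
    config = config or ProfileConfig()
    config.validate()
    rng = np.random.default_rng(rng)
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    rows = []
    for c in np.unique(y):
        sub = X[y == c]
        if len(sub) < 2:
            raise ValueError(f"cluster {c} has fewer than 2 subjects")
        idx = rng.integers(0, len(sub), size=(config.n_boot, len(sub)))
        boots = np.median(sub[idx], axis=1)  # (B, p)
        med = np.median(boots, axis=0)
        lo = np.quantile(boots, config.percentiles[0], axis=0)
        hi = np.quantile(boots, config.percentiles[1], axis=0)
        for j, fid in enumerate(feature_ids):
            rows.append({"cluster": int(c), "feature": fid,
                         "median": float(med[j]),
                         "lo": float(lo[j]), "hi": float(hi[j])})
    return pd.DataFrame(rows)
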