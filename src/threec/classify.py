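"""Classify stage: characterize cluster membership with biomarkers.

Three complementary views of the same question -- which objective
biomarkers separate the clinical clusters:

* random-forest variable importance (mean decrease Gini, with optional
  out-of-bag permutation importance),
* a single CART classification tree rendered with per-node counts and
  dominant-cluster proportions,
* marginal one-way ANOVA per biomarker with Benjamini-Hochberg control of
  the false discovery rate across the whole biomarker family.

The forest and tree are fitted with scikit-learn; importance is reported
on the count-weighted (unnormalized) scale so values are comparable to
the conventional randomForest MeanDecreaseGini index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from .cluster import bh_adjust


@dataclass
class ForestConfig:
    n_trees: int = 500
    max_features: str | int = "sqrt"
    permutation: bool = False

    def validate(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class TreeConfig:
    min_split: int = 20
    min_leaf: int = 7
    complexity: float = 0.01   # fraction of root Gini impurity

    def validate(self) -> None:
        if self.min_split < 2 or self.min_leaf < 1:
            raise ValueError("invalid tree size parameters")
        if self.complexity < 0:
            raise ValueError("complexity penalty must be >= 0")


@dataclass
class TreeNode:
    """One node of the fitted classification tree."""

    n: int
    dominant: int
    proportion: float
    feature: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None    # feature < threshold
    right: "TreeNode | None" = None   # feature >= threshold

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def to_dict(self) -> dict:
        d = {"n": self.n, "dominant": self.dominant,
             "proportion": self.proportion}
        if not self.is_leaf:
            d.update(feature=self.feature, threshold=self.threshold,
                     left=self.left.to_dict(), right=self.right.to_dict())
        return d


@dataclass
class FittedTree:
    root: TreeNode
    estimator: DecisionTreeClassifier
    feature_ids: list[str]
    classes: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(np.asarray(X, dtype=float))

    def render(self, cluster_names: dict[int, str] | None = None) -> str:
        """Indented text in the ``feature < threshold -> dominant
        (count/total = %)`` convention."""
        names = cluster_names or {}
        lines: list[str] = []

        def describe(node: TreeNode) -> str:
            label = names.get(node.dominant, f"cluster{node.dominant}")
            k = int(round(node.proportion * node.n))
            return f"{label} ({k}/{node.n} = {100*node.proportion:.0f}%)"

        def walk(node: TreeNode, indent: int, prefix: str) -> None:
            lines.append("  " * indent + prefix + describe(node))
            if not node.is_leaf:
                walk(node.left, indent + 1,
                     f"{node.feature} < {node.threshold:g} -> ")
                walk(node.right, indent + 1,
                     f"{node.feature} >= {node.threshold:g} -> ")

        walk(self.root, 0, "")
        return "\n".join(lines)


def forest_importance(X: np.ndarray, labels: Sequence[int],
                      feature_ids: Sequence[str] | None = None,
                      domains: dict[str, str] | None = None,
                      config: ForestConfig | None = None,
                      seed: int = 0) -> pd.DataFrame:
    """Random-forest mean-decrease-Gini importance per biomarker.

    Importance is the impurity decrease attributed to splits on a feature,
    count-weighted and averaged over trees.  When ``config.permutation`` is
    set, out-of-bag permutation importance (mean accuracy loss over trees
    after permuting the feature among each tree's OOB samples) is added.
    Ranks are 1-based, ties broken by feature order.
    """
    config = config or ForestConfig()
    config.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    if np.isnan(X).any():
        raise ValueError("forest requires a complete matrix")
    if len(np.unique(y)) < 2:
        raise ValueError("forest requires at least two classes")
    n, p = X.shape
    feature_ids = list(feature_ids) if feature_ids is not None \
        else [f"f{j}" for j in range(p)]
    forest = RandomForestClassifier(
        n_estimators=config.n_trees, max_features=config.max_features,
        bootstrap=True, random_state=seed)
    forest.fit(X, y)
    # unnormalized impurity decrease (sample-fraction weighted) x n gives the
    # count-weighted MeanDecreaseGini scale
    mdi = np.mean(
        [t.tree_.compute_feature_importances(normalize=False)
         for t in forest.estimators_], axis=0) * n

    out = pd.DataFrame({"feature": feature_ids})
    out["domain"] = [domains.get(f, "") if domains else ""
                     for f in feature_ids]
    out["gini_importance"] = mdi
    order = np.lexsort((np.arange(p), -mdi))
    ranks = np.empty(p, dtype=int)
    ranks[order] = np.arange(1, p + 1)
    out["rank"] = ranks

    if config.permutation:
        rng = np.random.default_rng(seed)
        losses = np.zeros(p)
        counts = np.zeros(p)
        for t, samples in zip(forest.estimators_, forest.estimators_samples_):
            oob = np.setdiff1d(np.arange(n), samples)
            if len(oob) == 0:
                continue
            Xo, yo = X[oob], y[oob]
            base = (t.predict(Xo) == yo).mean()
            used = np.unique(t.tree_.feature)
            for j in used[used >= 0]:
                Xp = Xo.copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                losses[j] += base - (t.predict(Xp) == yo).mean()
                counts[j] += 1
            counts[np.setdiff1d(np.arange(p), used)] += 1  # loss 0
        out["permutation_importance"] = np.where(counts > 0,
                                                 losses / np.maximum(counts, 1),
                                                 0.0)
    return out.sort_values("rank").reset_index(drop=True)


def fit_tree(X: np.ndarray, labels: Sequence[int],
             feature_ids: Sequence[str] | None = None,
             config: TreeConfig | None = None) -> FittedTree:
    """CART classification tree (Gini impurity, midpoint thresholds).

    Growth stops when a node is smaller than ``min_split``, a child would
    fall below ``min_leaf``, or no split improves impurity by at least
    ``complexity`` x root impurity.  Degenerate single-class data yields a
    single leaf.
    """
    config = config or TreeConfig()
    config.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    if np.isnan(X).any():
        raise ValueError("tree requires a complete matrix")
    feature_ids = list(feature_ids) if feature_ids is not None \
        else [f"f{j}" for j in range(X.shape[1])]
    _, counts = np.unique(y, return_counts=True)
    root_gini = 1.0 - np.sum((counts / counts.sum()) ** 2)
    est = DecisionTreeClassifier(
        criterion="gini",
        min_samples_split=config.min_split,
        min_samples_leaf=config.min_leaf,
        min_impurity_decrease=config.complexity * root_gini,
        random_state=0)
    est.fit(X, y)
    tree = est.tree_
    classes = est.classes_

    def build(node_id: int) -> TreeNode:
        raw = tree.value[node_id][0]
        if raw.sum() <= 1.0 + 1e-9:  # class fractions (newer sklearn)
            raw = raw * tree.weighted_n_node_samples[node_id]
        node_counts = np.rint(raw).astype(int)
        n_node = int(node_counts.sum())
        dom = int(np.argmax(node_counts))
        prop = float(node_counts[dom] / n_node)
        if tree.children_left[node_id] == -1:
            return TreeNode(n_node, int(classes[dom]), prop)
        return TreeNode(
            n_node, int(classes[dom]), prop,
            feature=feature_ids[int(tree.feature[node_id])],
            threshold=float(tree.threshold[node_id]),
            left=build(int(tree.children_left[node_id])),
            right=build(int(tree.children_right[node_id])),
        )

    return FittedTree(build(0), est, feature_ids, classes)


def marginal_anova(X: np.ndarray, labels: Sequence[int],
                   feature_ids: Sequence[str] | None = None,
                   q: float = 0.05) -> pd.DataFrame:
    """Per-biomarker one-way ANOVA across clusters, BH-adjusted jointly.

    Vectorized over features; a zero-variance feature has undefined F and
    is flagged (excluded from the BH family, never significant).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    if np.isnan(X).any():
        raise ValueError("ANOVA requires a complete matrix")
    groups = np.unique(y)
    k = len(groups)
    if k < 2:
        raise ValueError("ANOVA requires at least two clusters")
    ns = np.array([(y == g).sum() for g in groups])
    if (ns < 2).any():
        raise ValueError("every cluster must contain at least two subjects")
    n, p = X.shape
    feature_ids = list(feature_ids) if feature_ids is not None \
        else [f"f{j}" for j in range(p)]
    grand = X.mean(axis=0)
    ss_between = np.zeros(p)
    ss_within = np.zeros(p)
    for g, ng in zip(groups, ns):
        sub = X[y == g]
        m = sub.mean(axis=0)
        ss_between += ng * (m - grand) ** 2
        ss_within += ((sub - m) ** 2).sum(axis=0)
    df1, df2 = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df1) / (ss_within / df2)
    total_var = X.var(axis=0)
    F[total_var == 0] = np.nan
    pvals = np.where(np.isnan(F), np.nan, stats.f.sf(F, df1, df2))
    frame = pd.DataFrame({"feature": feature_ids, "F": F,
                          "df1": df1, "df2": df2, "p": pvals})
    ok = frame["p"].notna().to_numpy()
    p_adj = np.full(p, np.nan)
    significant = np.zeros(p, dtype=bool)
    if ok.any():
        adj, rej = bh_adjust(frame.loc[ok, "p"].to_numpy(), q)
        p_adj[ok] = adj
        significant[ok] = rej
    frame["p_adj"] = p_adj
    frame["significant"] = significant
    return frame


def anova_from_summary(means: Sequence[float], sds: Sequence[float],
                       ns: Sequence[int]) -> tuple[float, tuple[int, int]]:
    """One-way ANOVA F from per-group summary statistics.

    F = [sum n_i (m_i - m_bar)^2 / (k-1)] / [sum (n_i - 1) s_i^2 / (N-k)],
    an exact algebraic identity with the raw-data ANOVA.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=int)
    if not (len(means) == len(sds) == len(ns)) or len(means) < 2:
        raise ValueError("need matching summaries for >= 2 groups")
    if (ns < 2).any():
        raise ValueError("every group needs n >= 2")
    if (sds < 0).any():
        raise ValueError("SDs must be non-negative")
    N = int(ns.sum())
    k = len(means)
    grand = float((ns * means).sum() / N)
    ms_between = float((ns * (means - grand) ** 2).sum() / (k - 1))
    ms_within = float(((ns - 1) * sds ** 2).sum() / (N - k))
    if ms_within == 0:
        return (float("inf") if ms_between > 0 else 0.0), (k - 1, N - k)
    return ms_between / ms_within, (k - 1, N - k)
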