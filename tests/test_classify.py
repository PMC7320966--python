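"""Forest importance, CART tree, marginal ANOVA."""

import numpy as np
import pytest
from scipy import stats

import threec as tc


def test_zero_variance_feature_has_zero_importance():
    rng = np.random.default_rng(0)
    X = np.column_stack([rng.normal(size=60), np.full(60, 3.0)])
    y = (X[:, 0] > 0).astype(int)
    imp = tc.forest_importance(X, y, ["signal", "flat"],
                               config=tc.ForestConfig(n_trees=50))
    table = imp.set_index("feature")
    assert table.loc["flat", "gini_importance"] == 0.0
    assert table.loc["signal", "rank"] == 1


def test_perfect_separator_ranked_first_across_seeds():
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        y = np.repeat([0, 1], 30)
        signal = np.where(y == 0, -2.0, 2.0) + rng.normal(0, 0.1, 60)
        X = np.column_stack([signal, rng.normal(size=(60, 50))])
        imp = tc.forest_importance(X, y, seed=seed,
                                   config=tc.ForestConfig(n_trees=200))
        hits += imp.iloc[0]["feature"] == "f0"
    assert hits == 10


def test_duplicated_informative_feature_shares_importance():
    rng = np.random.default_rng(5)
    y = np.repeat([0, 1], 40)
    signal = np.where(y == 0, -1.5, 1.5) + rng.normal(0, 0.5, 80)
    X = np.column_stack([signal, signal, rng.normal(size=(80, 20))])
    imp = tc.forest_importance(X, y, seed=0,
                               config=tc.ForestConfig(n_trees=300))
    table = imp.set_index("feature")
    noise_median = table.iloc[2:]["gini_importance"].median()
    assert table.loc["f0", "gini_importance"] > noise_median
    assert table.loc["f1", "gini_importance"] > noise_median
    # neither copy monopolizes the shared signal
    ratio = (table.loc["f0", "gini_importance"]
             / table.loc["f1", "gini_importance"])
    assert 0.25 < ratio < 4.0


def test_oob_permutation_importance_favors_signal():
    rng = np.random.default_rng(2)
    y = np.repeat([0, 1], 40)
    X = np.column_stack([np.where(y == 0, -2.0, 2.0)
                         + rng.normal(0, 0.3, 80),
                         rng.normal(size=(80, 10))])
    imp = tc.forest_importance(
        X, y, seed=1, config=tc.ForestConfig(n_trees=100, permutation=True))
    table = imp.set_index("feature")
    assert table.loc["f0", "permutation_importance"] > \
        table.iloc[1:]["permutation_importance"].max()


def test_forest_requires_two_classes():
    with pytest.raises(ValueError):
        tc.forest_importance(np.zeros((10, 2)), np.zeros(10, dtype=int))


# ---------------------------------------------------------------------------
# classification tree
# ---------------------------------------------------------------------------

def test_tree_pure_root_is_single_leaf():
    X = np.random.default_rng(0).normal(size=(30, 3))
    fitted = tc.fit_tree(X, np.zeros(30, dtype=int))
    assert fitted.root.is_leaf
    assert fitted.root.proportion == 1.0
    assert fitted.root.n == 30


def test_tree_splits_at_midpoint_of_straddling_values():
    """20 subjects below 5 in cluster A, 20 above in cluster B: the root
    threshold is the midpoint of the two adjacent sorted values."""
    lo = np.linspace(0.0, 4.5, 20)
    hi = np.linspace(5.5, 9.0, 20)
    X = np.concatenate([lo, hi])[:, None]
    y = np.repeat([0, 1], 20)
    fitted = tc.fit_tree(X, y, ["vol"])
    root = fitted.root
    assert not root.is_leaf
    assert root.feature == "vol"
    assert root.threshold == pytest.approx((4.5 + 5.5) / 2)
    assert root.left.is_leaf and root.left.proportion == 1.0
    assert root.right.is_leaf and root.right.proportion == 1.0
    assert root.left.n == 20 and root.right.n == 20


def test_tree_render_convention():
    lo = np.linspace(0.0, 4.5, 20)
    hi = np.linspace(5.5, 9.0, 20)
    X = np.concatenate([lo, hi])[:, None]
    y = np.repeat([0, 1], 20)
    fitted = tc.fit_tree(X, y, ["ec_volume"])
    text = fitted.render({0: "HiClus", 1: "LoClus"})
    assert "ec_volume < 5 -> HiClus (20/20 = 100%)" in text
    assert "ec_volume >= 5 -> LoClus (20/20 = 100%)" in text
    assert "/40" in text.splitlines()[0]  # root total annotated


def test_tree_training_accuracy_beats_baseline(clustered):
    transformed, categories, _, labels = clustered
    Xb = transformed.subset_features(categories.biomarker_features).values
    fitted = tc.fit_tree(Xb, labels, categories.biomarker_features)
    acc = (fitted.predict(Xb) == labels).mean()
    baseline = max(np.mean(labels == 0), np.mean(labels == 1))
    assert acc >= baseline


# ---------------------------------------------------------------------------
# marginal ANOVA
# ---------------------------------------------------------------------------

def test_anova_hand_computed_two_groups():
    X = np.array([0.0, 2.0, 2.0, 4.0])[:, None]
    y = np.array([0, 0, 1, 1])
    frame = tc.marginal_anova(X, y)
    assert frame.loc[0, "F"] == pytest.approx(2.0)
    assert frame.loc[0, "df1"] == 1 and frame.loc[0, "df2"] == 2


def test_anova_equal_means_not_significant():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(40, 3))
    y = np.repeat([0, 1], 20)
    frame = tc.marginal_anova(X, y)
    assert not frame["significant"].any()


def test_anova_matches_scipy_oracle():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(30, 8))
    y = rng.integers(0, 3, 30)
    while len(np.unique(y)) < 3 or min(np.bincount(y)) < 2:
        y = rng.integers(0, 3, 30)
    frame = tc.marginal_anova(X, y)
    for j in range(8):
        F, p = stats.f_oneway(*[X[y == g, j] for g in np.unique(y)])
        assert frame.loc[j, "F"] == pytest.approx(F, rel=1e-10)
        assert frame.loc[j, "p"] == pytest.approx(p, rel=1e-9)


def test_anova_flags_zero_variance_feature():
    X = np.column_stack([np.arange(10.0), np.full(10, 1.0)])
    y = np.repeat([0, 1], 5)
    frame = tc.marginal_anova(X, y)
    assert np.isnan(frame.loc[1, "F"])
    assert not frame.loc[1, "significant"]


def test_anova_from_summary_identities():
    assert tc.anova_from_summary([3.0, 3.0], [1.0, 1.0], [5, 5])[0] == 0.0
    F, df = tc.anova_from_summary([1.0, 3.0], [np.sqrt(2), np.sqrt(2)],
                                  [2, 2])
    assert F == pytest.approx(2.0)
    assert df == (1, 2)


def test_anova_from_summary_agrees_with_raw_data():
    rng = np.random.default_rng(21)
    for _ in range(25):
        k = rng.integers(2, 5)
        ns = rng.integers(2, 12, size=k)
        groups = [rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2), n)
                  for n in ns]
        X = np.concatenate(groups)[:, None]
        y = np.concatenate([np.full(n, i) for i, n in enumerate(ns)])
        raw = tc.marginal_anova(X, y)
        F, df = tc.anova_from_summary(
            [g.mean() for g in groups],
            [g.std(ddof=1) for g in groups],
            ns.tolist())
        assert F == pytest.approx(raw.loc[0, "F"], rel=1e-9)
        assert df == (raw.loc[0, "df1"], raw.loc[0, "df2"])
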