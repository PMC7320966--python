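"""Screening, BH adjustment, PAM, silhouette, gap statistic, k choice."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import threec as tc
from threec.cluster import gap_curve, gap_one_se_choice

from conftest import make_table


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def stepup_oracle(p):
    """Direct BH step-up computation: p_(i) * m / i with monotonicity
    enforced from the largest p downward."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def test_bh_single_p_is_identity():
    adj, rej = tc.bh_adjust([0.03], q=0.05)
    assert adj[0] == pytest.approx(0.03)
    assert rej[0]


def test_bh_hand_computed_stepup():
    adj, _ = tc.bh_adjust([0.01, 0.04, 0.03, 0.005], q=0.05)
    np.testing.assert_allclose(adj, [0.02, 0.04, 0.04, 0.02])


def test_bh_ties_unchanged():
    adj, _ = tc.bh_adjust([0.05] * 10, q=0.05)
    np.testing.assert_allclose(adj, [0.05] * 10)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        tc.bh_adjust([0.5, 1.5])


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                max_size=40))
def test_bh_matches_stepup_oracle(pvals):
    adj, _ = tc.bh_adjust(pvals)
    np.testing.assert_allclose(adj, stepup_oracle(pvals), atol=1e-12)


# ---------------------------------------------------------------------------
# clinical screening
# ---------------------------------------------------------------------------

def test_screen_perfect_association_selected():
    rng = np.random.default_rng(0)
    y = rng.normal(size=40)
    values = np.column_stack([y, y, rng.normal(size=40)])
    table = make_table(values, feature_ids=["CAPS", "dup", "noise"])
    cats = tc.FeatureCategories(
        {"CAPS": "assigned_diagnosis", "dup": "clinical",
         "noise": "clinical"})
    screen = tc.screen_clinical(table, cats)
    row = screen.set_index("feature")
    assert row.loc["dup", "p"] < 1e-12
    assert row.loc["dup", "selected"]


def test_screen_selects_all_four_clinical_totals(preprocessed):
    transformed, categories, *_ = preprocessed
    screen = tc.screen_clinical(transformed, categories)
    assert screen["selected"].all()
    assert set(screen["feature"]) == {"PCL", "BDI", "BAI", "CGI"}


def test_screen_null_selection_rate_matches_level():
    """A single pure-noise clinical feature is selected at ~q = 0.2 (with
    m = 1 the BH screen reduces to the raw p threshold)."""
    n, sims = 101, 1500
    rng = np.random.default_rng(42)
    x = rng.normal(size=(sims, n))
    y = rng.normal(size=(sims, n))
    xz = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
    yz = (y - y.mean(1, keepdims=True)) / y.std(1, keepdims=True)
    r = (xz * yz).mean(axis=1)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    from scipy import stats
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    rate = (p <= 0.2).mean()
    assert rate == pytest.approx(0.2, abs=0.025)


def test_screen_flags_constant_feature():
    values = np.column_stack([np.arange(10.0), np.full(10, 3.0)])
    table = make_table(values, feature_ids=["CAPS", "flat"])
    cats = tc.FeatureCategories(
        {"CAPS": "assigned_diagnosis", "flat": "clinical"})
    screen = tc.screen_clinical(table, cats)
    row = screen.set_index("feature").loc["flat"]
    assert np.isnan(row["p"]) and not row["selected"]


# ---------------------------------------------------------------------------
# PAM
# ---------------------------------------------------------------------------

def test_manhattan_distance_basics():
    assert tc.manhattan_distance([1, 2], [1, 2]) == 0.0
    assert tc.manhattan_distance([0, 0], [3, 4]) == 7.0
    rng = np.random.default_rng(1)
    a, b = rng.normal(size=5), rng.normal(size=5)
    assert tc.manhattan_distance(a, b) == pytest.approx(
        tc.manhattan_distance(b, a))
    with pytest.raises(ValueError):
        tc.manhattan_distance([1], [1, 2])


def brute_force_pam_cost(X, k):
    """Exhaustive minimum total Manhattan cost over all medoid subsets."""
    from scipy.spatial.distance import cdist
    D = cdist(X, X, metric="cityblock")
    best = np.inf
    for subset in itertools.combinations(range(len(X)), k):
        cost = D[:, subset].min(axis=1).sum()
        best = min(best, cost)
    return best


def test_pam_every_point_its_own_medoid():
    X = np.arange(5.0)[:, None]
    model = tc.pam_cluster(X, 5)
    assert model.cost == 0.0
    assert sorted(model.medoid_indices) == list(range(5))


def test_pam_two_separated_triplets():
    X = np.array([0.0, 1.0, 2.0, 10.0, 11.0, 12.0])[:, None]
    model = tc.pam_cluster(X, 2)
    assert sorted(model.medoid_indices) == [1, 4]  # values {1, 11}
    assert model.cost == 4.0
    np.testing.assert_array_equal(model.labels, [0, 0, 0, 1, 1, 1])


def test_pam_matches_exhaustive_search_on_separated_instances():
    from threec.validation import sample_separated_instance
    rng = np.random.default_rng(7)
    for _ in range(40):
        X, k = sample_separated_instance(rng)
        model = tc.pam_cluster(X, k)
        assert model.cost == pytest.approx(brute_force_pam_cost(X, k))


def test_pam_partition_invariant_to_subject_order():
    rng = np.random.default_rng(12)
    X = np.vstack([rng.normal(0, 1, (10, 3)), rng.normal(8, 1, (10, 3))])
    perm = rng.permutation(len(X))
    a = tc.pam_cluster(X, 2).labels
    b = tc.pam_cluster(X[perm], 2).labels
    _, agreement = tc.match_clusters(a[perm], b)
    assert agreement == 1.0


def test_pam_rejects_k_beyond_distinct_rows():
    X = np.array([[1.0], [1.0], [2.0]])
    with pytest.raises(ValueError):
        tc.pam_cluster(X, 3)


# ---------------------------------------------------------------------------
# silhouette
# ---------------------------------------------------------------------------

def test_silhouette_coincident_pairs():
    X = np.array([[0.0], [0.0], [9.0], [9.0]])
    _, mean_s = tc.silhouette_width(X, [0, 0, 1, 1])
    assert mean_s == pytest.approx(1.0)


def test_silhouette_hand_computed():
    # {0,1,9,10} labelled AABB: s = (8.5/9.5, 7.5/8.5, 7.5/8.5, 8.5/9.5)
    X = np.array([[0.0], [1.0], [9.0], [10.0]])
    s, mean_s = tc.silhouette_width(X, [0, 0, 1, 1])
    np.testing.assert_allclose(
        s, [8.5 / 9.5, 7.5 / 8.5, 7.5 / 8.5, 8.5 / 9.5])
    assert mean_s == pytest.approx(0.888545, abs=1e-5)


def test_silhouette_singleton_contributes_zero():
    X = np.array([[0.0], [1.0], [50.0]])
    s, _ = tc.silhouette_width(X, [0, 0, 1])
    assert s[2] == 0.0


def test_silhouette_requires_two_clusters():
    with pytest.raises(ValueError):
        tc.silhouette_width(np.zeros((4, 1)), [0, 0, 0, 0])


# ---------------------------------------------------------------------------
# gap statistic and k choice
# ---------------------------------------------------------------------------

def test_gap_cost_curve_non_increasing():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(30, 3))
    gap = gap_curve(X, k_max=5, B=12, rng=0)
    w = np.exp(gap.log_w)
    assert np.all(np.diff(w) <= 1e-9)


def test_gap_two_blobs_selects_two():
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(0, 1, (25, 2)),
                       rng.normal(10, 1, (25, 2))])
        gap = gap_curve(X, k_max=5, B=50, rng=seed + 100)
        hits += gap.k_hat == 2
    assert hits >= 9


def test_gap_uniform_box_prefers_no_clusters():
    hits = 0
    for seed in range(8):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0, 1, size=(40, 2))
        gap = gap_curve(X, k_max=4, B=30, rng=seed)
        hits += gap.k_hat == 1
        assert np.max(np.abs(gap.gap)) < 0.5
    assert hits >= 6


def test_gap_rejects_constant_data():
    with pytest.raises(ValueError):
        gap_curve(np.ones((10, 2)), k_max=3, B=10, rng=0)


def test_choose_k_policies():
    gap = tc.GapResult(
        ks=np.arange(1, 5),
        gap=np.array([0.1, 0.9, 0.7, 0.6]),
        s_k=np.array([0.05, 0.05, 0.05, 0.05]),
        log_w=np.zeros(4), log_w_ref=np.zeros(4), k_hat=2)
    sil = {2: 0.6, 3: 0.4, 4: 0.2}
    k, info = tc.choose_k(gap, sil)
    assert k == 2 and info["agreement"]

    sil_disagree = {2: 0.3, 3: 0.7, 4: 0.2}
    k, info = tc.choose_k(gap, sil_disagree)
    assert k == 2 and not info["agreement"]
    assert info["k_silhouette"] == 3

    cfg = tc.ClusterConfig(k_policy="fixed", fixed_k=2)
    k, info = tc.choose_k(gap, sil_disagree, cfg)
    assert k == 2 and "fixed" in info["rationale"]


def test_gap_one_se_choice_respects_min_k():
    gap = tc.GapResult(
        ks=np.arange(1, 5),
        gap=np.array([0.9, 0.8, 0.75, 0.7]),
        s_k=np.full(4, 0.05),
        log_w=np.zeros(4), log_w_ref=np.zeros(4), k_hat=1)
    assert gap_one_se_choice(gap, min_k=1) == 1
    assert gap_one_se_choice(gap, min_k=2) == 2


def test_default_cohort_clusters_recover_planted_components(clustered):
    """Two-cluster PAM on the screened clinical features agrees with the
    planted severity components at >= 0.8 after label matching."""
    _, _, truth, labels = clustered
    _, agreement = tc.match_clusters(truth.component, labels)
    assert agreement >= 0.8
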