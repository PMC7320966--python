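"""Two-proportion test, cluster matching, cross-validation, bootstrap."""

import numpy as np
import pytest

import threec as tc


# ---------------------------------------------------------------------------
# two-proportion Z test
# ---------------------------------------------------------------------------

def test_two_proportion_equal_is_zero():
    res = tc.two_proportion_test([[10, 10], [5, 5]])
    assert res.z == 0.0


def test_two_proportion_hand_computed():
    # 9/10 vs 1/10, pooled 0.5: Z = 0.8 / sqrt(0.25 * 0.2)
    res = tc.two_proportion_test([[9, 1], [1, 9]])
    assert res.z == pytest.approx(3.5777, abs=1e-4)
    assert res.p_value < 0.001


def test_two_proportion_antisymmetric():
    a = tc.two_proportion_test([[30, 12], [8, 25]])
    b = tc.two_proportion_test([[8, 25], [30, 12]])
    assert a.z == pytest.approx(-b.z)


def test_two_proportion_rejects_empty_group():
    with pytest.raises(ValueError):
        tc.two_proportion_test([[0, 0], [3, 4]])


# ---------------------------------------------------------------------------
# cluster matching
# ---------------------------------------------------------------------------

def test_match_identical_labelings():
    mapping, agreement = tc.match_clusters([0, 0, 1, 1], [0, 0, 1, 1])
    assert agreement == 1.0
    assert mapping == {0: 0, 1: 1}


def test_match_swapped_names():
    mapping, agreement = tc.match_clusters([0, 0, 1, 1], [1, 1, 0, 0])
    assert agreement == 1.0
    assert mapping == {1: 0, 0: 1}


def test_match_partial_agreement():
    _, agreement = tc.match_clusters([0, 0, 1, 1], [0, 1, 1, 1])
    assert agreement == 0.75


def test_match_beats_chance_for_random_labelings():
    rng = np.random.default_rng(8)
    for k in (2, 3, 5):
        ref = rng.integers(0, k, 60)
        cand = rng.integers(0, k, 60)
        _, agreement = tc.match_clusters(ref, cand)
        assert agreement >= 1.0 / k


def test_match_rejects_size_mismatch():
    with pytest.raises(ValueError):
        tc.match_clusters([0, 1], [0, 1, 1])


# ---------------------------------------------------------------------------
# cross-validated stability
# ---------------------------------------------------------------------------

def test_cross_validate_reports_grid_and_is_reproducible(default_cohort,
                                                         clustered):
    table, categories, *_ = default_cohort
    *_, labels = clustered
    cfg = tc.StabilityConfig(training_fractions=(0.3, 0.6),
                             iterations=8, base_seed=3)
    a = tc.cross_validate(table, categories, labels, cfg)
    b = tc.cross_validate(table, categories, labels, cfg)
    assert list(a["p_train"]) == [0.3, 0.6]
    assert set(a.columns) >= {"p_train", "mean_matched_pct",
                              "sd_matched_pct", "n_skipped"}
    assert a["mean_matched_pct"].between(0, 100).all()
    assert (a["sd_matched_pct"] >= 0).all()
    np.testing.assert_allclose(a["mean_matched_pct"], b["mean_matched_pct"])


def test_cross_validate_strong_separation_high_agreement(default_cohort,
                                                         clustered):
    """With the default planted-biomarker signal, a tree trained on half
    the sample reproduces the full-data clusters for most held-out
    subjects."""
    table, categories, *_ = default_cohort
    *_, labels = clustered
    cfg = tc.StabilityConfig(training_fractions=(0.5,), iterations=15,
                             base_seed=1)
    out = tc.cross_validate(table, categories, labels, cfg)
    assert out.loc[0, "mean_matched_pct"] >= 85.0


def test_cross_validate_can_reestimate_k(default_cohort, clustered):
    table, categories, *_ = default_cohort
    *_, labels = clustered
    cfg = tc.StabilityConfig(training_fractions=(0.7,), iterations=4,
                             base_seed=2, fixed_k=None)
    cluster_cfg = tc.ClusterConfig(gap_B=15, k_max=4)
    out = tc.cross_validate(table, categories, labels, cfg,
                            cluster=cluster_cfg)
    assert 0.0 <= out.loc[0, "frac_k2"] <= 1.0


# ---------------------------------------------------------------------------
# bootstrap profiles
# ---------------------------------------------------------------------------

def test_bootstrap_constant_feature_zero_width():
    X = np.column_stack([np.full(20, 4.0)])
    y = np.repeat([0, 1], 10)
    prof = tc.bootstrap_profile(X, y, ["c"], rng=0)
    assert (prof["hi"] - prof["lo"]).max() == 0.0
    assert (prof["median"] == 4.0).all()


def test_bootstrap_interval_covers_true_median():
    """The percentile interval of bootstrap medians covers the population
    median near the nominal 95% rate."""
    covered = 0
    reps = 60
    cfg = tc.ProfileConfig(n_boot=200)
    for rep in range(reps):
        rng = np.random.default_rng(rep)
        X = rng.normal(size=(50, 1))
        prof = tc.bootstrap_profile(X, np.zeros(50, dtype=int), ["x"],
                                    cfg, rng=rep + 1000)
        covered += prof.loc[0, "lo"] <= 0.0 <= prof.loc[0, "hi"]
    assert covered / reps >= 0.85


def test_bootstrap_rows_per_cluster_and_feature():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(30, 3))
    y = np.repeat([0, 1], 15)
    prof = tc.bootstrap_profile(X, y, ["a", "b", "c"], rng=0)
    assert len(prof) == 6
    assert set(prof["cluster"]) == {0, 1}


def test_bootstrap_rejects_tiny_cluster():
    X = np.zeros((3, 1))
    with pytest.raises(ValueError):
        tc.bootstrap_profile(X, [0, 0, 1], ["x"], rng=0)
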