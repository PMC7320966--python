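import numpy as np
import pytest

import threec as tc
from threec.stability import _rank_clusters_by_severity


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort, shared across tests."""
    return tc.generate_dataset(tc.SyntheticSpec(seed=11))


@pytest.fixture(scope="session")
def preprocessed(default_cohort):
    table, categories, diagnosis, truth = default_cohort
    complete = tc.impute_knn(table)
    transformed, tlog = tc.symmetrize(complete)
    return transformed, categories, diagnosis, truth, tlog


@pytest.fixture(scope="session")
def clustered(preprocessed):
    """Screened + clustered default cohort with severity-ranked labels."""
    transformed, categories, diagnosis, truth, _ = preprocessed
    screen = tc.screen_clinical(transformed, categories)
    selected = screen.loc[screen["selected"], "feature"].tolist()
    clin = tc.standardize(transformed.subset_features(selected))
    model = tc.pam_cluster(clin.values, 2)
    labels = _rank_clusters_by_severity(
        model.labels, transformed.column("CAPS"))
    return transformed, categories, truth, labels


def make_table(values, subject_ids=None, feature_ids=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return tc.FeatureTable(
        subject_ids or [f"s{i}" for i in range(n)],
        feature_ids or [f"f{j}" for j in range(p)],
        values,
        np.isnan(values),
    )
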