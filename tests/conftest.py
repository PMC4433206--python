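import numpy as np
import pytest
from hypothesis import settings

from ocri.amplify import transform_cohort
from ocri.io import FeatureMatrix
from ocri.model import tune_and_train_svm
from ocri.synthetic import reference_mixture, simulate_case, simulate_cohort

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_case():
    """One 4000-cell draw from the reference three-population mixture."""
    return simulate_case(reference_mixture(4000, seed=0), case_id="ref0")


@pytest.fixture(scope="session")
def small_cohort():
    """12 normal + 6 OLK + 12 OSCC cases at modest cell counts."""
    return simulate_cohort(12, 6, 12, seed=5, cells_range=(600, 1200))


@pytest.fixture(scope="session")
def cohort_features(small_cohort):
    vectors, skipped = transform_cohort(small_cohort, seed=11)
    assert not skipped
    return FeatureMatrix.from_vectors(vectors)


@pytest.fixture(scope="session")
def two_class_features(cohort_features):
    keep = [
        i for i, lab in enumerate(cohort_features.labels) if lab in ("normal", "oscc")
    ]
    return FeatureMatrix(
        case_ids=[cohort_features.case_ids[i] for i in keep],
        labels=[cohort_features.labels[i] for i in keep],
        values=cohort_features.values[keep],
    )


@pytest.fixture(scope="session")
def trained_model(two_class_features):
    return tune_and_train_svm(two_class_features, seed=3)


@pytest.fixture(scope="session")
def separable_matrix():
    """Quick two-class feature matrix with well-separated Gaussian columns."""
    rng = np.random.default_rng(0)
    n0, n1 = 35, 30
    v0 = np.clip(rng.normal(0.3, 0.05, (n0, 16)), 0.0001, None)
    v1 = np.clip(rng.normal(0.5, 0.05, (n1, 16)), 0.0001, None)
    return FeatureMatrix(
        case_ids=[f"c{i}" for i in range(n0 + n1)],
        labels=["normal"] * n0 + ["oscc"] * n1,
        values=np.vstack([v0, v1]),
    )
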