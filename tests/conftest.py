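import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import propnma as P

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_studies():
    """The packaged 10-study MRI Alzheimer's-classification evidence base."""
    return P.load_fixture("table1")


@pytest.fixture(scope="session")
def accuracy_model(fixture_studies):
    """Accuracy network restricted to the SVM-connected component."""
    return P.NetworkMetaAnalysis.from_studies(
        fixture_studies, "accuracy", reference="SVM", component="SVM"
    )


@pytest.fixture(scope="session")
def accuracy_fit(accuracy_model):
    return accuracy_model.fit("random")


@pytest.fixture(scope="session")
def triangle_spec():
    """Consistent three-treatment synthetic network with mild heterogeneity."""
    return P.SyntheticNetworkSpec(
        treatments=("A", "B", "C"),
        reference="A",
        true_basic_effects={"B": 0.4, "C": 0.8},
        baseline_logit=0.5,
        tau2_true=0.03,
        designs=(
            P.DesignSpec(treatments=("A", "B"), n_studies=4, n_per_arm=300),
            P.DesignSpec(treatments=("A", "C"), n_studies=4, n_per_arm=300),
            P.DesignSpec(treatments=("B", "C"), n_studies=4, n_per_arm=300),
        ),
        seed=11,
    )


@pytest.fixture(scope="session")
def triangle_model(triangle_spec):
    studies = P.simulate_network(triangle_spec)
    return P.NetworkMetaAnalysis.from_studies(studies, "accuracy", reference="A")


def pairwise_dl_oracle(effects, variances):
    """Independently coded textbook two-treatment meta-analysis.

    Inverse-variance fixed effect, Cochran's Q, DerSimonian-Laird moment
    tau2, and the random-effects pooled estimate.  Used as the oracle the
    network engine must reduce to on two-treatment data.
    """
    d = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    w = 1.0 / v
    mu_fixed = float(np.sum(w * d) / np.sum(w))
    se_fixed = float(1.0 / np.sqrt(np.sum(w)))
    q = float(np.sum(w * (d - mu_fixed) ** 2))
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - (len(d) - 1)) / c) if len(d) > 1 else 0.0
    wr = 1.0 / (v + tau2)
    mu_rand = float(np.sum(wr * d) / np.sum(wr))
    se_rand = float(1.0 / np.sqrt(np.sum(wr)))
    return {
        "mu_fixed": mu_fixed, "se_fixed": se_fixed, "q": q,
        "tau2": tau2, "mu_random": mu_rand, "se_random": se_rand,
    }
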