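import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gripmr import HarmonizedPair, load_exposure_fixture, load_outcome_fixture

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def exposures():
    return load_exposure_fixture()


@pytest.fixture(scope="session")
def cad_outcomes():
    return load_outcome_fixture("cad")


def make_pair(E, D, s, scale="log-odds", snp_id="snp1"):
    """Harmonized pair with placeholder alleles, for estimator tests."""
    return HarmonizedPair(
        snp_id=snp_id,
        effect_allele="A",
        other_allele="G",
        exposure_beta=float(E),
        exposure_se=0.05,
        outcome_beta=float(D),
        outcome_se=float(s),
        outcome_scale=scale,
    )


def random_instance(rng, k=None):
    """Random IVW problem: non-degenerate exposure effects, positive SEs."""
    if k is None:
        k = int(rng.integers(1, 11))
    E = rng.uniform(0.05, 2.0, size=k) * rng.choice([-1.0, 1.0], size=k)
    D = rng.normal(0.0, 0.5, size=k)
    s = rng.uniform(0.01, 1.0, size=k)
    return [make_pair(E[i], D[i], s[i], snp_id=f"snp{i+1}") for i in range(k)]


def wls_origin_oracle(pairs):
    """Brute-force weighted least squares through the origin.

    Independent of the estimator under test: accumulates the two normal-
    equation sums in a plain Python loop and solves for the slope and its
    variance directly.
    """
    sum_ede = 0.0
    sum_e2 = 0.0
    for p in pairs:
        w = 1.0 / (p.outcome_se * p.outcome_se)
        sum_ede += p.exposure_beta * p.outcome_beta * w
        sum_e2 += p.exposure_beta * p.exposure_beta * w
    return sum_ede / sum_e2, (1.0 / sum_e2) ** 0.5
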