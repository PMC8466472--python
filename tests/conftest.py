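import pytest
from hypothesis import settings

from mrnaplant.rsm import CodedRSM
from mrnaplant.scenario import baseline_scenario

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def baseline():
    return baseline_scenario()


@pytest.fixture(scope="session")
def biomass_rsm():
    """Linear screening model of the perfusion biomass production rate
    (g/h) in coded recycle-condensation / bleed / residence-time factors."""
    return CodedRSM(
        factor_names=["A", "B", "C"],
        coding_ranges={"A": (1.0, 3.0), "B": (0.05, 0.5), "C": (10.0, 40.0)},
        coefficients={"Intercept": 464.0, "A": -0.0079, "B": 153.87,
                      "C": -114.82},
        response_name="biomass_production_rate")


@pytest.fixture(scope="session")
def rna_rate_rsm():
    """Full quadratic model of the IVT RNA production rate in coded
    polymerase / UTP / magnesium concentration factors."""
    return CodedRSM(
        factor_names=["A", "B", "C"],
        coding_ranges={"A": (0.1, 0.5), "B": (0.4, 4.0), "C": (2.0, 14.0)},
        coefficients={"Intercept": 1.03, "A": 0.0146, "B": 0.3218,
                      "C": 0.0144, "A*B": -0.0889, "A*C": -0.01001,
                      "B*C": -0.0161, "A^2": 0.0308, "B^2": -0.3152,
                      "C^2": 0.0427},
        response_name="rna_production_rate")
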