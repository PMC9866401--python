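import numpy as np
import pytest

import stemtherm as st


@pytest.fixture(scope="session")
def fixture_models():
    """The four shipped species models (cv = 0.15)."""
    return st.load_fixtures()


@pytest.fixture(scope="session")
def all_fixture_curves(fixture_models):
    """(species, stage, TPCParameterSet) triples for every shipped curve."""
    return [
        (species, stage, model.stage_curves[stage])
        for species, model in fixture_models.items()
        for stage in st.STAGES
    ]


# plausible positive-unimodal parameter sets, one per catalog model,
# for property tests that must run on every model form
GENERIC_PARAMS = {
    "analytis_77": {"a": 1e-4, "b": 1.5, "c": 1.0, "CTmin": 10.0, "CTmax": 38.0},
    "ratkowsky_83": {"c": 0.01, "k": 0.3, "CTmin": 10.0, "CTmax": 38.0},
    "hilbertLogan_83": {"phi": 0.05, "a": 8.0, "deltaT": 10.0, "CTmin": 10.0, "CTmax": 38.0},
    "beta_95": {"mu": -10.0, "a": 2.0, "b": 1.0, "CTmin": 10.0, "CTmax": 38.0},
    "beta_16": {"rm": 0.1, "Topt": 30.0, "CTmin": 10.0, "CTmax": 38.0},
    "briere1_99": {"a": 3e-5, "CTmin": 10.0, "CTmax": 38.0},
    "briere2_99": {"a": 3e-5, "b": 3.0, "CTmin": 10.0, "CTmax": 38.0},
    "kontodimas_04": {"a": 5e-5, "CTmin": 10.0, "CTmax": 38.0},
    "shi_11": {"c": 0.2, "k1": 0.1, "k2": 0.5, "CTmin": 10.0, "CTmax": 38.0},
    "perf2_11": {"c": 0.005, "k": 0.5, "CTmin": 10.0, "CTmax": 38.0},
    "regniere_12": {"phi": 0.01, "b": 0.15, "deltab": 5.0, "deltam": 5.0,
                    "CTmin": 10.0, "CTmax": 38.0},
}


@pytest.fixture(params=sorted(GENERIC_PARAMS))
def generic_curve(request):
    name = request.param
    return st.TPCParameterSet(st.get_model(name), GENERIC_PARAMS[name])


@pytest.fixture(scope="session")
def cp_larva_truth():
    """C. partellus larval curve, used as ground truth in recovery tests."""
    return st.TPCParameterSet(
        st.get_model("briere1_99"), {"a": 3.3e-5, "CTmin": 13.5, "CTmax": 37.1}
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
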