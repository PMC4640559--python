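import numpy as np
import pytest

from aktdyn.models import ModelSpec, RateParameters, build_initial_state
from aktdyn.splines import MEASUREMENT_GRID, SplineCurve
from aktdyn.synth import NoiseModel, default_truth_spec, make_fixture_bundle

GRID = list(MEASUREMENT_GRID)


@pytest.fixture(scope="session")
def truth_spec():
    return default_truth_spec()


@pytest.fixture(scope="session")
def noiseless_bundle():
    return make_fixture_bundle(seed=0, noise=NoiseModel(0.0, 0.0, 0.0))


@pytest.fixture(scope="session")
def default_bundle():
    return make_fixture_bundle(seed=0)


@pytest.fixture()
def h0_spec(truth_spec):
    """H0 with published rates and the packaged PIP3 input."""
    return ModelSpec(
        "H0",
        rates=RateParameters(),
        init=build_initial_state(),
        inputs={"PIP3": truth_spec.inputs["PIP3"]},
    )


def variant_spec(variant: str, truth, deviation_values=None) -> ModelSpec:
    """A simulatable spec of any variant sharing the truth's input curve."""
    from aktdyn.models import deviation_info

    dev, _, neutral = deviation_info(variant)
    deviations = {}
    if dev is not None:
        values = deviation_values or [neutral, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0]
        deviations = {dev: SplineCurve.on_grid(values)}
    rates = RateParameters(k9=0.5, k10=1.0, k11=0.05, k12=0.05, k13=0.02)
    return ModelSpec(variant, rates=rates,
                     init=build_initial_state(variant=variant),
                     inputs={"PIP3": truth.inputs["PIP3"]},
                     deviations=deviations)
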