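import numpy as np
import pytest

from umifid.simdata import (
    DEFAULT_TEMPLATE,
    ExperimentConfig,
    PolymeraseModel,
    UNIFORM_SPECTRUM,
    SUBSTITUTIONS,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def template():
    return DEFAULT_TEMPLATE


@pytest.fixture
def uniform_polymerase():
    return PolymeraseModel("uniform", 1e-4, UNIFORM_SPECTRUM, efficiency=1.8)


@pytest.fixture
def ag_heavy_polymerase():
    """Spectrum concentrated 0.6 on A>G, rest uniform."""
    w = np.full(12, 0.4 / 11.0)
    w[SUBSTITUTIONS.index("A>G")] = 0.6
    return PolymeraseModel("ag-heavy", 1e-4, w, efficiency=1.8)


def make_spectrum(**weights):
    """Spectrum from class weights, e.g. make_spectrum(**{'C>A': 1.0})."""
    w = np.zeros(12)
    for cls, val in weights.items():
        w[SUBSTITUTIONS.index(cls)] = val
    return w / w.sum()


@pytest.fixture
def small_config():
    return ExperimentConfig(
        n_templates=300,
        dilution_fraction=1e-4,
        reads_per_umi_distribution={"kind": "constant", "value": 8},
        seed=99,
    )
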