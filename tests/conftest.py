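import numpy as np
import pytest

from chondromorph.edma import GroupSample
from chondromorph.landmarks import LandmarkConfiguration
from chondromorph.synth import CHONDRO_MEAN, MC_MEAN


def make_config(coords: dict, specimen="s1", genotype="wildtype",
                age="E14.5", trial=1, missing=frozenset()):
    return LandmarkConfiguration(
        specimen_id=specimen, genotype=genotype, age=age, trial=trial,
        coordinates={k: np.asarray(v, dtype=float) for k, v in coords.items()},
        missing=missing)


def make_group(coord_sets, label="g", **kwargs):
    configs = [make_config(c, specimen=f"{label}{i}", **kwargs)
               for i, c in enumerate(coord_sets)]
    return GroupSample(label=label, configurations=configs)


@pytest.fixture
def mc_mean():
    return dict(MC_MEAN)


@pytest.fixture
def chondro_mean():
    return dict(CHONDRO_MEAN)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
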