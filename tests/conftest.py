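import numpy as np
import pytest

from bestmcg import (
    ClassifierConfig,
    HeartModel,
    assemble_final_measurements,
    generate_noise_bank,
    measure_models,
    sample_lesion_sets,
    split_dataset,
)
from bestmcg.datasets import LabeledFieldMap
from bestmcg.sensors import ArrayConfig, SensorSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def lesion_sets_100():
    """A fixed batch of 100 sampled lesion sets shared across tests."""
    return sample_lesion_sets(100, np.random.default_rng(777))


@pytest.fixture(scope="session")
def small_dataset(lesion_sets_100):
    """A small end-to-end dataset at the reference geometry (100 per class)."""
    import warnings

    normal, abnormal = measure_models(
        HeartModel(), lesion_sets_100, ArrayConfig(d=2.0), SensorSpec(a=0.5, h=0.5)
    )
    bank = generate_noise_bank(100, 0.04, np.random.default_rng(3))
    maps = assemble_final_measurements(normal, abnormal, bank)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return split_dataset(maps, attrs={"a": 0.5, "h": 0.5, "d": 2.0, "sigma": 0.04})


def synthetic_maps(n_per_class: int, offset: float, seed: int) -> list[LabeledFieldMap]:
    """Gaussian 6x6 maps; the abnormal class is shifted by ``offset``.

    ``offset = 0`` gives the no-signal null fixture, a large offset a
    linearly separable fixture.
    """
    gen = np.random.default_rng(seed)
    maps = []
    for i in range(n_per_class):
        base = gen.normal(size=(6, 6))
        other = gen.normal(size=(6, 6)) + offset
        maps.append(LabeledFieldMap(map=base, label=0, pair_index=i))
        maps.append(LabeledFieldMap(map=other, label=1, pair_index=i))
    return maps


def quick_classifier(epochs: int = 5, seed: int = 0, **kwargs) -> ClassifierConfig:
    return ClassifierConfig(
        architecture="logistic_baseline", epochs=epochs, seed=seed, **kwargs
    )
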