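import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from oilspec.simulate import NoiseConfig, SyntheticConfig, simulate_dataset
from oilspec.spectra import AcquisitionMeta, SpectraMatrix


@pytest.fixture
def tiny_spectra() -> SpectraMatrix:
    """Three replicate spectra of two samples on a 5-point TRANS axis."""
    axis = np.array([600.0, 604.0, 608.0, 612.0, 616.0])
    rng = np.random.default_rng(7)
    meta = [
        AcquisitionMeta(sample_id=s, technique="TRANS", resolution=8, replicate=r)
        for s in ("a", "b")
        for r in (1, 2, 3)
    ]
    values = rng.uniform(0.1, 1.0, size=(6, 5))
    return SpectraMatrix(axis=axis, values=values, meta=meta)


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced synthetic dataset (5 oil types, one block) for grid tests."""
    cfg = SyntheticConfig(
        n_types=5,
        type_counts=(3, 2, 1, 4, 2),
        techniques=("TRANS",),
        resolutions=(8,),
        seed=11,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Zero-noise dataset: responses are exact linear functionals of spectra."""
    cfg = SyntheticConfig(
        n_types=5,
        type_counts=(3, 3, 2, 3, 1),
        techniques=("TRANS",),
        resolutions=(8,),
        noise=NoiseConfig(additive_sd=0.0, baseline_sd=0.0, scatter_sd=0.0),
        seed=5,
    )
    return simulate_dataset(cfg)
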