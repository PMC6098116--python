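import numpy as np
import pytest

from tensorxfer.synthetic import PhantomSpec, make_template, template_geometry


@pytest.fixture(scope="session")
def tiny_spec() -> PhantomSpec:
    """16^3 phantom with short runs: fast enough for unit tests."""
    return PhantomSpec(
        grid_shape=(16, 16, 16),
        tract_radius=2.0,
        tract_amplitude=1.0,
        gm_thickness=1.5,
        trials_per_run=6,
        runs_per_subject=2,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_template(tiny_spec):
    geo = template_geometry(tiny_spec)
    return make_template(tiny_spec, geo), geo


@pytest.fixture(scope="session")
def desk_spec() -> PhantomSpec:
    """32^3 phantom with scaled-down run lengths (the desk-scale cohort)."""
    return PhantomSpec.desk(seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_symmetric_tensors(rng: np.random.Generator, n: int,
                             scale: float = 1.0) -> np.ndarray:
    """Random (n, 6) tensors with components of order ``scale``."""
    return rng.normal(0.0, scale, size=(n, 6))
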