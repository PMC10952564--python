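import numpy as np
import pytest

import donorsim as ds


@pytest.fixture(scope="session")
def female_model():
    return ds.default_recovery_model("female")


@pytest.fixture(scope="session")
def male_model():
    return ds.default_recovery_model("male")


@pytest.fixture(scope="session")
def female_behavior():
    return ds.behavior_for("female")


@pytest.fixture(scope="session")
def male_behavior():
    return ds.behavior_for("male")


@pytest.fixture(scope="session")
def rules():
    return ds.deferral_rules()


@pytest.fixture(scope="session")
def female_thresholds():
    return ds.thresholds_for("female")


@pytest.fixture(scope="session")
def male_thresholds():
    return ds.thresholds_for("male")


@pytest.fixture(scope="session")
def female_pop_small():
    cfg = ds.population_config(n=500, sex="female", seed=11)
    return ds.generate_reference_population(cfg)


@pytest.fixture(scope="session")
def female_pop_5k():
    cfg = ds.population_config(n=5000, sex="female", seed=12)
    return ds.generate_reference_population(cfg)


@pytest.fixture(scope="session")
def male_pop_small():
    cfg = ds.population_config(n=500, sex="male", seed=13)
    return ds.generate_reference_population(cfg)


@pytest.fixture
def example_donor():
    """A fixed donor for hand-arithmetic checks."""
    return ds.Donor(
        id=0, sex="female", age=40.0, ethnicity="White", blood_group="O+",
        index_hb=134.0, latent_offset=0.0,
    )


def make_donor(**kw):
    base = dict(
        id=0, sex="female", age=40.0, ethnicity="White", blood_group="O+",
        index_hb=134.0, latent_offset=0.0,
    )
    base.update(kw)
    return ds.Donor(**base)


@pytest.fixture
def donor_factory():
    return make_donor


def random_donor(rng, sex="female"):
    return make_donor(
        id=int(rng.integers(1_000_000)),
        sex=sex,
        age=float(rng.uniform(18, 70)),
        index_hb=float(rng.uniform(110, 165)),
    )


@pytest.fixture
def random_donor_factory():
    return random_donor
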