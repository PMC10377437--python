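import numpy as np
import pytest

from pvrisk import synthgen


@pytest.fixture(scope="session")
def small_cohort():
    """Default-structure synthetic cohort, small enough for unit tests."""
    return synthgen.generate_cohort(synthgen.GeneratorConfig(n_patients=400, seed=7))


@pytest.fixture(scope="session")
def null_config():
    """Generator settings with every planted effect switched off."""
    def make(n, seed, **overrides):
        kw = dict(
            n_patients=n,
            seed=seed,
            log_hr={"te_history": 0.0, "anticoag": 0.0, "age_per_decade": 0.0},
            interactions=(),
        )
        kw.update(overrides)
        return synthgen.GeneratorConfig(**kw)

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(0)
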