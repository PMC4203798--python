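import numpy as np
import pytest

from strokecea import (
    build_life_table,
    default_config,
    pooled_arm_outcomes,
)


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def windows(cfg):
    return cfg.windows


@pytest.fixture(scope="session")
def params(cfg):
    return cfg.params


@pytest.fixture(scope="session")
def life_table(params):
    return build_life_table(params)


@pytest.fixture(scope="session")
def pooled(windows):
    return {arm: pooled_arm_outcomes(windows, arm) for arm in ("tpa", "control")}


@pytest.fixture()
def zero_mortality_life_table(params):
    """Life table with (numerically) no non-stroke death, for closed forms."""
    from strokecea.mortality import LifeTable

    ages = np.arange(int(params.start_age), int(params.start_age) + 41)
    return LifeTable(ages=ages, q=np.zeros_like(ages, dtype=float))
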