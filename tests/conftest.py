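import numpy as np
import pytest

from sca1cea.config import MortalityParams, default_config
from sca1cea.eq5d import load_dutch_valueset


@pytest.fixture(scope="session")
def cfg():
    """Bundled default configuration (10,000 patients, calibrated table)."""
    return default_config()


@pytest.fixture(scope="session")
def small_cfg(cfg):
    """Default parameters on a small cohort for fast simulation tests."""
    return cfg.replace(settings=cfg.settings.replace(n_patients=300, seed=11))


@pytest.fixture(scope="session")
def valueset():
    return load_dutch_valueset()


def plateau_mortality(s5: float, background: float = 0.0) -> MortalityParams:
    """Constant 5-year survival over SARA 14-40 (handy for closed forms)."""
    return MortalityParams(
        sara_grid=np.array([14.0, 40.0]),
        survival_5yr=np.array([s5, s5]),
        background_annual_prob=background,
    )


@pytest.fixture
def no_mortality():
    """Death only at the SARA-40 ceiling."""
    return plateau_mortality(1.0, background=0.0)
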