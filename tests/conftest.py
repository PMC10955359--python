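import dataclasses

import numpy as np
import pytest

from coopcast import GameConfig, RaterConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def game_config():
    return GameConfig()


@pytest.fixture
def cohort94_config():
    """An explicitly 94-player cohort (even gender split) for product-count
    checks that condition on a 94-player study."""
    return dataclasses.replace(GameConfig(), n_male=47, n_female=47)


@pytest.fixture
def small_rater_config():
    """A reduced rater cohort for fast end-to-end checks."""
    return dataclasses.replace(
        RaterConfig(),
        n_none=6,
        n_label=6,
        n_photo=4,
        n_video=4,
        n_excluded_small_screen=2,
        n_excluded_fast=1,
    )
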