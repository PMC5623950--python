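import numpy as np
import pytest

from thermopheno import (SyntheticConfig, draw_true_tc, make_layout,
                         render_mosaic)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(seed=11, n_genotypes=20)


@pytest.fixture(scope="session")
def small_trial(small_config):
    """A small two-plot trial: layout, truth and both rendered mosaics."""
    layout = make_layout(small_config)
    true_state = draw_true_tc(small_config, layout)
    mosaics = {tr: render_mosaic(small_config, layout, true_state, tr)
               for tr in ("WW", "mDr")}
    return {"config": small_config, "layout": layout,
            "true_state": true_state, "mosaics": mosaics}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
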