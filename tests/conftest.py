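import numpy as np
import pandas as pd
import pytest

import fjordbeta as fb


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run on the default synthetic scenario (fixed seed)."""
    cfg = fb.PipelineConfig(scenario=fb.default_scenario(seed=0), seed=0)
    return fb.run_pipeline(cfg, through="trends")


@pytest.fixture(scope="session")
def fast_scenario():
    """A shorter, coarser scenario for tests that only need structure, not scale."""
    return fb.default_scenario(
        start="2012-03-01", end="2013-01-31",
        sampling_interval_env=10.0,
        decline_start="2012-05-01", decline_days=60.0,
        severe_hypoxia_days=100.0, seed=7,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_env(values: dict, start="2012-01-01", freq="1min") -> fb.EnvSeries:
    n = len(next(iter(values.values())))
    idx = pd.date_range(start, periods=n, freq=freq)
    return fb.EnvSeries(pd.DataFrame(values, index=idx))
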