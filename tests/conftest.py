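import numpy as np
import pytest

from oculodx import synthesis
from oculodx.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def default_cohort():
    """The standard 96-subject cohort (3 groups of 12/8/12)."""
    return synthesis.generate_cohort(seed=0)


@pytest.fixture(scope="session")
def default_result():
    """One full end-to-end pipeline run with default configuration."""
    return run_pipeline(PipelineConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def render_ellipse(center=(120, 100), axes=(20, 20), angle=0.0,
                   size=(240, 320), **kw):
    return synthesis.render_frame(center, axes, angle, size, **kw)
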