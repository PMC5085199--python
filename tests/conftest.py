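import numpy as np
import pytest

from tshmeta.effect_measures import Estimate


@pytest.fixture
def toy_estimates():
    """Six hand-sized log-ratio estimates with unequal variances."""
    y = [0.10, 0.35, -0.05, 0.50, 0.22, 0.41]
    v = [0.010, 0.040, 0.025, 0.090, 0.015, 0.060]
    return [Estimate(study_id=f"S{i}", y=yi, v=vi, measure="log_rom")
            for i, (yi, vi) in enumerate(zip(y, v), start=1)]


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def make_estimates(y, v, measure="log_rom"):
    return [Estimate(study_id=f"S{i}", y=float(yi), v=float(vi), measure=measure)
            for i, (yi, vi) in enumerate(zip(y, v), start=1)]
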