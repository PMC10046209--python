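import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import figground as fg

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def cutoff_respond_fn(cutoff):
    """Deterministic observer: correct iff the noise level <= cutoff."""

    def fn(level, truth, rng):
        if level <= cutoff:
            return truth
        return "scrambled" if truth == "grouped" else "grouped"

    return fn


@pytest.fixture(scope="session")
def walker_clip():
    return fg.generate_walker()


@pytest.fixture(scope="session")
def template_bank():
    return fg.build_template_bank()


@pytest.fixture(scope="session")
def central_layout():
    return fg.Layout(0.0, 16.0)


@pytest.fixture(scope="session")
def small_detectors(central_layout):
    """Detectors calibrated on a reduced clip budget for unit tests."""
    cfg = fg.StimulusConfig()
    return {
        task: fg.calibrate_detector(task, central_layout, config=cfg,
                                    n_per_class=40, seed=101)
        for task in ("static", "dynamic", "walker")
    }, cfg
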