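import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from tissuefit.params import ModelParams


@pytest.fixture(scope="session")
def fisher_modes():
    """Posterior-mode Fisher-KPP parameters from the single-expansion fit."""
    return ModelParams("linear", 1073.0, 0.289, 5113.0)


@pytest.fixture(scope="session")
def porous_modes():
    """Posterior-mode Porous-Fisher parameters from the single-expansion fit."""
    return ModelParams("porous", 1.18, 0.214, 5319.0)


@pytest.fixture(scope="session")
def collision_fit():
    """Porous-Fisher parameters fitted to the control rectangle collision."""
    return ModelParams("porous", 3.26, 0.11, 4077.0)


@pytest.fixture(scope="session")
def coarse_experiment(porous_modes):
    """A small noise-free synthetic expansion for fast likelihood tests."""
    from tissuefit.observations import expansion_protocol

    return expansion_protocol(
        porous_modes,
        sigma=0.0,
        seed=0,
        times=(16.0, 26.0),
        domain_radius_mm=2.6,
        solver_h_mm=0.04,
    )
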