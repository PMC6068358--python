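import numpy as np
import pytest

from commonsig.ar_spectral import ARModel, FrequencyGrid, connected_model


@pytest.fixture(scope="session")
def grid() -> FrequencyGrid:
    return FrequencyGrid.default()


@pytest.fixture(scope="session")
def connected() -> ARModel:
    return connected_model()


def _model(natural, noise):
    return ARModel.from_natural(np.asarray(natural, dtype=float), np.asarray(noise, dtype=float))


@pytest.fixture(scope="session")
def ar_battery() -> list[ARModel]:
    """Stable bivariate AR models exercising one-way coupling, two-way
    coupling, correlated innovations, and order 2."""
    return [
        connected_model(),
        _model([[[0.5, 0.2], [0.1, 0.3]]], [[1.0, 0.0], [0.0, 1.0]]),
        _model([[[0.4, 0.0], [0.3, 0.2]]], [[1.0, 0.4], [0.4, 2.0]]),  # gamma != 0
        _model(
            [[[0.55, 0.0], [0.25, 0.35]], [[-0.2, 0.05], [0.0, -0.15]]],
            [[1.5, -0.3], [-0.3, 0.8]],
        ),
        _model([[[0.0, 0.0], [0.0, 0.0]]], [[2.0, 0.5], [0.5, 1.0]]),  # white correlated
    ]
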