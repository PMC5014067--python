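import numpy as np
import pytest

from gammachain import CascadeSpec, GammaModule, InputSignal


@pytest.fixture
def fig_cascade() -> CascadeSpec:
    """The reference equal-rate cascade used throughout: n=5,
    alpha=(3,4,4,4,4), beta=3 (geometric-mean rate 3.776, gain 768/243)."""
    return CascadeSpec(5, (3, 4, 4, 4, 4), (3, 3, 3, 3, 3))


@pytest.fixture
def fig_module(fig_cascade) -> GammaModule:
    return fig_cascade.to_gamma_module()


@pytest.fixture
def grid() -> np.ndarray:
    return np.linspace(0.0, 10.0, 201)


@pytest.fixture
def step() -> InputSignal:
    return InputSignal.step()
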