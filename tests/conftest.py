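import numpy as np
import pytest

from kernelfield.kernels import KernelSpec

#: one representative spec per kernel family, reused across oracle tests
ALL_SPECS = [
    KernelSpec("linear", theta=0.0),
    KernelSpec("linear", theta=1.5),
    KernelSpec("polynomial", degree=2, theta=0.1),
    KernelSpec("polynomial", degree=4, theta=1.5),
    KernelSpec("rbf", sigma=0.5),
    KernelSpec("rbf", sigma=2.0),
    KernelSpec("sigmoid", v=0.5, r=-0.2),
]


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
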