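import numpy as np
import pytest

from waveseg.autograd import Tensor


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


def numeric_grad(fn, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite-difference gradient of scalar-valued fn at x."""
    g = np.zeros_like(x, dtype=np.float64)
    flat = x.reshape(-1)
    gf = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = fn(x)
        flat[i] = orig - eps
        lo = fn(x)
        flat[i] = orig
        gf[i] = (hi - lo) / (2 * eps)
    return g


def check_gradient(op, x: np.ndarray, atol: float = 1e-6) -> None:
    """Compare analytic backward of sum(op(x)) with finite differences."""
    t = Tensor(x.copy(), requires_grad=True)
    out = op(t)
    out.sum().backward()
    analytic = t.grad

    def scalar(arr):
        return float(op(Tensor(arr)).data.sum())

    numeric = numeric_grad(scalar, x.copy())
    np.testing.assert_allclose(analytic, numeric, atol=atol, rtol=1e-4)
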