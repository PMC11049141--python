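import numpy as np
import pytest

from pisnet import nn


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(autouse=True)
def _deterministic_init():
    """Every test starts from the same parameter-init stream."""
    nn.seed_all(99)
    yield


def gradcheck(fn, tensors, eps=1e-5, atol=1e-6, rtol=1e-4):
    """Compare analytic gradients of scalar fn(*tensors) to central
    finite differences (tensors must hold float64 data)."""
    for t in tensors:
        t.grad = None
    out = fn(*tensors)
    out.backward()
    for t in tensors:
        if not t.requires_grad:
            continue
        assert t.grad is not None, "missing gradient"
        num = np.zeros_like(t.data)
        flat = t.data.ravel()
        nflat = num.ravel()
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            hi = float(fn(*tensors).data)
            flat[i] = orig - eps
            lo = float(fn(*tensors).data)
            flat[i] = orig
            nflat[i] = (hi - lo) / (2 * eps)
        np.testing.assert_allclose(t.grad, num, atol=atol, rtol=rtol)
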