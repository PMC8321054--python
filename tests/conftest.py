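import numpy as np
import pytest

from locseg3d import PhantomSpec, generate


@pytest.fixture(scope="session")
def blob_cases():
    """Small blob phantom set shared across tests (deterministic)."""
    return generate(PhantomSpec(mode="blob", shape=(16, 32, 32), n_cases=10, seed=11))


@pytest.fixture(scope="session")
def shortaxis_cases():
    """Small anisotropic three-structure phantom set."""
    return generate(PhantomSpec(mode="shortaxis", n_cases=6, seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def fd_gradcheck(build, tensors, eps=1e-5):
    """Max |central finite difference - autodiff gradient| over probes."""
    for t in tensors:
        t.grad = None
    build().backward()
    worst = 0.0
    for t in tensors:
        flat = t.data.ravel()
        step = max(1, t.data.size // 13)
        for i in range(0, t.data.size, step):
            old = flat[i]
            flat[i] = old + eps
            lp = float(build().data)
            flat[i] = old - eps
            lm = float(build().data)
            flat[i] = old
            worst = max(worst, abs((lp - lm) / (2 * eps) - t.grad.ravel()[i]))
    return worst
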