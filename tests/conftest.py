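import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def gradcheck(f, x, eps: float = 1e-6, atol: float = 1e-6) -> float:
    """Max abs difference between autodiff and central finite differences."""
    from privvae.autodiff import Tensor

    x = np.asarray(x, dtype=np.float64)
    xt = Tensor(x, requires_grad=True)
    out = f(xt)
    out.backward()
    analytic = xt.grad.copy()
    numeric = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        xp, xm = x.copy(), x.copy()
        xp[i] += eps
        xm[i] -= eps
        numeric[i] = (float(f(Tensor(xp)).data) - float(f(Tensor(xm)).data)) / (2 * eps)
    err = float(np.max(np.abs(analytic - numeric)))
    assert err < atol, f"gradient mismatch: {err}"
    return err
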