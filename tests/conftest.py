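import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def loop_conv2d(x, w, stride=1, pad=0):
    """Brute-force per-output-element convolution (oracle).

    x: (B, C, H, W); w: (Cout, C, K, K). Also returns the MAC count
    actually executed, for cost-formula cross-checks.
    """
    b, c, h, wd = x.shape
    cout, cin, k, _ = w.shape
    assert cin == c
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (wd + 2 * pad - k) // stride + 1
    y = np.zeros((b, cout, ho, wo), np.float64)
    macs = 0
    for bi in range(b):
        for o in range(cout):
            for i in range(ho):
                for j in range(wo):
                    patch = xp[bi, :, i * stride:i * stride + k,
                               j * stride:j * stride + k]
                    y[bi, o, i, j] = float((patch * w[o]).sum())
                    macs += patch.size
    return y.astype(np.float32), macs


@pytest.fixture
def loop_conv():
    return loop_conv2d
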