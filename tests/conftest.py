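import numpy as np
import pytest

from nwsr.fiber_model import (build_cellmap, downsample_to_fibers,
                              generate_fiber_layout, signals_to_sparse)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_layout():
    """50 jittered fibres on a 64x64 grid, shared across read-only tests."""
    return generate_fiber_layout(50, (64, 64), jitter=0.2, seed=7)


@pytest.fixture(scope="session")
def small_sparse(small_layout):
    """A sparse frame whose signals come from a smooth synthetic field."""
    cm = build_cellmap(small_layout)
    rr, cc = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
    field = 0.5 + 0.3 * np.sin(rr / 9.0) * np.cos(cc / 7.0)
    return signals_to_sparse(downsample_to_fibers(field, cm), small_layout)


# ---------------------------------------------------------------------------
# Independent brute-force oracles (deliberately naive implementations)
# ---------------------------------------------------------------------------

def brute_force_nearest(positions: np.ndarray, grid_shape) -> np.ndarray:
    """Exhaustive nearest-fibre labels; ties to the lowest fibre index."""
    gh, gw = grid_shape
    labels = np.empty((gh, gw), dtype=np.int64)
    for r in range(gh):
        for c in range(gw):
            d2 = (positions[:, 0] - r) ** 2 + (positions[:, 1] - c) ** 2
            labels[r, c] = int(np.argmin(d2))
    return labels


def brute_force_nw(features, masks, weights, biases, eps=1e-8):
    """Per-pixel double-loop NW operation with zero padding.

    R = sum S w / sum M |w| + b per output kernel; M_up = sum M |w|;
    where the denominator <= eps the output is the bias and M_up is 0.
    """
    c_in, h, w_ = features.shape
    t, _, kh, kw = weights.shape
    k = (kh - 1) // 2
    r_out = np.zeros((t, h, w_))
    m_out = np.zeros((t, h, w_))
    for ti in range(t):
        for u in range(h):
            for v in range(w_):
                num = 0.0
                den = 0.0
                for ci in range(c_in):
                    for i in range(-k, k + 1):
                        for j in range(-k, k + 1):
                            uu, vv = u + i, v + j
                            if 0 <= uu < h and 0 <= vv < w_:
                                wgt = weights[ti, ci, i + k, j + k]
                                num += features[ci, uu, vv] * wgt
                                den += masks[ci, uu, vv] * abs(wgt)
                if den > eps:
                    r_out[ti, u, v] = num / den + biases[ti]
                    m_out[ti, u, v] = den
                else:
                    r_out[ti, u, v] = biases[ti]
    return r_out, m_out


def random_sparse_instance(rng, c_in, h, w, density=0.3, binary_mask=True):
    """Random (features, masks) pair satisfying the NW layer preconditions."""
    if binary_mask:
        masks = (rng.random((c_in, h, w)) < density).astype(float)
    else:
        masks = rng.random((c_in, h, w)) * (rng.random((c_in, h, w)) < 0.8)
    features = rng.standard_normal((c_in, h, w))
    if binary_mask:
        features = features * masks
    return features, masks
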