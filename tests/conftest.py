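import numpy as np
import pytest

from emalign import generate_phantom, slice_volume


@pytest.fixture(scope="session")
def phantom_volume():
    """Small phantom volume shared across tests (deterministic)."""
    return generate_phantom((16, 128, 128), seed=42)


@pytest.fixture(scope="session")
def textured_slice(phantom_volume):
    """One feature-rich 2D slice."""
    return phantom_volume[8]


@pytest.fixture(scope="session")
def phantom_stack(phantom_volume):
    return slice_volume(phantom_volume, 1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def interior(arr, margin=12):
    """Trim a border margin off the trailing two axes."""
    return arr[..., margin:-margin, margin:-margin]


# --- translation-model oracle machinery -----------------------------------
#
# A row-ramp image makes every translated copy recoverable exactly: slice
# values are (row - shift)/H, so the row shift between two copies is the
# median of (fixed - moving) * H over the interior.  This yields an exact
# flow oracle for pure-translation stacks, independent of the estimator.

RAMP_SIZE = 64


def ramp_image(h=RAMP_SIZE, w=RAMP_SIZE):
    return np.outer(np.arange(h, dtype=float), np.ones(w)) / h


def ramp_flow_oracle(fixed, moving, margin=8):
    h = fixed.shape[0]
    d = np.median((fixed - moving)[margin:-margin, margin:-margin]) * h
    field = np.zeros((2,) + fixed.shape)
    field[0] = d
    return field


def scalar_elastic_step(u_prev, u_i, u_next, kernel):
    """Symbolic brute force of the five-step filtering procedure on scalar
    shifts; returns the combined field value phi_i (row component).

    Independent oracle for the image-space implementation: every step acts
    on shift scalars instead of images/fields.
    """
    gm1, g0, g1 = kernel.g(-1), kernel.g(0), kernel.g(1)
    phi_prev = u_i - u_prev          # flow(I_{i-1}, I_i)
    phi_next = u_next - u_i          # flow(I_i, I_{i+1})
    a0 = u_i - gm1 * phi_prev        # shift of I_i^tmp
    a1 = u_next - g0 * phi_next      # shift of I_{i+1}^tmp
    t0 = u_i - a0                    # flow(I_i^tmp, I_i)
    t1 = u_i - a1                    # flow(I_{i+1}^tmp, I_i)
    w0 = (gm1 + g0) / ((gm1 + g0) + (g0 + g1))
    return w0 * t0 + (1 - w0) * t1
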