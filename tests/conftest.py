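import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def bilinear_oracle(grid: np.ndarray, ny: float, nx: float) -> float:
    """Reference bilinear sample at one normalised position.

    Implements the package-wide convention independently: pixel centres at
    (i + 0.5, j + 0.5) on a half-open grid, border clamping.
    """
    H, W = grid.shape
    y = min(max(ny * H - 0.5, 0.0), H - 1.0)
    x = min(max(nx * W - 0.5, 0.0), W - 1.0)
    y0 = min(int(np.floor(y)), H - 2) if H > 1 else 0
    x0 = min(int(np.floor(x)), W - 2) if W > 1 else 0
    y1, x1 = min(y0 + 1, H - 1), min(x0 + 1, W - 1)
    wy, wx = y - y0, x - x0
    return float(
        grid[y0, x0] * (1 - wy) * (1 - wx)
        + grid[y0, x1] * (1 - wy) * wx
        + grid[y1, x0] * wy * (1 - wx)
        + grid[y1, x1] * wy * wx
    )
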