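import numpy as np
import pytest

from ramident.io import Spectrum
from ramident.synthetic import wavenumber_grid


@pytest.fixture
def grid():
    return wavenumber_grid()


@pytest.fixture
def make_spectrum(grid):
    """Factory building a Spectrum from a callable or array on the grid."""

    def _make(values, meta=None):
        y = values(grid) if callable(values) else np.asarray(values, float)
        if np.isscalar(y) or y.ndim == 0:
            y = np.full(grid.size, float(y))
        return Spectrum(grid.copy(), y, dict(meta or {}))

    return _make


@pytest.fixture
def gaussian():
    """Gaussian band profile g(wn; center, sigma, amplitude)."""

    def _g(wn, center, sigma, amplitude=1.0):
        return amplitude * np.exp(-0.5 * ((wn - center) / sigma) ** 2)

    return _g
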