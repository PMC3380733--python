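import numpy as np
import pytest

from msqc.ensemble import build_graph
from msqc.spectra import Spectrum


@pytest.fixture
def spectrum_a() -> Spectrum:
    """Three-peak hand-checkable spectrum: neutral precursor mass 600.0,
    one complementary pair (200+400) and one glycine gap (200→257.02)."""
    return Spectrum.from_arrays("S_A", 601.00728, 1,
                                [200.0, 257.02, 400.0], [10.0, 30.0, 60.0])


#: The worked 5-spectra x 6-features toy assignment (rows = features).
TOY_ASSIGNMENTS = np.array([
    [1, 1, 2, 2, 2],   # F1
    [1, 1, 2, 2, 2],   # F2
    [2, 1, 2, 1, 2],   # F3
    [1, 2, 1, 2, 2],   # F4
    [1, 2, 2, 1, 2],   # F5
    [2, 1, 1, 2, 2],   # F6
]).T


@pytest.fixture
def toy_graph():
    return build_graph(TOY_ASSIGNMENTS)


def random_spectrum(rng: np.random.Generator, n_peaks: int | None = None,
                    mz_span: tuple[float, float] = (100.0, 1200.0)) -> Spectrum:
    """A random spectrum for property tests (no planted structure)."""
    if n_peaks is None:
        n_peaks = int(rng.integers(2, 51))
    mz = rng.uniform(*mz_span, size=n_peaks)
    intensity = rng.lognormal(3.0, 1.0, size=n_peaks)
    precursor_mz = float(rng.uniform(400.0, 1600.0))
    return Spectrum.from_arrays(f"rand_{rng.integers(1 << 30)}", precursor_mz,
                                int(rng.integers(1, 4)), mz, intensity)


def random_graph(rng: np.random.Generator, n_max: int = 50, m_max: int = 10):
    """A random ensemble graph (arbitrary binary assignments)."""
    n = int(rng.integers(2, n_max + 1))
    m = int(rng.integers(1, m_max + 1))
    return build_graph(rng.integers(1, 3, size=(n, m)))
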