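import numpy as np
import pytest

from esrwpt import ExtractionConfig, Spectrum, extract, make_benchmark


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def plain_spectrum(rng):
    """A generic valid spectrum: three derivative lines plus mild noise."""
    field = np.linspace(3300.0, 3360.0, 512)
    y = np.zeros_like(field)
    for center in (3315.0, 3330.0, 3345.0):
        x = field - center
        y += -x * np.exp(-0.5 * (x / 1.5) ** 2)
    y += 0.01 * rng.standard_normal(field.size)
    return Spectrum(field, y, mw_frequency_ghz=9.33, label="triplet")


@pytest.fixture(scope="session")
def tempo_spectrum():
    (s, truth), = make_benchmark("tempo_like", seed=0)
    return s, truth


@pytest.fixture(scope="session")
def cuqu_spectrum():
    (s, truth), = make_benchmark("cuqu_like", seed=0)
    return s, truth


@pytest.fixture(scope="session")
def nitroxide_panel():
    """Recovered couplings for the unresolved nitroxide panel.

    Maps (preset, wavelet) -> list of recovered A values over 20 seeds.
    Computed once; the recovery and wavelet-robustness checks share it.
    """
    out = {}
    for preset in ("tempo_like", "tempol_like"):
        for wavelet in ("db9", "db6", "coif3"):
            values = []
            for seed in range(20):
                (s, truth), = make_benchmark(preset, seed=seed)
                res = extract(s, ExtractionConfig(spin_I=0.5, wavelet=wavelet))
                values.append((res.A_fine, truth["A_fine"]))
            out[(preset, wavelet)] = values
    return out
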