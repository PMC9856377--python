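import numpy as np
import pytest

from epibarrier import (
    DEFAULT_FREQUENCIES,
    ImpedanceSpectrum,
    one_path_impedance,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_spectrum(r_sub=10.0, r_epi=90.0, cap=3e-6, freqs=None, noise=0.0,
                  rng=None, corrected=True):
    """Noise-free (or perturbed) one-path spectrum on the default grid."""
    f = DEFAULT_FREQUENCIES if freqs is None else np.asarray(freqs, float)
    z = one_path_impedance(f, r_sub, r_epi, cap)
    if noise > 0:
        z = z.real * (1 + noise * rng.standard_normal(f.size)) + 1j * z.imag * (
            1 + noise * rng.standard_normal(f.size)
        )
    return ImpedanceSpectrum(freqs=f, z=z, bath_corrected=corrected)


@pytest.fixture
def reference_spectrum():
    return make_spectrum()
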