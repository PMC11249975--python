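import numpy as np
import pytest

from ssqpgm import OpticalConfig, PhaseMap


@pytest.fixture
def optical():
    return OpticalConfig()


@pytest.fixture
def bandlimited():
    """Factory for periodic band-limited random fields.

    ``bandlimited(n, cutoff, amp, seed)`` returns an n x n real field with
    DFT support strictly inside |u| < cutoff (cycles/pixel) in each axis,
    scaled to peak amplitude ``amp``.
    """

    def make(n, cutoff, amp, seed):
        rng = np.random.default_rng(seed)
        k = np.fft.fftfreq(n)
        spec = rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))
        mask = (np.abs(k)[:, None] < cutoff) & (np.abs(k)[None, :] < cutoff)
        f = np.fft.ifft2(spec * mask).real
        return f / np.abs(f).max() * amp

    return make


@pytest.fixture
def bandlimited_phase(bandlimited, optical):
    """Band-limited random PhaseMap suitable for exact round trips.

    Cutoff and amplitude are chosen so the complex field exp(i*phi) is
    itself effectively band-limited below Nyquist (harmonics fall under
    1e-12), which the frequency-domain shear requires for exactness.
    """

    def make(n=128, cutoff=0.04, amp=0.5, seed=0):
        return PhaseMap(
            bandlimited(n, cutoff, amp, seed),
            pixel_pitch_um=optical.pixel_pitch_um,
            wavelength_um=optical.wavelength_um,
        )

    return make
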