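"""Forward model of the single-shot phase-gradient measurement.

A DIC microscope splits the illumination into two orthogonally polarized
beams displaced by ``±Δr`` about each image point.  A quarter-wave plate
maps the two sheared linear components to opposite circular states, so a
linear analyzer at angle θ reads out their phase difference.  Writing the
two sheared complex fields

    f∓ = A(r ∓ Δr) · exp(i φ(r ∓ Δr)),

the four analyzer channels are (with the analyzer 0° axis oriented at 45°
to the shear axes, the standard DIC-polarimetry arrangement)

    S  = |f−|² + |f+|²,   C = Re(conj(f−)·f+),   Sn = Im(conj(f−)·f+)
    I0 = S/2 + C,   I90 = S/2 − C,   I45 = S/2 + Sn,   I135 = S/2 − Sn,

all non-negative by Cauchy–Schwarz, and satisfying the conservation
identity I0 + I90 = I45 + I135 = S.  It follows that

    atan2(I45 − I135, I0 − I90) = φ(r + Δr) − φ(r − Δr),

the sheared phase difference, independent of the amplitude A.

A division-of-focal-plane sensor interleaves the four channels into a
single 2x2-periodic mosaic; Poisson shot noise and Gaussian read noise can
be added to emulate a real exposure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from .config import DEFAULT_LAYOUT, validate_layout
from .phantoms import PhaseMap

__all__ = [
    "ShearedFieldPair",
    "PolarizationChannels",
    "RawMosaic",
    "shear_field",
    "polarization_intensities",
    "mosaic",
    "add_noise",
    "simulate_raw",
    "translate_field",
]


@dataclass
class ShearedFieldPair:
    """The two sheared complex fields ``f∓ = A(r ∓ Δr) e^{iφ(r ∓ Δr)}``."""

    f_minus: np.ndarray
    f_plus: np.ndarray
    shear_half_vector_px: Tuple[float, float]

    def __post_init__(self) -> None:
        self.f_minus = np.asarray(self.f_minus, dtype=complex)
        self.f_plus = np.asarray(self.f_plus, dtype=complex)
        if self.f_minus.shape != self.f_plus.shape:
            raise ValueError("sheared fields must have the same shape")
        if not (np.all(np.isfinite(self.f_minus)) and np.all(np.isfinite(self.f_plus))):
            raise ValueError("sheared fields must be finite")


@dataclass
class PolarizationChannels:
    """Four co-registered analyzer-channel intensity images."""

    I0: np.ndarray
    I45: np.ndarray
    I90: np.ndarray
    I135: np.ndarray

    def __post_init__(self) -> None:
        arrays = [np.asarray(a, dtype=float) for a in (self.I0, self.I45, self.I90, self.I135)]
        shapes = {a.shape for a in arrays}
        if len(shapes) != 1:
            raise ValueError("the four channels must be co-registered (same shape)")
        self.I0, self.I45, self.I90, self.I135 = arrays

    def as_dict(self) -> Dict[int, np.ndarray]:
        return {0: self.I0, 45: self.I45, 90: self.I90, 135: self.I135}

    @property
    def shape(self) -> Tuple[int, int]:
        return self.I0.shape


@dataclass
class RawMosaic:
    """A single polarization-filter-array frame.

    ``values[i, j]`` carries the channel assigned by
    ``layout[i % 2][j % 2]`` (angles in degrees).
    """

    values: np.ndarray
    layout: Tuple[Tuple[int, int], Tuple[int, int]] = DEFAULT_LAYOUT

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("mosaic must be 2-D")
        h, w = self.values.shape
        if h % 2 or w % 2:
            raise ValueError(f"mosaic dimensions must be even, got {h}x{w}")
        self.layout = validate_layout(self.layout)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape


def translate_field(field: np.ndarray, shift_px: Tuple[float, float]) -> np.ndarray:
    """Translate a 2-D field by ``(dx, dy)`` pixels with periodic boundary.

    Uses a frequency-domain phase ramp, which is an exact translation for
    band-limited periodic inputs and supports sub-pixel shifts.
    """
    field = np.asarray(field, dtype=complex)
    h, w = field.shape
    dx, dy = shift_px
    uy = np.fft.fftfreq(h)[:, None]
    ux = np.fft.fftfreq(w)[None, :]
    ramp = np.exp(-2j * np.pi * (ux * dx + uy * dy))
    return np.fft.ifft2(np.fft.fft2(field) * ramp)


def shear_field(
    phase: PhaseMap,
    amplitude: np.ndarray,
    delta_r: Tuple[float, float],
) -> ShearedFieldPair:
    """Form the sheared complex field pair from a phase map and amplitude.

    The complex field ``A e^{iφ}`` is translated by ``−Δr`` and ``+Δr``
    (periodic, frequency-domain translation; exact for band-limited
    inputs).  ``delta_r`` is ``(dx, dy)`` in pixels and may be sub-pixel.
    """
    amplitude = np.asarray(amplitude, dtype=float)
    if amplitude.shape != phase.values.shape:
        raise ValueError("amplitude shape must match phase shape")
    if not np.all(np.isfinite(amplitude)):
        raise ValueError("amplitude must be finite")
    if np.any(amplitude < 0):
        raise ValueError("amplitude must be non-negative")
    field = amplitude * np.exp(1j * phase.values)
    dx, dy = float(delta_r[0]), float(delta_r[1])
    if dx == 0.0 and dy == 0.0:
        f_minus = field.copy()
        f_plus = field.copy()
    else:
        f_minus = translate_field(field, (dx, dy))     # samples field at r - Δr
        f_plus = translate_field(field, (-dx, -dy))    # samples field at r + Δr
    return ShearedFieldPair(f_minus, f_plus, (dx, dy))


def polarization_intensities(pair: ShearedFieldPair) -> PolarizationChannels:
    """Evaluate the four analyzer-channel intensities of the Jones model."""
    fm, fp = pair.f_minus, pair.f_plus
    cross = np.conj(fm) * fp
    S = np.abs(fm) ** 2 + np.abs(fp) ** 2
    C = cross.real
    Sn = cross.imag
    half = S / 2.0
    I0 = half + C
    I90 = half - C
    I45 = half + Sn
    I135 = half - Sn
    # Cauchy-Schwarz guarantees non-negativity; clamp float round-off only.
    eps = -1e-12 * max(S.max(), 1.0)
    for arr in (I0, I45, I90, I135):
        if arr.min() < eps:
            raise AssertionError("negative intensity beyond round-off")
        np.maximum(arr, 0.0, out=arr)
    return PolarizationChannels(I0=I0, I45=I45, I90=I90, I135=I135)


def mosaic(channels: PolarizationChannels, layout=DEFAULT_LAYOUT) -> RawMosaic:
    """Interleave four channels into a polarization-filter-array frame.

    Pixel ``(i, j)`` of the output carries channel ``layout[i % 2][j % 2]``
    sampled at ``(i, j)`` — no resampling is performed.
    """
    layout = validate_layout(layout)
    h, w = channels.shape
    if h % 2 or w % 2:
        raise ValueError(f"channel dimensions must be even, got {h}x{w}")
    out = np.empty((h, w), dtype=float)
    chans = channels.as_dict()
    for di in (0, 1):
        for dj in (0, 1):
            angle = layout[di][dj]
            out[di::2, dj::2] = chans[angle][di::2, dj::2]
    return RawMosaic(out, layout=layout)


def add_noise(
    raw: RawMosaic,
    photons_per_unit: float,
    read_noise_sd: float = 0.0,
    seed: int = 0,
) -> RawMosaic:
    """Add shot noise and read noise to a mosaic frame.

    Each pixel value ``v`` becomes ``(Poisson(v·photons_per_unit) +
    N(0, read_noise_sd²)) / photons_per_unit`` — a Poisson photon count at
    the pixel's mean plus zero-mean Gaussian read noise (in photon units),
    rescaled back to intensity units.  Deterministic given ``seed``.
    """
    if photons_per_unit <= 0:
        raise ValueError("photons_per_unit must be positive")
    if read_noise_sd < 0:
        raise ValueError("read_noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(raw.values * photons_per_unit).astype(float)
    if read_noise_sd > 0:
        counts += rng.normal(0.0, read_noise_sd, size=raw.values.shape)
    return RawMosaic(counts / photons_per_unit, layout=raw.layout)


def simulate_raw(
    phase: PhaseMap,
    delta_r: Tuple[float, float],
    amplitude: np.ndarray | None = None,
    layout=DEFAULT_LAYOUT,
    photons_per_unit: float | None = None,
    read_noise_sd: float = 0.0,
    seed: int = 0,
) -> RawMosaic:
    """Convenience composition: phase → sheared fields → channels → mosaic.

    With ``photons_per_unit`` set, shot/read noise is added; otherwise the
    frame is noiseless.
    """
    if amplitude is None:
        amplitude = np.ones_like(phase.values)
    pair = shear_field(phase, amplitude, delta_r)
    channels = polarization_intensities(pair)
    raw = mosaic(channels, layout=layout)
    if photons_per_unit is not None:
        raw = add_noise(raw, photons_per_unit, read_noise_sd, seed)
    return raw
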