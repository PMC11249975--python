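"""Phase-gradient extraction and Tikhonov-regularized integration.

The quadrant-aware arctangent of the polarization-channel differences
recovers the sheared phase difference

    Δφ(r) = φ(r + Δr) − φ(r − Δr) = atan2(I45 − I135, I0 − I90),

covering the full (−π, π] range.  The shear-difference operator is a
circular convolution whose transfer function on the discrete frequency
grid is

    H̃(u) = 2j · sin(2π u · Δr),

purely imaginary and odd, with nulls at DC, along the axis perpendicular
to Δr, and wherever u·Δr is a multiple of 1/2.  Direct division by H̃
therefore amplifies noise at near-null frequencies, so the phase is
recovered as the Tikhonov-regularized least-squares solution

    φ = F⁻¹{ conj(H̃) · F{Δφ} / (|H̃|² + α) },

a fixed linear filter.  Frequencies where H̃ = 0 do not propagate, so the
reconstructed phase is relative (zero mean).

DFT conventions: forward kernel ``e^{−2πi u·r}``, unnormalized forward and
1/N² inverse (numpy's default); ``u`` in cycles per pixel and ``Δr`` in
pixels, so ``u·Δr`` is dimensionless.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .config import OpticalConfig, ReconstructionConfig
from .demosaic import demosaic_newton
from .forward import PolarizationChannels, RawMosaic
from .phantoms import PhaseMap

__all__ = [
    "GradientMap",
    "phase_gradient",
    "gradient_transfer_function",
    "shear_difference",
    "integrate_gradient",
    "reconstruct_frame",
    "reconstruct_series",
]

logger = logging.getLogger(__name__)

_NULL_REL_TOL = 1e-12
_WRAP_WARN_FRACTION = 1e-3


@dataclass
class GradientMap:
    """Sheared phase difference per pixel, in radians within (−π, π].

    ``validity_mask`` is False where both channel differences were
    numerically zero and the gradient is undefined (reported as 0).
    """

    values: np.ndarray
    shear_half_vector_px: Tuple[float, float]
    validity_mask: np.ndarray
    pixel_pitch_um: float = 0.1725
    wavelength_um: float = 0.670

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validity_mask = np.asarray(self.validity_mask, dtype=bool)
        if self.values.shape != self.validity_mask.shape:
            raise ValueError("validity mask shape must match values")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("gradient values must be finite")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape


def phase_gradient(
    channels: PolarizationChannels,
    delta_r: Tuple[float, float] = (0.5, 0.0),
    pixel_pitch_um: float = 0.1725,
    wavelength_um: float = 0.670,
) -> GradientMap:
    """Quadrant-aware arctangent gradient from the four channels.

    Pixels where both ``I45 − I135`` and ``I0 − I90`` fall below
    ``1e-12`` of the frame maximum carry value 0 and a False validity
    mask.  Values wrap into (−π, π]; no unwrapping is attempted, but a
    warning is emitted when a noticeable fraction of pixels sits near ±π.
    """
    num = channels.I45 - channels.I135
    den = channels.I0 - channels.I90
    frame_max = max(
        float(np.max(np.abs(c))) for c in (channels.I0, channels.I45, channels.I90, channels.I135)
    )
    tol = _NULL_REL_TOL * max(frame_max, 1.0)
    undefined = (np.abs(num) < tol) & (np.abs(den) < tol)
    values = np.arctan2(num, den)
    values[undefined] = 0.0
    valid = ~undefined
    # wrap heuristic: a sheared phase difference within (-pi, pi] varies
    # smoothly, so neighbor jumps larger than pi indicate 2*pi wrapping
    jumps = (np.abs(np.diff(values, axis=0)) > np.pi).mean() + (
        np.abs(np.diff(values, axis=1)) > np.pi
    ).mean()
    if jumps > _WRAP_WARN_FRACTION:
        warnings.warn(
            "gradient shows neighbor jumps larger than π; the sheared "
            "phase difference likely exceeds the unambiguous (−π, π] "
            "range and wraps",
            UserWarning,
            stacklevel=2,
        )
    return GradientMap(
        values,
        shear_half_vector_px=(float(delta_r[0]), float(delta_r[1])),
        validity_mask=valid,
        pixel_pitch_um=pixel_pitch_um,
        wavelength_um=wavelength_um,
    )


def gradient_transfer_function(
    shape: Tuple[int, int], delta_r: Tuple[float, float]
) -> np.ndarray:
    """Transfer function ``H̃(u) = 2j sin(2π u·Δr)`` on the DFT grid.

    Purely imaginary, odd under ``u → −u``, zero at DC and along the axis
    perpendicular to the shear.  On even-sized grids with a fractional
    shear the Nyquist row/column is its own negation and the oddness
    cannot hold there; :func:`integrate_gradient` symmetrizes its filter,
    which zeroes those frequencies exactly as the real-valued spatial
    shear-difference operator does.
    """
    h, w = int(shape[0]), int(shape[1])
    if h <= 0 or w <= 0:
        raise ValueError("shape must be positive")
    dx, dy = delta_r
    uy = np.fft.fftfreq(h)[:, None]
    ux = np.fft.fftfreq(w)[None, :]
    return 2j * np.sin(2.0 * np.pi * (ux * dx + uy * dy))


def _neg_index(n: int) -> np.ndarray:
    """Index array mapping DFT bin ``u`` to ``-u`` (mod n)."""
    return (-np.arange(n)) % n


def shear_difference(values: np.ndarray, delta_r: Tuple[float, float]) -> np.ndarray:
    """Apply the shear-difference operator ``f(r+Δr) − f(r−Δr)``.

    Implemented as the circular convolution with transfer function
    ``H̃(u)``; exact for band-limited periodic fields, supports sub-pixel
    shear.
    """
    values = np.asarray(values, dtype=float)
    H = gradient_transfer_function(values.shape, delta_r)
    return np.fft.ifft2(H * np.fft.fft2(values)).real


def integrate_gradient(
    grad: GradientMap, config: Optional[ReconstructionConfig] = None
) -> PhaseMap:
    """Integrate a sheared phase difference into a (relative) phase map.

    Solves the Tikhonov-regularized least squares problem

        min_φ ‖Δφ − H̃·φ̃‖² + α·‖φ̃‖²

    frequency by frequency, i.e. applies the fixed linear filter
    ``conj(H̃)/(|H̃|² + α)``.  The gradient is mirror-padded by
    ``config.pad_px`` before the transform (edge-ringing control for
    non-periodic fields) and cropped afterwards; the result is reported
    zero-mean, since the DC component of the phase is unobservable.
    """
    if config is None:
        config = ReconstructionConfig()
    g = grad.values
    pad = int(config.pad_px)
    if pad > 0:
        g = np.pad(g, pad, mode="symmetric")
    H = gradient_transfer_function(g.shape, grad.shear_half_vector_px)
    denom = (np.abs(H) ** 2) + config.alpha
    if config.alpha == 0.0:
        # unregularized inverse filter: leave exact nulls out of the division
        filt = np.zeros_like(H)
        nz = np.abs(H) > 0
        filt[nz] = np.conj(H[nz]) / denom[nz]
    else:
        filt = np.conj(H) / denom
    # Enforce Hermitian symmetry of the filter so real gradients map to
    # real phases.  With a fractional shear, H̃ on the Nyquist lines is not
    # odd under u -> -u on the discrete grid; symmetrizing zeros the filter
    # exactly there, which is also what the real-valued spatial-domain
    # shear-difference operator does.
    filt = 0.5 * (
        filt + np.conj(filt[np.ix_(_neg_index(filt.shape[0]), _neg_index(filt.shape[1]))])
    )
    phi_c = np.fft.ifft2(filt * np.fft.fft2(g))
    scale = max(float(np.max(np.abs(g))), 1.0)
    imag_residue = float(np.max(np.abs(phi_c.imag)))
    if imag_residue > 1e-10 * scale:
        raise AssertionError(
            f"non-negligible imaginary residue {imag_residue:.3e} in the "
            "integrated phase; the filter should map real fields to real fields"
        )
    phi = phi_c.real
    if pad > 0:
        phi = phi[pad:-pad, pad:-pad]
    phi = phi - phi.mean()
    return PhaseMap(
        phi, pixel_pitch_um=grad.pixel_pitch_um, wavelength_um=grad.wavelength_um
    )


def _staged(stage: str):
    def deco(call):
        try:
            return call()
        except Exception as exc:
            exc.add_note(f"reconstruction stage: {stage}")
            raise

    return deco


def reconstruct_frame(
    raw: RawMosaic,
    optical: Optional[OpticalConfig] = None,
    recon: Optional[ReconstructionConfig] = None,
) -> Tuple[GradientMap, PhaseMap]:
    """Full inverse pipeline: demosaic → gradient → integration.

    Returns both the gradient map and the integrated phase map; the
    gradient alone is often the more sensitive readout of dynamic
    changes, while the phase map is quantitative.
    """
    optical = optical or OpticalConfig()
    recon = recon or ReconstructionConfig(alpha=optical.alpha)
    channels = _staged("demosaic")(lambda: demosaic_newton(raw))
    grad = _staged("phase_gradient")(
        lambda: phase_gradient(
            channels,
            delta_r=optical.shear_half_vector_px,
            pixel_pitch_um=optical.pixel_pitch_um,
            wavelength_um=optical.wavelength_um,
        )
    )
    phase = _staged("integrate_gradient")(lambda: integrate_gradient(grad, recon))
    return grad, phase


def reconstruct_series(
    frames: Sequence[RawMosaic],
    optical: Optional[OpticalConfig] = None,
    recon: Optional[ReconstructionConfig] = None,
) -> List[Optional[Tuple[GradientMap, PhaseMap]]]:
    """Apply :func:`reconstruct_frame` to a sequence of frames.

    Frames are processed in order with a shared configuration.  A failing
    frame is logged with its index and yields ``None`` in the output; the
    remaining frames are still processed.
    """
    results: List[Optional[Tuple[GradientMap, PhaseMap]]] = []
    for i, raw in enumerate(frames):
        try:
            results.append(reconstruct_frame(raw, optical, recon))
        except Exception:
            logger.exception("frame %d failed; continuing with remaining frames", i)
            results.append(None)
        else:
            logger.info("frame %d/%d reconstructed", i + 1, len(frames))
    return results
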