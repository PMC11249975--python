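"""Optical and reconstruction configuration.

Grid convention used throughout the package: arrays are row-major with the
origin at the top-left corner; ``x`` is the column index and ``y`` the row
index.  Every shear vector is expressed as ``(dx, dy)`` in sample-plane
pixels, where the stored value is the *half* shear ``Δr`` — the physical
beam separation is ``2·Δr``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Tuple

__all__ = [
    "OpticalConfig",
    "ReconstructionConfig",
    "DEFAULT_LAYOUT",
    "ShearWarning",
]

#: Default 2x2 polarization-filter-array layout, given as analyzer angles
#: in degrees for superpixel positions ((row 0, col 0), (row 0, col 1)),
#: ((row 1, col 0), (row 1, col 1)).  This matches the common commercial
#: division-of-focal-plane sensor arrangement; any permutation of the four
#: angles is accepted wherever a layout is taken.
DEFAULT_LAYOUT: Tuple[Tuple[int, int], Tuple[int, int]] = ((90, 45), (135, 0))


class ShearWarning(UserWarning):
    """Raised when the configured shear exceeds the diffraction limit."""


@dataclass(frozen=True)
class OpticalConfig:
    """Optical parameters of the DIC/polarization-camera system.

    Parameters
    ----------
    wavelength_um
        Center wavelength of the illumination in micrometres.
    numerical_aperture
        Objective numerical aperture, in ``(0, 1]``.
    magnification
        Lateral magnification from sample to camera.
    camera_pixel_um
        Physical camera pixel pitch in micrometres.
    shear_half_vector_px
        Half shear vector ``Δr = (dx, dy)`` in sample-plane pixels; the two
        sheared beams are displaced by ``±Δr`` so their separation is
        ``2·Δr``.
    alpha
        Tikhonov regularization parameter used when integrating the phase
        gradient.
    """

    wavelength_um: float = 0.670
    numerical_aperture: float = 0.5
    magnification: float = 20.0
    camera_pixel_um: float = 3.45
    shear_half_vector_px: Tuple[float, float] = (0.5, 0.0)
    alpha: float = 3e-4

    def __post_init__(self) -> None:
        if self.wavelength_um <= 0:
            raise ValueError("wavelength_um must be positive")
        if not (0.0 < self.numerical_aperture <= 1.0):
            raise ValueError("numerical_aperture must lie in (0, 1]")
        if self.magnification <= 0:
            raise ValueError("magnification must be positive")
        if self.camera_pixel_um <= 0:
            raise ValueError("camera_pixel_um must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.full_shear_um > self.diffraction_limit_um:
            warnings.warn(
                f"full shear {self.full_shear_um:.4f} um exceeds the "
                f"diffraction limit lambda/(2 NA) = "
                f"{self.diffraction_limit_um:.4f} um; the two beams are no "
                "longer separated by less than the system's diffraction limit",
                ShearWarning,
                stacklevel=2,
            )

    @property
    def pixel_pitch_um(self) -> float:
        """Sample-plane pixel pitch, camera pitch divided by magnification."""
        return self.camera_pixel_um / self.magnification

    @property
    def full_shear_um(self) -> float:
        """Magnitude of the full beam separation ``2·|Δr|`` in micrometres."""
        dx, dy = self.shear_half_vector_px
        return 2.0 * (dx * dx + dy * dy) ** 0.5 * self.pixel_pitch_um

    @property
    def diffraction_limit_um(self) -> float:
        """Coherent diffraction limit ``λ / (2 NA)`` in micrometres."""
        return self.wavelength_um / (2.0 * self.numerical_aperture)

    @property
    def field_of_view_um(self) -> float:
        """Field of view per 2048 pixels, for reference."""
        return 2048 * self.pixel_pitch_um


@dataclass(frozen=True)
class ReconstructionConfig:
    """Parameters of the Tikhonov-regularized gradient integration.

    ``alpha = 0`` is the unregularized inverse filter, which divides by zero
    at the nulls of the gradient transfer function; it is permitted only
    when ``allow_unregularized`` is set explicitly.
    """

    alpha: float = 3e-4
    pad_px: int = 32
    allow_unregularized: bool = False

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.pad_px < 0:
            raise ValueError("pad_px must be non-negative")
        if self.alpha == 0 and not self.allow_unregularized:
            raise ValueError(
                "alpha = 0 is unstable at the nulls of the transfer "
                "function; pass allow_unregularized=True to force it"
            )


def validate_layout(layout) -> Tuple[Tuple[int, int], Tuple[int, int]]:
    """Check that ``layout`` is a 2x2 permutation of {0, 45, 90, 135}."""
    try:
        (a, b), (c, d) = layout
    except (TypeError, ValueError) as exc:
        raise ValueError(f"layout must be a 2x2 nested sequence, got {layout!r}") from exc
    angles = (int(a), int(b), int(c), int(d))
    if sorted(angles) != [0, 45, 90, 135]:
        raise ValueError(
            f"layout must be a permutation of (0, 45, 90, 135), got {angles}"
        )
    return ((angles[0], angles[1]), (angles[2], angles[3]))
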