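"""Polarization-filter-array demosaicking.

Each channel of the 2x2 mosaic is sampled on a lattice with period 2 in
both directions.  Two interpolators recover full-resolution channels:

``demosaic_newton``
    Edge-aware third-order Newton (divided-difference) polynomial
    interpolation.  Missing pixels that share a row (column) with native
    samples are filled from the 4 nearest same-channel samples along that
    row (column) with the order-3 Newton polynomial, equivalent to the
    midpoint cubic stencil (−1, 9, 9, −1)/16.  Diagonal positions are then
    filled from the partially completed grid, blending the horizontal and
    vertical cubic estimates with weights inversely proportional to the
    local absolute second difference, so the smoother direction dominates
    and edges are preserved.

``demosaic_bilinear``
    Separable linear interpolation on each channel's native lattice — the
    conventional baseline.

Border support comes from padding each channel's native lattice by two
samples with an odd ("derivative-preserving") reflection, which continues
globally affine fields exactly; interpolation therefore reproduces
constant and affine channels to round-off everywhere, including borders.
Native samples pass through unchanged and interpolated values are clipped
at zero from below.
"""

from __future__ import annotations

from typing import Callable, Dict, Tuple

import numpy as np

from .forward import PolarizationChannels, RawMosaic

__all__ = ["split_mosaic", "demosaic_newton", "demosaic_bilinear"]

_PAD = 2  # native-lattice samples on each side
_EDGE_EPS = 1e-10


def split_mosaic(raw: RawMosaic) -> Dict[int, Tuple[np.ndarray, Tuple[int, int]]]:
    """Split a mosaic into four quarter-resolution channel images.

    Returns a mapping ``angle -> (image, (row_offset, col_offset))`` where
    the image is the exact subsampling of that channel's native pixels and
    the offset locates its lattice within the full frame.
    """
    out: Dict[int, Tuple[np.ndarray, Tuple[int, int]]] = {}
    for di in (0, 1):
        for dj in (0, 1):
            angle = raw.layout[di][dj]
            out[angle] = (raw.values[di::2, dj::2].copy(), (di, dj))
    return out


def _check_size(raw: RawMosaic) -> None:
    h, w = raw.shape
    if h < 8 or w < 8:
        raise ValueError(f"frame {h}x{w} too small to demosaic; need at least 8x8")


def _cubic_axial(samples: np.ndarray, axis: int) -> np.ndarray:
    """Order-3 Newton interpolation at the midpoints of a sample lattice.

    For samples at positions (−3, −1, 1, 3) relative to the target, the
    divided-difference polynomial evaluates to the midpoint cubic stencil
    (−1, 9, 9, −1)/16.  Length shrinks by 3 along ``axis``.
    """

    def sl(a, b):
        s = [slice(None)] * samples.ndim
        s[axis] = slice(a, b if b != 0 else None)
        return samples[tuple(s)]

    return (-sl(0, -3) + 9.0 * sl(1, -2) + 9.0 * sl(2, -1) - sl(3, 0)) / 16.0


def _second_difference(samples: np.ndarray, axis: int) -> np.ndarray:
    def sl(a, b):
        s = [slice(None)] * samples.ndim
        s[axis] = slice(a, b if b != 0 else None)
        return samples[tuple(s)]

    return np.abs(sl(0, -3) - sl(1, -2) - sl(2, -1) + sl(3, 0))


def _interp_newton(native: np.ndarray) -> np.ndarray:
    """Interpolate a (padded) native lattice to the full-resolution grid.

    ``native[k, m]`` lands on full-grid position ``(2k, 2m)``.
    """
    nr, nc = native.shape
    out = np.full((2 * nr, 2 * nc), np.nan)
    out[::2, ::2] = native

    # Axial passes: rows/columns that contain native samples.
    est_h = _cubic_axial(native, axis=1)
    out[::2, 3 : 3 + 2 * est_h.shape[1] : 2] = est_h
    est_v = _cubic_axial(native, axis=0)
    out[3 : 3 + 2 * est_v.shape[0] : 2, ::2] = est_v

    # Diagonal pass on the partially filled grid: a diagonal target's row
    # holds vertical-pass values at native columns, and its column holds
    # horizontal-pass values at native rows.
    row_grid = out[1::2, ::2]
    col_grid = out[::2, 1::2]
    nr_d, nc_d = nr, nc
    dh = _cubic_axial(row_grid, axis=1)          # target col index b = m + 1
    wh = 1.0 / (_EDGE_EPS + _second_difference(row_grid, axis=1))
    dv = _cubic_axial(col_grid, axis=0)          # target row index a = k + 1
    wv = 1.0 / (_EDGE_EPS + _second_difference(col_grid, axis=0))

    dh_full = np.full((nr_d, nc_d), np.nan)
    wh_full = np.zeros((nr_d, nc_d))
    dh_full[: dh.shape[0], 1 : 1 + dh.shape[1]] = dh
    wh_full[: wh.shape[0], 1 : 1 + wh.shape[1]] = wh
    dv_full = np.full((nr_d, nc_d), np.nan)
    wv_full = np.zeros((nr_d, nc_d))
    dv_full[1 : 1 + dv.shape[0], : dv.shape[1]] = dv
    wv_full[1 : 1 + wv.shape[0], : wv.shape[1]] = wv

    h_ok = np.isfinite(dh_full)
    v_ok = np.isfinite(dv_full)
    wh_full = np.where(h_ok, wh_full, 0.0)
    wv_full = np.where(v_ok, wv_full, 0.0)
    num = np.where(h_ok, wh_full * dh_full, 0.0) + np.where(v_ok, wv_full * dv_full, 0.0)
    den = wh_full + wv_full
    blend = np.full((nr_d, nc_d), np.nan)
    np.divide(num, den, out=blend, where=den > 0)
    out[1::2, 1::2] = blend
    return out


def _interp_bilinear(native: np.ndarray) -> np.ndarray:
    nr, nc = native.shape
    out = np.full((2 * nr, 2 * nc), np.nan)
    out[::2, ::2] = native
    mid_h = (native[:, :-1] + native[:, 1:]) / 2.0
    out[::2, 1 : 1 + 2 * mid_h.shape[1] : 2] = mid_h
    mid_v = (native[:-1, :] + native[1:, :]) / 2.0
    out[1 : 1 + 2 * mid_v.shape[0] : 2, ::2] = mid_v
    diag = (native[:-1, :-1] + native[:-1, 1:] + native[1:, :-1] + native[1:, 1:]) / 4.0
    out[1 : 1 + 2 * diag.shape[0] : 2, 1 : 1 + 2 * diag.shape[1] : 2] = diag
    return out


def _demosaic(raw: RawMosaic, interp: Callable[[np.ndarray], np.ndarray]) -> PolarizationChannels:
    _check_size(raw)
    h, w = raw.shape
    channels: Dict[int, np.ndarray] = {}
    for di in (0, 1):
        for dj in (0, 1):
            angle = raw.layout[di][dj]
            native = raw.values[di::2, dj::2]
            padded = np.pad(native, _PAD, mode="reflect", reflect_type="odd")
            full = interp(padded)
            # native sample k sits at full-grid row 2(k + _PAD),
            # i.e. original row i = di + 2k maps to full row i - di + 2*_PAD
            r0, c0 = 2 * _PAD - di, 2 * _PAD - dj
            crop = full[r0 : r0 + h, c0 : c0 + w]
            if np.any(np.isnan(crop)):
                raise AssertionError("demosaic left unfilled pixels")
            # clip interpolated pixels at 0, restore native samples bit-for-bit
            crop = np.maximum(crop, 0.0)
            crop[di::2, dj::2] = native
            channels[angle] = crop
    return PolarizationChannels(
        I0=channels[0], I45=channels[45], I90=channels[90], I135=channels[135]
    )


def demosaic_newton(raw: RawMosaic) -> PolarizationChannels:
    """Edge-aware Newton-polynomial demosaicking (see module docstring)."""
    return _demosaic(raw, _interp_newton)


def demosaic_bilinear(raw: RawMosaic) -> PolarizationChannels:
    """Separable bilinear demosaicking baseline."""
    return _demosaic(raw, _interp_bilinear)
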