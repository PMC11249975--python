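"""TIFF input/output with structured-text metadata sidecars.

Raw mosaics are exchanged as single-page grayscale TIFF (16-bit unsigned
for camera-like export, 32-bit float for noiseless simulations); phase and
gradient maps as 32-bit float TIFF, multi-page for time series.  Every
written image gets a YAML sidecar (``<path>.meta.yaml``) recording the
information needed to interpret and reproduce it: layout, scale factor,
pixel pitch, wavelength, regularization, shear, seed, and a free-form
configuration echo.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import tifffile
import yaml

from . import __version__ as _version
from .config import DEFAULT_LAYOUT, validate_layout
from .forward import RawMosaic
from .phantoms import PhaseMap

__all__ = [
    "sidecar_path",
    "read_sidecar",
    "write_sidecar",
    "load_raw",
    "save_raw",
    "save_channels",
    "save_phase",
    "load_phase",
    "save_report",
]

logger = logging.getLogger(__name__)


def sidecar_path(path: Union[str, Path]) -> Path:
    return Path(str(path) + ".meta.yaml")


def write_sidecar(path: Union[str, Path], metadata: Dict) -> None:
    with open(sidecar_path(path), "w") as fh:
        yaml.safe_dump({"software": f"ssqpgm {_version}", **metadata}, fh, sort_keys=False)


def read_sidecar(path: Union[str, Path]) -> Optional[Dict]:
    sp = sidecar_path(path)
    if not sp.exists():
        return None
    with open(sp) as fh:
        return yaml.safe_load(fh)


def save_raw(
    raw: RawMosaic,
    path: Union[str, Path],
    dtype: str = "float32",
    full_scale_fraction: float = 0.9,
    metadata: Optional[Dict] = None,
) -> None:
    """Write a mosaic frame as grayscale TIFF plus a metadata sidecar.

    ``dtype="uint16"`` emulates a camera frame: intensities are scaled so
    the maximum sits at ``full_scale_fraction`` of the 16-bit range and
    the scale is recorded in the sidecar so loading undoes it.
    ``dtype="float32"`` stores values as-is (lossless at float32).
    """
    path = Path(path)
    meta: Dict = {
        "kind": "raw_mosaic",
        "layout": [list(row) for row in raw.layout],
        **(metadata or {}),
    }
    if dtype == "uint16":
        peak = float(raw.values.max())
        scale = full_scale_fraction * 65535.0 / peak if peak > 0 else 1.0
        data = np.clip(np.round(raw.values * scale), 0, 65535).astype(np.uint16)
        meta["intensity_scale"] = scale
    elif dtype == "float32":
        data = raw.values.astype(np.float32)
        meta["intensity_scale"] = 1.0
    else:
        raise ValueError(f"unsupported dtype {dtype!r}; use 'uint16' or 'float32'")
    tifffile.imwrite(path, data)
    write_sidecar(path, meta)


def load_raw(
    path: Union[str, Path], layout=None
) -> RawMosaic:
    """Load a raw mosaic frame from a grayscale TIFF.

    The polarization layout and any intensity scale are taken from the
    sidecar when present; otherwise ``layout`` (or the package default,
    with a logged warning) is used.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raw frame not found: {path}")
    data = tifffile.imread(path)
    if data.ndim != 2:
        raise ValueError(
            f"{path} has shape {data.shape}; a raw mosaic must be a single "
            "grayscale (2-D) image, not multi-channel/color"
        )
    h, w = data.shape
    if h % 2 or w % 2:
        raise ValueError(f"{path} has odd dimensions {h}x{w}; mosaics must be even")
    values = data.astype(float)
    meta = read_sidecar(path)
    if meta is not None:
        scale = float(meta.get("intensity_scale", 1.0))
        if scale != 1.0:
            values = values / scale
        layout = meta.get("layout", layout)
    if layout is None:
        logger.warning(
            "%s: no layout in sidecar or argument; assuming default %s",
            path,
            DEFAULT_LAYOUT,
        )
        layout = DEFAULT_LAYOUT
    return RawMosaic(values, layout=validate_layout(layout))


def save_channels(channels, path: Union[str, Path], metadata: Optional[Dict] = None) -> None:
    """Write four polarization channels as a 4-page 32-bit float TIFF.

    Page order is 0, 45, 90, 135 degrees, recorded in the sidecar.
    """
    path = Path(path)
    stack = np.stack(
        [c.astype(np.float32) for c in (channels.I0, channels.I45, channels.I90, channels.I135)]
    )
    tifffile.imwrite(path, stack, photometric="minisblack")
    write_sidecar(
        path,
        {"kind": "polarization_channels", "page_angles_deg": [0, 45, 90, 135], **(metadata or {})},
    )


def save_phase(
    phase: Union[PhaseMap, Sequence[PhaseMap]],
    path: Union[str, Path],
    metadata: Optional[Dict] = None,
) -> None:
    """Write phase (or gradient) maps as 32-bit float TIFF, in radians.

    A sequence of maps becomes a multi-page file.  The sidecar records
    pixel pitch and wavelength plus any extra ``metadata`` (e.g. α, Δr).
    """
    path = Path(path)
    series = [phase] if isinstance(phase, PhaseMap) else list(phase)
    if not series:
        raise ValueError("no phase maps to save")
    stack = np.stack([p.values.astype(np.float32) for p in series])
    tifffile.imwrite(
        path, stack[0] if len(series) == 1 else stack, photometric="minisblack"
    )
    write_sidecar(
        path,
        {
            "kind": "phase_map",
            "units": "radians",
            "n_frames": len(series),
            "pixel_pitch_um": float(series[0].pixel_pitch_um),
            "wavelength_um": float(series[0].wavelength_um),
            **(metadata or {}),
        },
    )


def load_phase(path: Union[str, Path]) -> List[PhaseMap]:
    """Load one or more phase maps written by :func:`save_phase`."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    meta = read_sidecar(path) or {}
    pitch = float(meta.get("pixel_pitch_um", 0.1725))
    wl = float(meta.get("wavelength_um", 0.670))
    return [PhaseMap(frame.astype(float), pitch, wl) for frame in data]


def save_report(report, path: Union[str, Path]) -> None:
    """Serialize a :class:`~ssqpgm.metrics.ValidationReport` as YAML text."""
    with open(path, "w") as fh:
        yaml.safe_dump(
            {"software": f"ssqpgm {_version}", **report.as_dict()}, fh, sort_keys=False
        )
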