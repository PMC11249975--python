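"""Simulate a cell-like scene and reconstruct its phase from one frame.

Builds a smooth blob phantom, images it through the polarization-camera
DIC forward model (shot noise at ~1e4 photons/px), and runs the inverse
pipeline: demosaic -> quadrant-aware arctangent gradient -> Tikhonov
integration.  Prints the agreement with the ground truth seen through the
reconstruction pass band.
"""

import numpy as np

from ssqpgm import (
    OpticalConfig,
    PhantomSpec,
    ReconstructionConfig,
    gradient_transfer_function,
    make_phantom,
    reconstruct_frame,
    simulate_raw,
)

optical = OpticalConfig()  # 670 nm, 20x/0.5NA, 3.45 um camera pixels
recon = ReconstructionConfig(alpha=3e-4, pad_px=0)

spec = PhantomSpec(
    kind="cell_blobs", n_blobs=6, n_granules=0,
    blob_radius_um=(2.0, 4.0), blob_peak_phase_rad=(0.1, 0.5),
    margin_px=12, edge_sigma_px=2.0, seed=1,
)
phantom, _ = make_phantom(spec, optical, (128, 128))

raw = simulate_raw(
    phantom, optical.shear_half_vector_px, photons_per_unit=1e4, seed=1
)
gradient, phase = reconstruct_frame(raw, optical, recon)

H = gradient_transfer_function(phantom.shape, optical.shear_half_vector_px)
passband = np.abs(H) ** 2 / (np.abs(H) ** 2 + recon.alpha)
projected = np.fft.ifft2(np.fft.fft2(phantom.values) * passband).real
projected -= projected.mean()

rms = np.sqrt(np.mean((phase.values - projected) ** 2))
print(f"scene peak phase:            {phantom.values.max():.3f} rad")
print(f"gradient dynamic range:      {np.ptp(gradient.values):.4f} rad")
print(f"rms error vs pass-band truth: {rms:.5f} rad")
# The reconstruction is relative (zero-mean) and matches the ground truth
# projected through |H|^2/(|H|^2+alpha).  The ~0.03 rad rms residual is
# dominated by shot noise amplified near the low-frequency edge of the
# pass band (1/|H| grows toward the nulls); rerun with
# photons_per_unit=None to see the noiseless residual drop to the
# demosaic interpolation level (~1e-4 rad).
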