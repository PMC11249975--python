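# ssqpgm

Computational pipeline for **single-shot quantitative phase gradient
microscopy (ss-QPGM)** — phase imaging with a DIC microscope whose
analyzer is replaced by a quarter-wave plate and a polarization-filter-array
(division-of-focal-plane) camera, so that a single exposure captures the
four analyzer channels needed to reconstruct a quantitative phase map.

The package is aimed at people building or characterizing such
instruments: it provides a Jones-calculus **forward simulator** of the
measurement, the **inverse pipeline** (demosaicking → phase gradient →
regularized integration), calibrated **synthetic phase targets**
(USAF-1951-style bar elements, uniform pads, cell-like scenes) with exact
ground truth, and the **validation metrics** used to characterize a real
system (contrast/MTF sweeps, region SNR, thickness calibration,
information-theoretic resolution bounds).

## Model

The sample plane is described by an amplitude *A*(**r**) and a phase
φ(**r**). Two orthogonally polarized copies of the field, sheared by
±Δ**r**, interfere after a quarter-wave plate and a micro-polarizer array.
With

    f∓ = A(r ∓ Δr)·exp(iφ(r ∓ Δr)),
    S  = |f−|² + |f+|²,  C = Re(f̄− f+),  Sn = Im(f̄− f+),

the four analyzer channels are

    I0 = S/2 + C,  I90 = S/2 − C,  I45 = S/2 + Sn,  I135 = S/2 − Sn,

which satisfy I0 + I90 = I45 + I135 and give the sheared phase difference
amplitude-independently:

    Δφ(r) = φ(r+Δr) − φ(r−Δr) = atan2(I45 − I135, I0 − I90).

The shear-difference operator has transfer function
H̃(**u**) = 2j·sin(2π **u**·Δ**r**) — zero at DC, along the axis
perpendicular to the shear, and wherever **u**·Δ**r** is a half-integer —
so the phase is recovered as the Tikhonov-regularized least-squares
solution

    φ = F⁻¹{ H̃* · F{Δφ} / (|H̃|² + α) },    α = 3×10⁻⁴ by default,

a fixed linear filter that suppresses noise amplification at the nulls.
The recovered phase is relative (zero mean). Default optics: λ = 670 nm,
20×/0.5 NA, 3.45 µm camera pixels (0.1725 µm sample-plane pitch),
half-shear Δr = (0.5, 0) px.

## Worked example

`examples/thickness_calibration.py` runs the end-to-end calibration:
bar targets (n = 1.52 in air) at seven thicknesses are imaged through the
forward model with shot noise (~10⁴ photons/px) and reconstructed; each
recovered phase step is converted back to thickness via
d = φ·λ/(2π(n−1)):

```
nominal (nm)  recovered (nm)
       50         48.71
      100         97.61
      150        147.00
      200        197.02
      250        246.18
      300        293.83
      350        345.30
slope      = 0.9867   (1.0 = perfect; slightly below from
              pass-band attenuation of the pattern envelope)
intercept  = -0.82 nm
pearson r  = 0.999978  (linearity of the phase response)
```

The slope just under 1 is the expected signature of the regularized
integration (low-frequency pass-band attenuation); the Pearson r near 1
says the phase response is linear in thickness across the series.
`examples/mtf_and_resolution.py` sweeps contrast against spatial
frequency in both orientations (exposing the anisotropic null-axis
response) and prints the information-theoretic resolution bound
λ/(NA·log₂(1+SNR)); `examples/simulate_and_reconstruct.py` reconstructs a
cell-like scene from a single noisy frame.

## Command line

A thin CLI wraps the library for batch work:

```sh
ssqpgm simulate    -c run.yaml -o out/      # phantom -> raw mosaic TIFF
ssqpgm reconstruct -c run.yaml -o out/ raw.tif [raw2.tif ...]
ssqpgm validate    -c run.yaml -o out/      # calibration + MTF + SNR report
```

Configuration is one flat YAML file (flags override; unknown keys are
rejected); every run writes a resolved-config echo and YAML metadata
sidecars next to its TIFF outputs, and is bit-reproducible from config +
seed.

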