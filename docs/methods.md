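# Methods

## Measurement model

ss-QPGM modifies a DIC microscope: Wollaston prisms split the illumination
into two orthogonally polarized beams displaced by ±Δ**r** about each image
point (full separation 2Δ**r**, kept below the diffraction limit λ/2NA; the
configuration warns if it is not), and a quarter-wave plate at 45° maps the
two sheared linear components to opposite circular states so that a linear
analyzer at angle θ reads out their phase difference. The package fixes the
standard DIC-polarimetry convention in which the analyzer 0° axis lies at
45° to the shear axes; under this convention the channel intensities have
the exact closed forms given in the README and the quadrant-aware
arctangent of the channel differences is *identically* the sheared phase
difference Δφ = φ(**r**+Δ**r**) − φ(**r**−Δ**r**), independent of any
positive amplitude modulation (the common factor A(r−Δr)A(r+Δr) cancels).
Other analyzer conventions map onto this one by an angle offset.

Assumptions: scalar fields, a non-birefringent sample, no pupil /
partial-coherence model (the simulator represents shear and polarization
analysis only), periodic boundaries (shear is applied as a frequency-domain
phase ramp, exact for band-limited fields). Quantitative comparisons
therefore use scenes that are band-limited and periodic-friendly (zero-phase
margins, or features kept inside the frame).

## Inverse pipeline

1. **Demosaic.** The 2×2 polarization mosaic is split into four channels on
   period-2 lattices. The default interpolator builds order-3 Newton
   (divided-difference) polynomials from the four nearest same-channel
   samples along rows and columns — the midpoint stencil (−1, 9, 9, −1)/16 —
   filling axial neighbors first, then diagonal positions from the partially
   completed grid, blending the horizontal and vertical estimates with
   weights inversely proportional to the local absolute second difference so
   that the smoother direction dominates across edges. Borders are handled by
   padding each channel's native lattice with two samples of *odd* reflection,
   which continues affine fields exactly; constant and affine channels are
   therefore reproduced to round-off everywhere. Native samples always pass
   through unchanged; interpolated values are clipped at zero. A separable
   bilinear interpolator is provided as the baseline; on band-limited test
   mosaics the Newton scheme has lower RMSE in ≥ 90% of seeded trials.
   The exact stencil of the interpolation used on the original instrument is
   not public; this scheme realizes the same Newton-polynomial,
   edge-preserving idea in a fully specified, testable form.

2. **Phase gradient.** Δφ = atan2(I45−I135, I0−I90), covering (−π, π].
   Pixels where both differences are below 10⁻¹² of the frame maximum are
   reported as 0 with a false validity mask. No unwrapping is performed; a
   heuristic (fraction of neighbor jumps larger than π, threshold 10⁻³)
   warns when the shear or the sample puts Δφ outside the unambiguous range.
   The near-±π pixel count is not used as the detector because coarsely
   sampled wrapped gradients can skip the ±π band entirely.

3. **Integration.** φ = F⁻¹{H̃*·F{Δφ}/(|H̃|²+α)} with
   H̃ = 2j·sin(2π**u**·Δ**r**) evaluated on the DFT grid (forward kernel
   e^(−2πi u·r), unnormalized forward / 1/N² inverse; **u** in cycles per
   pixel, Δ**r** in pixels). α defaults to 3×10⁻⁴; α = 0 (pure inverse
   filter, unstable near nulls) requires an explicit flag. The gradient is
   mirror-padded by `pad_px` (default 32) before the transform and cropped
   after, suppressing edge ringing for non-periodic fields; the result is
   reported zero-mean since the phase DC is unobservable. On even grids with
   fractional shear, H̃ on the Nyquist row/column is its own negation
   partner and cannot be odd there; the filter is Hermitian-symmetrized,
   which zeroes exactly those bins — provably the same treatment the
   real-valued spatial shear-difference operator applies — and makes the
   output real to machine precision. The whole filter matches an explicit
   dense Tikhonov normal-equations solve to ~10⁻¹³ on 16×16 grids.

## Synthetic targets

Bar elements follow USAF-1951 indexing, f = 2^(group+(element−1)/6) lp/mm;
bar width is half the line-pair period and bar length five times the width.
Feature phase is the thin-sample delay (2π/λ)(n_target−n_medium)d, default
n = 1.52 in air at λ = 670 nm (100 nm → 0.488 rad). Edges are rendered at
4× supersampling then box-averaged, so values lie in [0, level] with exact
levels away from the one-pixel edge band; per-feature bar and background
masks accompany every phantom. Cell-like scenes are seeded sums of smooth,
compactly supported radial bumps (C¹ at the boundary; cytoplasm-scale radii
3–8 µm) plus small high-phase granules, deterministic given the seed; an
optional margin keeps all features inside a zero-phase border band.

**Edge smoothing.** `make_phantom` renders sharp geometry by default, but
every quantitative end-to-end driver smooths the rendered phase with a
Gaussian at the optics-derived scale σ = 0.21·λ/NA (≈1.6 px at the default
configuration, `edge_sigma_px="auto"`). The reason is physical: at 0.1725 µm
sampling the coherent cutoff is 0.129 cycles/px, so single-pixel edges could
never reach a real camera, and feeding them to the demosaic stage produces
an interpolation bias that grows nonlinearly with modulation depth. With
the band-limited rendering the pipeline's thickness response is linear to
r > 0.9999.

## Noise

Shot noise is Poisson at `value·photons_per_unit` counts per pixel plus
optional zero-mean Gaussian read noise, rescaled to intensity units;
deterministic given the seed. ~10⁴ photons/px is used as the default
exposure for noisy validations.

## Validation metrics and protocol choices

* **Contrast** of a feature is 100·(mean(bars)−mean(background))/nominal
  phase, with bar interiors eroded by 1 px (2 px for bars wider than 16 px)
  to exclude edge ringing. The background is the *adjacent* gap region of
  the pattern, which cancels the low-frequency pattern envelope the
  regularized integration attenuates — the same reason one measures "bars
  minus slide" right next to a feature on a real target. Normalization by
  the nominal phase makes 100% = full designed step recovered.
* **MTF sweep** pushes elements through the full forward + inverse pipeline
  in both orientations. The parallel sweep probes the pass band; the
  perpendicular sweep exposes the anti-symmetric response (spectral content
  along the null axis is unobservable, so large/low-frequency features lose
  contrast — the ~8 µm feature, group 6 element 1, is the top of the
  high-contrast regime at the defaults, passing at ~97%, while 31 µm bars
  drop to ~57% because their fundamental sits at |H̃|² ≈ α).
* **Calibration** uses group 7 element 1 (3.9 µm bars), chosen so that the
  slowest spectral component of the pattern (its envelope at 1/(5·bar
  width) ≈ 0.009 cycles/px) clears the |H̃|² ≈ α stop band edge
  (~0.003 cycles/px). Recovered phase is converted to thickness with
  d = φ·λ/(2π(n−1)) and regressed (ordinary least squares) against nominal;
  the Pearson r (not r²) is reported. Noiseless, the slope is 0.98 — the
  pass-band attenuation signature — with r ≈ 1.
* **SNR** is mean/sample-standard-deviation (ddof = 1) over a uniform
  feature interior (group 6 element 1 by convention); a zero-variance
  region is flagged and reported infinite.
* **Resolution bounds**: information-theoretic λ/(NA·log₂(1+SNR)) and the
  physical rules of thumb λ/(k·NA), k = 3..4, reported in nm, alongside
  the coherent (NA/λ = 746 lp/mm) and incoherent (2NA/λ = 1493 lp/mm)
  cutoffs at the defaults.

## What the synthetic data does and does not show

The generator emulates geometry, phase levels, band-limited rendering,
mosaic sampling, and photon noise. It does **not** model the physical
pupil (diffraction MTF), partial coherence, sample birefringence,
polarizer extinction, or filter-array misalignment — so passing tests
demonstrate the correctness and self-consistency of the processing chain,
not the instrument's hardware-limited figures (a measured SNR of ~25 or
20% contrast at 912.3 lp/mm depend on real optics and detector noise and
are treated here only as inputs to the resolution-bound formulas).

## Problem sizes and tolerances

Default validation runs use 512×512 frames (seven-thickness calibration,
SNR scene) and auto-sized grids for MTF elements (1.5× the pattern extent,
rounded up to a power of two); these sizes put every quantity well past
its asymptotic behavior while keeping the full suite in seconds. Exact
identities (channel conservation, round-trip gradient, dense-oracle
agreement) are asserted at 10⁻⁸–10⁻¹²; full-pipeline comparisons against
pass-band-projected ground truth are asserted at the demosaic
interpolation scale (~10⁻³·amplitude on smooth scenes), which is the
stage's genuine accuracy limit on a period-2 lattice.

## Known limitations

* Anisotropic response is inherent to a fixed shear: structure along the
  null axis is unrecoverable without shear rotation, illumination
  modulation, or learned priors — all out of scope here.
* Phase is relative (zero-mean); absolute offsets require a reference.
* Gradients beyond ±π wrap and are only warned about, not unwrapped.
* The Newton demosaic is a faithful realization of the published idea, not
  a bit-exact replica of any vendor implementation.
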