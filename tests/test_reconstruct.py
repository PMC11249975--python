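import logging

import numpy as np
import pytest

from ssqpgm import (
    GradientMap,
    OpticalConfig,
    PhaseMap,
    PolarizationChannels,
    ReconstructionConfig,
    gradient_transfer_function,
    integrate_gradient,
    phase_gradient,
    polarization_intensities,
    reconstruct_frame,
    reconstruct_series,
    shear_difference,
    shear_field,
    simulate_raw,
)


def gradient_of(values, dr=(0.5, 0.0), mask=None):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    return GradientMap(values, dr, mask)


class TestPhaseGradient:
    def make_channels(self, num, den):
        base = np.full((8, 8), 2.0)
        return PolarizationChannels(
            I0=base + den / 2, I90=base - den / 2, I45=base + num / 2, I135=base - num / 2
        )

    def test_zero_numerator(self):
        g = phase_gradient(self.make_channels(0.0, 1.0))
        assert np.allclose(g.values, 0.0)
        assert g.validity_mask.all()

    def test_equal_positive_differences_give_quarter_pi(self):
        g = phase_gradient(self.make_channels(0.5, 0.5))
        assert np.allclose(g.values, np.pi / 4)

    def test_quadrant_awareness_beyond_half_pi(self):
        # negative denominator: a plain ratio arctangent could not reach here
        g = phase_gradient(self.make_channels(0.5, -0.5))
        assert np.allclose(g.values, 3 * np.pi / 4)

    def test_undefined_pixels_masked(self):
        num = np.zeros((8, 8))
        den = np.zeros((8, 8))
        den[0, 0] = 1.0
        ch = self.make_channels(num, den)
        g = phase_gradient(ch)
        assert g.validity_mask[0, 0]
        assert not g.validity_mask[1, 1]
        assert g.values[1, 1] == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            PolarizationChannels(
                I0=np.ones((4, 4)), I45=np.ones((4, 4)),
                I90=np.ones((4, 4)), I135=np.ones((6, 6)),
            )

    def test_wrapping_warned(self, optical):
        # sheared phase difference beyond pi wraps; heuristic should warn
        n = 64
        x = np.arange(n)
        phi = 3.5 * np.sin(2 * np.pi * 4 * x / n)[None, :] * np.ones((n, 1))
        pm = PhaseMap(phi, optical.pixel_pitch_um, optical.wavelength_um)
        ch = polarization_intensities(shear_field(pm, np.ones((n, n)), (4.0, 0.0)))
        with pytest.warns(UserWarning, match="wrap"):
            phase_gradient(ch, (4.0, 0.0))


class TestTransferFunction:
    def test_dc_null(self):
        H = gradient_transfer_function((8, 8), (0.5, 0.0))
        assert H[0, 0] == 0.0

    def test_quarter_cycle_gives_2j(self):
        # u = (0.25, 0) with delta_r = (1, 0): u . delta_r = 1/4
        H = gradient_transfer_function((8, 8), (1.0, 0.0))
        assert H[0, 2] == pytest.approx(2j)

    def test_purely_imaginary_and_odd(self):
        # odd grid sizes: every frequency has a distinct negation partner
        H = gradient_transfer_function((11, 9), (0.5, 0.25))
        assert np.allclose(H.real, 0.0)
        neg = H[np.ix_((-np.arange(11)) % 11, (-np.arange(9)) % 9)]
        assert np.allclose(neg, -H)
        assert np.allclose(neg, np.conj(H))

    def test_null_axis_perpendicular_to_shear(self):
        H = gradient_transfer_function((16, 16), (0.5, 0.0))
        assert np.allclose(H[:, 0], 0.0)  # all uy at ux = 0


class TestIntegrateGradient:
    def test_zero_gradient_gives_zero_phase(self):
        out = integrate_gradient(gradient_of(np.zeros((16, 16))))
        assert np.allclose(out.values, 0.0)

    def test_sinusoid_attenuation_closed_form(self):
        # u0 . delta_r = 1/4 -> |H| = 2; recovered amplitude is
        # |H|^2/(|H|^2 + alpha) = 4/(4 + 3e-4) of the true amplitude
        n = 16
        dr = (1.0, 0.0)
        x = np.arange(n)
        phi = np.sin(2 * np.pi * 0.25 * x)[None, :] * np.ones((n, 1))
        grad = shear_difference(phi, dr)
        out = integrate_gradient(gradient_of(grad, dr), ReconstructionConfig(pad_px=0))
        factor = np.max(np.abs(out.values)) / np.max(np.abs(phi - phi.mean()))
        assert factor == pytest.approx(4 / (4 + 3e-4), abs=1e-9)

    def test_matches_dense_least_squares_oracle(self, bandlimited):
        """Frequency-domain filter equals the explicit Tikhonov normal
        equations assembled from the spatial shear-difference operator."""
        n = 16
        dr = (0.5, 0.0)
        alpha = 3e-4
        A = np.zeros((n * n, n * n))
        for j in range(n * n):
            e = np.zeros(n * n)
            e[j] = 1.0
            A[:, j] = shear_difference(e.reshape(n, n), dr).ravel()
        g = bandlimited(n, 0.3, 1.0, seed=5)
        sol = np.linalg.solve(A.T @ A + alpha * np.eye(n * n), A.T @ g.ravel())
        sol = sol.reshape(n, n)
        sol -= sol.mean()
        ours = integrate_gradient(
            gradient_of(g, dr), ReconstructionConfig(alpha=alpha, pad_px=0)
        ).values
        assert np.max(np.abs(ours - sol)) / np.max(np.abs(sol)) < 1e-8

    def test_linearity(self, bandlimited):
        g1 = bandlimited(32, 0.2, 1.0, 1)
        g2 = bandlimited(32, 0.2, 1.0, 2)
        rc = ReconstructionConfig(pad_px=0)
        lhs = integrate_gradient(gradient_of(2.0 * g1 - 3.0 * g2), rc).values
        rhs = (
            2.0 * integrate_gradient(gradient_of(g1), rc).values
            - 3.0 * integrate_gradient(gradient_of(g2), rc).values
        )
        assert np.max(np.abs(lhs - rhs)) < 1e-10

    def test_gradient_consistency_in_passband(self, bandlimited):
        """Re-applying the shear-difference to the reconstruction returns
        the input gradient wherever the transfer function is strong.

        Per frequency the filter gives back |H|^2/(|H|^2 + alpha) of the
        input, i.e. a relative deficit alpha/(|H|^2 + alpha), so
        |H|^2 > 2000*alpha guarantees agreement below 1e-3.  An odd grid
        keeps every frequency paired with its distinct negation.
        """
        dr = (0.5, 0.0)
        n = 63
        g = bandlimited(n, 0.3, 1.0, 3)
        rc = ReconstructionConfig(pad_px=0)
        phi = integrate_gradient(gradient_of(g, dr), rc).values
        g_back = np.fft.fft2(shear_difference(phi, dr))
        g_in = np.fft.fft2(g)
        H2 = np.abs(gradient_transfer_function((n, n), dr)) ** 2
        strong = (H2 > 2000 * rc.alpha) & (np.abs(g_in) > 1e-9 * np.abs(g_in).max())
        rel = np.abs(g_back[strong] - g_in[strong]) / np.abs(g_in[strong])
        assert rel.max() < 1e-3

    def test_alpha_limit_monotone(self):
        n = 32
        dr = (0.5, 0.0)
        x = np.arange(n)
        phi = np.sin(2 * np.pi * 4 * x / n)[None, :] * np.ones((n, 1))
        grad = shear_difference(phi, dr)
        true_amp = np.max(np.abs(phi - phi.mean()))
        amps = []
        for alpha in (1e-1, 1e-2, 1e-3, 1e-4, 1e-6):
            out = integrate_gradient(
                gradient_of(grad, dr), ReconstructionConfig(alpha=alpha, pad_px=0)
            )
            amps.append(np.max(np.abs(out.values)))
        assert all(a < b for a, b in zip(amps, amps[1:]))
        assert amps[-1] == pytest.approx(true_amp, rel=1e-5)

    def test_alpha_zero_requires_explicit_flag(self):
        with pytest.raises(ValueError, match="unstable|unregularized"):
            ReconstructionConfig(alpha=0.0)
        rc = ReconstructionConfig(alpha=0.0, allow_unregularized=True, pad_px=0)
        out = integrate_gradient(gradient_of(np.zeros((8, 8))), rc)
        assert np.allclose(out.values, 0.0)


class TestNullAxisAnisotropy:
    def test_perpendicular_grating_vanishes(self, optical):
        """A grating with wavevector perpendicular to the shear is invisible;
        the same grating parallel to the shear is recovered."""
        n = 128
        u0 = 1 / 16
        x = np.arange(n)
        wave = 0.5 * np.sin(2 * np.pi * u0 * x)
        rc = ReconstructionConfig(pad_px=0)
        amps = {}
        for name, phi in (
            ("parallel", wave[None, :] * np.ones((n, 1))),
            ("perpendicular", wave[:, None] * np.ones((1, n))),
        ):
            pm = PhaseMap(phi, optical.pixel_pitch_um, optical.wavelength_um)
            raw = simulate_raw(pm, optical.shear_half_vector_px)
            _, phase = reconstruct_frame(raw, optical, rc)
            amps[name] = np.max(np.abs(phase.values))
        assert amps["perpendicular"] / amps["parallel"] < 1e-3
        assert amps["parallel"] > 0.4  # parallel grating is actually recovered


class TestReconstructFrame:
    def test_flat_phase_reconstructs_to_zero(self, optical):
        pm = PhaseMap(np.zeros((64, 64)), optical.pixel_pitch_um, optical.wavelength_um)
        raw = simulate_raw(pm, optical.shear_half_vector_px)
        _, phase = reconstruct_frame(raw, optical)
        assert np.max(np.abs(phase.values)) < 1e-6

    def test_matches_passband_projected_truth(self, optical, bandlimited_phase):
        """Noiseless pipeline output equals the ground truth seen through
        the Tikhonov pass-band filter |H|^2/(|H|^2+alpha).

        The residual is dominated by the cubic interpolation error of the
        demosaic stage, fourth-order in the field's bandwidth.
        """
        n = 128
        pm = bandlimited_phase(n=n, cutoff=0.02, amp=0.5, seed=2)
        rc = ReconstructionConfig(pad_px=0)
        raw = simulate_raw(pm, optical.shear_half_vector_px)
        _, phase = reconstruct_frame(raw, optical, rc)
        H = gradient_transfer_function((n, n), optical.shear_half_vector_px)
        filt = np.abs(H) ** 2 / (np.abs(H) ** 2 + rc.alpha)
        truth = np.fft.ifft2(np.fft.fft2(pm.values) * filt).real
        truth -= truth.mean()
        assert np.max(np.abs(phase.values - truth)) < 2e-3

    def test_exact_channels_match_passband_truth_tightly(self, optical, bandlimited_phase):
        # bypassing the demosaic stage, the pipeline is exact to round-off
        n = 128
        pm = bandlimited_phase(n=n, cutoff=0.04, amp=0.5, seed=6)
        dr = optical.shear_half_vector_px
        rc = ReconstructionConfig(pad_px=0)
        ch = polarization_intensities(shear_field(pm, np.ones((n, n)), dr))
        phase = integrate_gradient(phase_gradient(ch, dr), rc)
        H = gradient_transfer_function((n, n), dr)
        filt = np.abs(H) ** 2 / (np.abs(H) ** 2 + rc.alpha)
        truth = np.fft.ifft2(np.fft.fft2(pm.values) * filt).real
        truth -= truth.mean()
        assert np.max(np.abs(phase.values - truth)) < 1e-9


class TestReconstructSeries:
    def test_empty_sequence(self):
        assert reconstruct_series([]) == []

    def test_identical_frames_identical_outputs(self, optical, bandlimited_phase):
        pm = bandlimited_phase(n=32, seed=4)
        raw = simulate_raw(pm, optical.shear_half_vector_px)
        results = reconstruct_series([raw, raw, raw], optical)
        assert len(results) == 3
        g0, p0 = results[0]
        for g, p in results[1:]:
            assert np.array_equal(g.values, g0.values)
            assert np.array_equal(p.values, p0.values)

    def test_failing_frame_logged_and_skipped(self, optical, bandlimited_phase, caplog):
        from ssqpgm import RawMosaic

        good = simulate_raw(bandlimited_phase(n=32, seed=8), optical.shear_half_vector_px)
        bad = RawMosaic(np.ones((4, 4)))  # too small to demosaic
        with caplog.at_level(logging.ERROR):
            results = reconstruct_series([good, bad, good], optical)
        assert results[0] is not None and results[2] is not None
        assert results[1] is None
        assert "frame 1" in caplog.text
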