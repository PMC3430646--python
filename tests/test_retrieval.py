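"""Multi-distance phase retrieval: resampling, CTF inversion, CG refinement."""

import numpy as np
import pytest
from scipy import fft as sp_fft

from nanobone.optics import OpticsGeometry, propagate_field, simulate_scan
from nanobone.retrieval import (
    AlignedRadiographs,
    RetrievalConfig,
    _ProjectionProblem,
    ctf_factors,
    linear_ctf_retrieval,
    nonlinear_refine,
    resample_to_common_magnification,
)

from conftest import small_config, small_geometry
from nanobone.phantom import generate_phantom

GEOM = OpticsGeometry()  # four-distance beamline geometry
D_EQ = GEOM.equivalent_distances_mm
LAM = GEOM.wavelength_A


def _gaussian_phase(n, amplitude, width=16.0):
    yy, xx = np.mgrid[0:n, 0:n]
    return -amplitude * np.exp(
        -(((yy - n / 2) / width) ** 2 + ((xx - n / 2 + 4) / (0.7 * width)) ** 2)
    )


def _simulate_aligned(phi, amp, d_eq=D_EQ, pixel=60.0, noise=None, seed=0):
    n = phi.shape[0]
    K = len(d_eq)
    rng = np.random.default_rng(seed)
    data = np.empty((K, 1, n, n))
    for k, d in enumerate(d_eq):
        i = np.abs(propagate_field(amp * np.exp(1j * phi), d, LAM, pixel)) ** 2
        if noise:
            i = rng.poisson(i * noise) / noise
        data[k, 0] = i
    return AlignedRadiographs(
        intensities=data, angles=np.array([0.0]), pixel_nm=pixel,
        d_eq_mm=np.asarray(d_eq), wavelength_A=LAM,
    )


class TestResampling:
    def test_single_distance_identity(self):
        p = generate_phantom(small_config(), seed=3)
        geom = small_geometry(n_angles=2)
        single = OpticsGeometry(
            energy_keV=17.0, d1_mm=(32.6,), d_total_mm=525.0,
            detector_pixel_um=geom.detector_pixel_um, n_detector=48, n_angles=2,
        )
        stack = simulate_scan(p, single, seed=0)
        aligned = resample_to_common_magnification(stack)
        assert np.array_equal(aligned.intensities, stack.intensities)

    def test_constructed_rescaling_recovered(self):
        # image at a coarser pixel is an exact rescale of the fine image;
        # resampling must bring it back onto the fine grid
        n = 96
        yy, xx = np.mgrid[0:n, 0:n]
        fine = 1.0 + 0.1 * np.exp(-(((yy - 48) / 14.0) ** 2 + ((xx - 44) / 9.0) ** 2))
        ratio = 1.3
        from nanobone.optics import resample_image

        coarse = resample_image(fine, 60.0, 60.0 * ratio, n, cval=1.0,
                                anti_alias=False)
        stack_like = AlignedRadiographs(
            intensities=np.stack([fine, coarse])[:, None],
            angles=np.array([0.0]), pixel_nm=60.0,
            d_eq_mm=np.array([1.0, 1.0]), wavelength_A=LAM,
        )
        from nanobone.optics import RadiographStack

        stack = RadiographStack(
            intensities=np.stack([fine, coarse])[:, None],
            angles=np.array([0.0]),
            pixel_nm=np.array([60.0, 60.0 * ratio]),
            d_eq_mm=np.array([1.0, 1.0]),
            magnifications=np.array([2.0, 2.0 / ratio]),
            energy_keV=17.0,
        )
        aligned = resample_to_common_magnification(stack)
        inner = slice(8, n - 8)
        assert np.allclose(
            aligned.intensities[1, 0][inner, inner], fine[inner, inner], atol=2e-4
        )

    def test_empty_beam_mean_preserved(self):
        # flat-field normalization must survive resampling to within 0.1%
        from nanobone.phantom import BonePhantom

        shape = (32, 32, 32)
        empty = BonePhantom(
            density=np.zeros(shape), labels=np.zeros(shape, np.uint8),
            regions=np.zeros(shape, np.uint8), structures=[],
            voxel_size_nm=120.0, seed=None,
        )
        stack = simulate_scan(
            empty, small_geometry(n_detector=32, n_angles=1, photons=5e4),
            seed=4,
        )
        aligned = resample_to_common_magnification(stack)
        for k in range(stack.intensities.shape[0]):
            assert aligned.intensities[k, 0].mean() == pytest.approx(
                stack.intensities[k, 0].mean(), rel=1e-3
            )


class TestLinearCTF:
    def test_flat_radiographs_give_zero_phase(self):
        n = 64
        aligned = AlignedRadiographs(
            intensities=np.ones((4, 1, n, n)), angles=np.array([0.0]),
            pixel_nm=60.0, d_eq_mm=D_EQ, wavelength_A=LAM,
        )
        maps = linear_ctf_retrieval(aligned)
        assert np.allclose(maps.phase, 0.0)
        assert np.allclose(maps.amplitude, 1.0)

    def test_weak_pure_phase_recovery(self):
        n = 128
        phi = _gaussian_phase(n, 0.05)
        aligned = _simulate_aligned(phi, np.ones((n, n)))
        maps = linear_ctf_retrieval(aligned)
        est = maps.phase[0]
        assert np.corrcoef(est.ravel(), phi.ravel())[0, 1] > 0.99
        # relative L2 error away from the lowest-frequency band
        f = np.fft.fftfreq(n, d=60.0)
        f2 = f[:, None] ** 2 + f[None, :] ** 2
        keep = f2 > (0.05 * 0.5 / 60.0) ** 2
        err = sp_fft.fft2(est - phi)
        ref = sp_fft.fft2(phi)
        assert np.linalg.norm(err[keep]) / np.linalg.norm(ref[keep]) < 0.05

    def test_single_distance_equals_closed_form_filter(self):
        n, pixel = 64, 60.0
        rng = np.random.default_rng(2)
        intensity = 1.0 + 0.02 * rng.standard_normal((n, n))
        cfg = RetrievalConfig()
        aligned = AlignedRadiographs(
            intensities=intensity[None, None], angles=np.array([0.0]),
            pixel_nm=pixel, d_eq_mm=np.array([D_EQ[0]]), wavelength_A=LAM,
        )
        maps = linear_ctf_retrieval(aligned, cfg)
        a, reg = ctf_factors(n, pixel, LAM, np.array([D_EQ[0]]), cfg)
        expected = sp_fft.ifft2(
            a[0] * sp_fft.fft2(intensity - 1.0) / (a[0] ** 2 + reg)
        ).real
        assert np.allclose(maps.phase[0], expected, atol=1e-12)

    def test_retrieved_phase_is_nonpositive_for_matter(self):
        n = 128
        phi = _gaussian_phase(n, 0.4)
        aligned = _simulate_aligned(phi, np.exp(phi / 202.0))
        maps = linear_ctf_retrieval(aligned)
        assert maps.phase[0].min() < -0.2
        assert maps.phase[0].mean() < 0.0
        # small positive ringing from regularization is tolerated
        assert maps.amplitude.max() < 1.001


class TestNonlinearRefinement:
    def test_zero_iterations_returns_input(self):
        n = 64
        phi = _gaussian_phase(n, 0.3)
        aligned = _simulate_aligned(phi, np.ones((n, n)))
        lin = linear_ctf_retrieval(aligned)
        out = nonlinear_refine(lin, aligned, RetrievalConfig(iterations=0))
        assert np.array_equal(out.phase, lin.phase)
        assert out.provenance == "refined"

    def test_fixed_point_at_ground_truth(self):
        from nanobone.retrieval import PhaseMaps

        n = 64
        phi = _gaussian_phase(n, 0.8)
        amp = np.exp(phi / 202.0)
        aligned = _simulate_aligned(phi, amp)
        cfg = RetrievalConfig(iterations=5, amp_cutoff_frac=1.0,
                              phase_anchor_frac=0.0)
        start = PhaseMaps(phase=phi[None], amplitude=amp[None], pixel_nm=60.0,
                          provenance="linear")
        out = nonlinear_refine(start, aligned, cfg)
        assert out.misfit_history[0, 0] < 1e-4
        assert np.allclose(out.phase[0], phi, atol=1e-3)

    def test_strong_phase_object_improves(self):
        n = 128
        phi = _gaussian_phase(n, 1.5, width=8.0)
        aligned = _simulate_aligned(phi, np.exp(phi / 202.0))
        cfg = RetrievalConfig()
        lin = linear_ctf_retrieval(aligned, cfg)
        out = nonlinear_refine(lin, aligned, cfg)
        hist = out.misfit_history[0]
        assert hist[-1] < hist[0]
        err_lin = np.linalg.norm(lin.phase[0] - phi)
        err_ref = np.linalg.norm(out.phase[0] - phi)
        assert err_ref < err_lin

    def test_misfit_history_non_increasing(self):
        n = 64
        phi = _gaussian_phase(n, 0.7)
        aligned = _simulate_aligned(phi, np.exp(phi / 202.0), noise=1e4)
        lin = linear_ctf_retrieval(aligned)
        out = nonlinear_refine(lin, aligned, RetrievalConfig(iterations=6))
        assert np.all(np.diff(out.misfit_history[0]) <= 1e-9)

    def test_amplitude_spectrum_zero_above_cutoff(self):
        # decoupled-amplitude mode: the free amplitude is constrained to
        # contain no spatial frequencies above the configured cutoff
        n = 64
        phi = _gaussian_phase(n, 0.7)
        cfg = RetrievalConfig(iterations=3, amp_cutoff_frac=0.1,
                              amplitude_mode="free", phase_anchor_frac=0.12)
        aligned = _simulate_aligned(phi, np.exp(phi / 202.0))
        out = nonlinear_refine(linear_ctf_retrieval(aligned, cfg), aligned, cfg)
        spec = sp_fft.fft2(out.amplitude[0].astype(np.float64) - out.amplitude[0].mean())
        f = np.fft.fftfreq(n, d=60.0)
        f2 = f[:, None] ** 2 + f[None, :] ** 2
        beyond = f2 > (cfg.amp_cutoff_frac * 0.5 / 60.0) ** 2
        assert np.abs(spec[beyond]).max() < 1e-3 * np.abs(spec).max()

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        n = 32
        data = (1.0 + 0.05 * rng.standard_normal((3, n, n))).astype(np.float64)
        cfg = RetrievalConfig(phase_anchor_frac=0.0)
        prob = _ProjectionProblem(data, np.array([10.0, 20.0, 30.0]), LAM, 60.0, cfg)
        phi = 0.1 * rng.standard_normal((n, n))
        amp = prob.lowpass(1.0 + 0.05 * rng.standard_normal((n, n)))
        _, g_phi, g_amp = prob.misfit_grad(phi, amp)
        d_phi = rng.standard_normal((n, n))
        d_amp = prob.lowpass(rng.standard_normal((n, n)))
        eps = 1e-6
        fd = (
            prob.misfit(phi + eps * d_phi, amp + eps * d_amp)
            - prob.misfit(phi - eps * d_phi, amp - eps * d_amp)
        ) / (2 * eps)
        analytic = float(np.vdot(g_phi, d_phi).real + np.vdot(g_amp, d_amp).real)
        assert analytic == pytest.approx(fd, rel=1e-4)

    def test_linear_model_is_first_order_expansion_of_misfit_model(self):
        """The forward model inside the CG misfit and the linear CTF model
        agree to first order in the contrast (shared weak-object limit)."""
        n, pixel = 128, 60.0
        phi = _gaussian_phase(n, 0.02, width=10.0)
        amp = np.exp(phi / 202.0)
        cfg = RetrievalConfig()
        prob = _ProjectionProblem(
            np.ones((len(D_EQ), n, n)), D_EQ, LAM, pixel, cfg
        )
        fields = prob._fields(amp * np.exp(1j * phi))
        a, _ = ctf_factors(n, pixel, LAM, D_EQ, cfg)
        spec_phi = sp_fft.fft2(phi)
        for k, field in enumerate(fields):
            w = field[prob.sl] + 1.0
            model = sp_fft.fft2(np.abs(w) ** 2 - 1.0)
            linear = a[k] * spec_phi
            assert (
                np.linalg.norm(model - linear) / np.linalg.norm(linear) < 0.05
            )

    def test_noise_robustness_monotone(self):
        # the noise-induced part of the retrieval error (departure from the
        # noise-free retrieval of the same object) grows as photons drop
        n = 64
        phi = _gaussian_phase(n, 0.3)
        amp = np.exp(phi / 202.0)
        clean = linear_ctf_retrieval(_simulate_aligned(phi, amp)).phase[0]
        errors = []
        for photons in (1e6, 1e4, 1e2):
            aligned = _simulate_aligned(phi, amp, noise=photons, seed=42)
            maps = linear_ctf_retrieval(aligned)
            errors.append(np.linalg.norm(maps.phase[0] - clean))
        assert errors[0] < errors[1] < errors[2]
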