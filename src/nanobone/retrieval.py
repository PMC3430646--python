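"""Multi-distance phase retrieval.

Per projection angle, the K radiographs measured at different focus–sample
distances are (i) resampled to the unique magnification of the plane
closest to the focus, (ii) inverted with a weighted per-frequency linear
least squares based on the weak-contrast transfer functions, assuming the
phase and amplitude modulations are proportional through a fixed δ/β
ratio, and (iii) refined with a preconditioned non-linear
conjugate-gradient descent on the full Fresnel intensity misfit — either
with the δ/β coupling retained (default; exact for single-material
objects) or with a free amplitude constrained to contain no high spatial
frequencies.

Conventions: the exit phase is ≤ 0 for matter, the attenuation
B = −ln A = −φ/(δ/β), and for a weak object the intensity contrast at
distance D is  FT(I − 1) = (2 sin χ + (2/ratio) cos χ)·φ̃  with
χ = πλD|f|².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import fft as sp_fft

from .constants import ANGSTROM_NM, MM_NM
from .optics import RadiographStack, resample_image, safe_propagation_size

__all__ = [
    "RetrievalConfig",
    "AlignedRadiographs",
    "PhaseMaps",
    "resample_to_common_magnification",
    "ctf_factors",
    "linear_ctf_retrieval",
    "nonlinear_refine",
    "retrieve",
]


@dataclass
class RetrievalConfig:
    """Tunable parameters of both retrieval stages.

    ``reg_hf`` is the broadband Tikhonov floor of the CTF normal-equation
    denominator; it blends down to ``reg_lf`` inside a Gaussian
    low-frequency band of width ``lf_sigma_frac``×Nyquist.  The
    low-frequency floor must stay well below the squared absorption
    coefficient (2/ratio)² ≈ 1e-4 or the absorption-borne smooth-bulk
    information is suppressed.  ``prior_mode`` selects whether the δ/β
    coupling of amplitude to phase is used at all frequencies ("all") or
    only inside the low-frequency band ("low").

    Refinement: ``amplitude_mode="coupled"`` (default) keeps the δ/β
    proportionality through the non-linear stage — exact for a
    single-material object, and it removes the near rank-deficiency of
    jointly estimating phase and a free amplitude from four *similar*
    equivalent distances.  ``amplitude_mode="free"`` releases the
    amplitude as an independent low-passed variable (spectrum identically
    zero above ``amp_cutoff_frac``×Nyquist); in that mode the phase
    spectrum below ``phase_anchor_frac``×Nyquist stays at the linear,
    absorption-complemented estimate (the free-amplitude misfit cannot
    determine it).  ``preconditioned`` divides the CG gradient by the CTF
    normal operator ``2Σa² + precond_floor``, without which the smooth
    components converge orders of magnitude more slowly than the rest.
    """

    delta_beta_ratio: float = 202.0
    reg_hf: float = 1e-3
    reg_lf: float = 1e-5
    lf_sigma_frac: float = 0.05
    prior_mode: str = "all"
    iterations: int = 10
    amplitude_mode: str = "coupled"
    amp_cutoff_frac: float = 0.1
    phase_anchor_frac: float = 0.12  # used by the "free" amplitude mode
    preconditioned: bool = True
    precond_floor: float = 0.1
    armijo_c1: float = 1e-4
    backtrack_factor: float = 0.5
    max_backtracks: int = 20
    cg_restart: int = 0  # 0: restart only on a non-descent direction
    initial_step: float = 1.0

    def __post_init__(self) -> None:
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if not (0.0 < self.amp_cutoff_frac <= 1.0):
            raise ValueError("amplitude cutoff must lie in (0, 1]")
        if self.prior_mode not in ("all", "low"):
            raise ValueError("prior_mode must be 'all' or 'low'")
        if self.amplitude_mode not in ("coupled", "free"):
            raise ValueError("amplitude_mode must be 'coupled' or 'free'")


@dataclass
class AlignedRadiographs:
    """Radiographs of all distances resampled onto the common grid.

    ``native_pixel_nm`` keeps each distance's object-plane pixel before
    resampling: a resampled image carries no information above its native
    Nyquist, and both retrieval stages restrict that distance's
    contribution to the band it actually measured.
    """

    intensities: np.ndarray  # [K, n_angles, n, n]
    angles: np.ndarray
    pixel_nm: float
    d_eq_mm: np.ndarray
    wavelength_A: float
    native_pixel_nm: np.ndarray | None = None


from functools import lru_cache

from scipy import ndimage as _ndimage


@lru_cache(maxsize=32)
def _measured_transfer(n: int, ratio_key: int) -> np.ndarray:
    """Measured frequency response of the detector resampling chain.

    A distance recorded at a coarser object-plane pixel passes through
    anti-aliased cubic downsampling to the detector pitch and cubic
    upsampling back onto the common grid.  Its net response is estimated
    on white-noise probes pushed through exactly that chain at the actual
    grid sizes (fixed seed; cross-/auto-spectrum ratio averaged over
    probes, lightly smoothed, zeroed beyond the native Nyquist).
    """
    ratio = ratio_key / 1e6
    rng = np.random.default_rng(20240917)
    n_can = int(np.ceil(n * ratio)) + 4
    n_can += n_can % 2
    o = (n_can - n) // 2
    cross = np.zeros((n, n))
    auto = np.zeros((n, n))
    # Hann window against crop leakage when estimating the spectra
    w1 = np.hanning(n)
    window = w1[:, None] * w1[None, :]
    for _ in range(32):
        canvas = rng.standard_normal((n_can, n_can))
        det = resample_image(canvas, 1.0, ratio, n, cval=0.0, order=3,
                             anti_alias=True)
        back = resample_image(det, ratio, 1.0, n, cval=0.0, order=3,
                              anti_alias=False)
        probe = canvas[o : o + n, o : o + n]
        spec_in = sp_fft.fft2(probe * window)
        spec_out = sp_fft.fft2(back * window)
        cross += (spec_out * np.conj(spec_in)).real
        auto += np.abs(spec_in) ** 2
    response = np.clip(cross / auto, 0.0, 1.05)
    response = np.fft.ifftshift(
        _ndimage.gaussian_filter(np.fft.fftshift(response), 2.0, mode="nearest")
    )
    f = np.abs(np.fft.fftfreq(n))  # cycles per fine pixel
    beyond = (f[:, None] > 0.5 / ratio) | (f[None, :] > 0.5 / ratio)
    response[beyond] = 0.0
    return response


def _data_transfer(n: int, pixel_nm: float, native_pixel_nm: float) -> np.ndarray | None:
    """Detector transfer of a distance recorded at a coarser pixel.

    Returns the measured net frequency response on the common grid (see
    :func:`_measured_transfer`), or None for the native-resolution
    distance.
    """
    ratio = native_pixel_nm / pixel_nm
    if ratio <= 1 + 1e-9:
        return None
    return _measured_transfer(n, int(round(ratio * 1e6)))


@dataclass
class PhaseMaps:
    """Retrieved per-angle phase (and optionally amplitude) maps."""

    phase: np.ndarray  # [n_angles, n, n]
    amplitude: np.ndarray | None
    pixel_nm: float
    provenance: str  # "linear" | "refined"
    misfit_history: np.ndarray | None = None  # [n_angles, iterations + 1]

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("phase", data=self.phase, compression="gzip")
            if self.amplitude is not None:
                f.create_dataset("amplitude", data=self.amplitude,
                                 compression="gzip")
            if self.misfit_history is not None:
                f.create_dataset("misfit_history", data=self.misfit_history)
            f.attrs["pixel_nm"] = self.pixel_nm
            f.attrs["provenance"] = self.provenance

    @classmethod
    def from_hdf5(cls, path) -> "PhaseMaps":
        with h5py.File(path, "r") as f:
            return cls(
                phase=f["phase"][...],
                amplitude=f["amplitude"][...] if "amplitude" in f else None,
                pixel_nm=float(f.attrs["pixel_nm"]),
                provenance=str(f.attrs["provenance"]),
                misfit_history=(
                    f["misfit_history"][...] if "misfit_history" in f else None
                ),
            )


def resample_to_common_magnification(stack: RadiographStack) -> AlignedRadiographs:
    """Resample all distances to the closest-plane (smallest) pixel.

    Separable cubic interpolation on centered grids; the geometry provides
    the exact magnification ratios, no registration is attempted.  Regions
    beyond a coarser image's field of view take the empty-beam value 1.
    """
    pixels = np.asarray(stack.pixel_nm, dtype=float)
    common = float(pixels.min())
    K, n_angles, ny, nx = stack.intensities.shape
    if ny != nx:
        raise ValueError("radiographs must be square")
    out = np.empty_like(stack.intensities)
    for k in range(K):
        if abs(pixels[k] - common) < 1e-9:
            out[k] = stack.intensities[k]
            continue
        for i in range(n_angles):
            out[k, i] = resample_image(
                stack.intensities[k, i].astype(np.float64),
                in_pixel_nm=pixels[k],
                out_pixel_nm=common,
                n_out=ny,
                cval=1.0,
                order=3,
                anti_alias=False,
            )
    return AlignedRadiographs(
        intensities=out,
        angles=stack.angles,
        pixel_nm=common,
        d_eq_mm=np.asarray(stack.d_eq_mm, dtype=float),
        wavelength_A=stack.wavelength_A,
        native_pixel_nm=pixels.copy(),
    )


def _freq_sq(n: int, pixel_nm: float) -> np.ndarray:
    f = np.fft.fftfreq(n, d=pixel_nm)
    return f[:, None] ** 2 + f[None, :] ** 2


def ctf_factors(
    n: int,
    pixel_nm: float,
    lambda_A: float,
    d_eq_mm: np.ndarray,
    cfg: RetrievalConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-distance linear coefficients a_k(f) of the weak-contrast model
    and the regularization field reg(f)."""
    lam_nm = lambda_A * ANGSTROM_NM
    f2 = _freq_sq(n, pixel_nm)
    f_nyq = 0.5 / pixel_nm
    lf_weight = np.exp(-f2 / (2.0 * (cfg.lf_sigma_frac * f_nyq) ** 2))
    a = np.empty((len(d_eq_mm), n, n))
    for k, d in enumerate(d_eq_mm):
        chi = np.pi * lam_nm * (d * MM_NM) * f2
        cos_weight = 1.0 if cfg.prior_mode == "all" else lf_weight
        a[k] = 2.0 * np.sin(chi) + (2.0 / cfg.delta_beta_ratio) * np.cos(chi) * cos_weight
    # blend between the low-frequency floor and the broadband floor: at
    # low f the prior-coupled absorption term is of order (2/ratio)², so
    # the floor there must stay well below it or the smooth bulk is lost
    reg = cfg.reg_hf * (1.0 - lf_weight) + cfg.reg_lf * lf_weight
    return a, reg


def linear_ctf_retrieval(
    aligned: AlignedRadiographs, cfg: RetrievalConfig | None = None
) -> PhaseMaps:
    """First phase estimate: per-frequency weighted linear least squares
    over the K distances, with the amplitude coupled through the δ/β prior.

    φ̃ = Σ_k a_k·FT(I_k − 1) / (Σ_k a_k² + reg); the amplitude estimate is
    exp(φ/ratio) (≤ 1, since φ ≤ 0 for matter).
    """
    cfg = cfg or RetrievalConfig()
    K, n_angles, n, _ = aligned.intensities.shape
    a, reg = ctf_factors(n, aligned.pixel_nm, aligned.wavelength_A,
                         aligned.d_eq_mm, cfg)
    if aligned.native_pixel_nm is not None:
        for k in range(K):
            mask = _data_transfer(n, aligned.pixel_nm, aligned.native_pixel_nm[k])
            if mask is not None:
                a[k] *= mask
    denom = (a**2).sum(axis=0) + reg
    if np.any(denom <= 0):
        raise ValueError(
            "CTF normal equations singular: all transfer factors vanish and "
            "no regularization is configured"
        )
    phase = np.empty((n_angles, n, n), dtype=np.float64)
    for i in range(n_angles):
        num = np.zeros((n, n), dtype=np.complex128)
        for k in range(K):
            num += a[k] * sp_fft.fft2(
                aligned.intensities[k, i].astype(np.float64) - 1.0
            )
        phase[i] = sp_fft.ifft2(num / denom).real
    amplitude = np.exp(phase / cfg.delta_beta_ratio)
    return PhaseMaps(
        phase=phase,
        amplitude=amplitude,
        pixel_nm=aligned.pixel_nm,
        provenance="linear",
    )


# ---------------------------------------------------------------------------
# non-linear conjugate-gradient refinement
# ---------------------------------------------------------------------------

class _ProjectionProblem:
    """Fresnel intensity misfit for one projection and its exact gradient.

    The complex field ψ = A·e^{iφ} lives on the n² data grid; propagation
    embeds ψ − 1 in a vacuum canvas large enough for alias-free transfer
    functions (an affine operator whose linear part has the crop as exact
    adjoint).  The amplitude is parameterized through a sharp Fourier
    low-pass, so its spectrum is identically zero above the cutoff.
    """

    def __init__(self, data, d_eq_mm, lambda_A, pixel_nm, cfg: RetrievalConfig,
                 native_pixel_nm=None):
        self.data = data  # [K, n, n]
        self.cfg = cfg
        self.n = data.shape[-1]
        self.band_masks = [
            _data_transfer(self.n, pixel_nm, p) for p in native_pixel_nm
        ] if native_pixel_nm is not None else [None] * len(d_eq_mm)
        self.ctype = np.complex64 if data.dtype == np.float32 else np.complex128
        n_prop = self.n
        for d in d_eq_mm:
            n_prop = max(n_prop, safe_propagation_size(self.n, d, lambda_A, pixel_nm))
        self.n_prop = n_prop
        lam_nm = lambda_A * ANGSTROM_NM
        f = np.fft.fftfreq(n_prop, d=pixel_nm)
        f2 = f[:, None] ** 2 + f[None, :] ** 2
        self.kernels = np.stack([
            np.exp(-1j * np.pi * lam_nm * (d * MM_NM) * f2).astype(self.ctype)
            for d in d_eq_mm
        ])
        self.kernels_conj = np.conj(self.kernels)
        i0 = (n_prop - self.n) // 2
        self.sl = (slice(i0, i0 + self.n), slice(i0, i0 + self.n))
        fn = np.fft.fftfreq(self.n, d=pixel_nm)
        fn2 = fn[:, None] ** 2 + fn[None, :] ** 2
        cutoff = cfg.amp_cutoff_frac * 0.5 / pixel_nm
        self.lp_mask = fn2 <= cutoff**2
        anchor = cfg.phase_anchor_frac * 0.5 / pixel_nm
        self.hp_mask = (
            fn2 > anchor**2
            if cfg.amplitude_mode == "free" and cfg.phase_anchor_frac > 0
            else None
        )
        # CTF normal-operator preconditioner: the misfit curvature w.r.t.
        # the phase is ≈ 2·Σ_k a_k(f)² — five orders of magnitude between
        # low and mid frequencies — so plain CG stalls on the smooth
        # components; dividing the gradient by it equilibrates convergence
        a_lin = np.empty((len(d_eq_mm), self.n, self.n))
        for k, d in enumerate(d_eq_mm):
            chi_n = np.pi * lam_nm * (d * MM_NM) * fn2
            a_lin[k] = (
                2.0 * np.sin(chi_n)
                + (2.0 / cfg.delta_beta_ratio) * np.cos(chi_n)
            )
            if self.band_masks[k] is not None:
                a_lin[k] *= self.band_masks[k]
        self.precond = 1.0 / (2.0 * (a_lin**2).sum(axis=0) + cfg.precond_floor)
        c_lin = np.empty_like(a_lin)
        for k, d in enumerate(d_eq_mm):
            chi_n = np.pi * lam_nm * (d * MM_NM) * fn2
            c_lin[k] = 2.0 * np.cos(chi_n)
            if self.band_masks[k] is not None:
                c_lin[k] *= self.band_masks[k]
        self.precond_amp = 1.0 / (2.0 * (c_lin**2).sum(axis=0) + cfg.precond_floor)
        self.set_data(data)

    def set_data(self, data) -> None:
        """Swap in another projection's radiographs (same geometry)."""
        self.data = data
        # measured data restricted to each distance's sampled band (the
        # content above the native Nyquist is interpolation junk)
        self.data_band = np.empty_like(data)
        for k, mask in enumerate(self.band_masks):
            if mask is None:
                self.data_band[k] = data[k]
            else:
                self.data_band[k] = sp_fft.ifft2(
                    sp_fft.fft2(data[k].astype(np.float64)) * (mask > 0)
                ).real.astype(data.dtype)

    def precondition(self, g: np.ndarray, which: str = "phase") -> np.ndarray:
        p = self.precond if which == "phase" else self.precond_amp
        return sp_fft.ifft2(sp_fft.fft2(g) * p).real.astype(g.dtype)

    def lowpass(self, x: np.ndarray) -> np.ndarray:
        return sp_fft.ifft2(sp_fft.fft2(x) * self.lp_mask).real.astype(x.dtype)

    def highpass(self, x: np.ndarray) -> np.ndarray:
        """Project onto the refinable phase band (identity if unanchored)."""
        if self.hp_mask is None:
            return x
        return sp_fft.ifft2(sp_fft.fft2(x) * self.hp_mask).real.astype(x.dtype)

    def _fields(self, psi):
        canvas = np.zeros((self.n_prop, self.n_prop), dtype=self.ctype)
        canvas[self.sl] = psi - 1.0
        spec = sp_fft.fft2(canvas)
        return sp_fft.ifft2(spec[None] * self.kernels, axes=(-2, -1))

    def _residual(self, w, k):
        """Residual of one distance in its measured band.

        The model intensity is passed through the distance's detector
        transfer before comparison with the (band-restricted) data; the
        transfer is a symmetric real multiplier, so misfit and gradient
        stay an exact pair.
        """
        model = w.real**2 + w.imag**2
        mask = self.band_masks[k]
        if mask is not None:
            model = sp_fft.ifft2(sp_fft.fft2(model) * mask).real.astype(model.dtype)
        return model - self.data_band[k]

    def _backfilter(self, r, k):
        mask = self.band_masks[k]
        if mask is None:
            return r
        return sp_fft.ifft2(sp_fft.fft2(r) * mask).real.astype(r.dtype)

    def _psi(self, phi, amp):
        if amp is None:  # amplitude slaved to the phase via the δ/β ratio
            return np.exp(phi / self.cfg.delta_beta_ratio) * np.exp(1j * phi)
        return amp * np.exp(1j * phi)

    def misfit(self, phi, amp):
        psi = self._psi(phi, amp)
        fields = self._fields(psi)
        # cache for a following gradient call at the same point (the
        # accepted line-search trial is always the last one evaluated)
        self._cached = (psi, fields)
        total = 0.0
        for k in range(len(self.data)):
            r = self._residual(fields[k][self.sl] + 1.0, k)
            total += float(np.sum(r.astype(np.float64) ** 2))
        return total

    def misfit_grad(self, phi, amp, reuse_cached: bool = False):
        if reuse_cached and getattr(self, "_cached", None) is not None:
            psi, fields = self._cached
        else:
            psi = self._psi(phi, amp)
            fields = self._fields(psi)
        total = 0.0
        K = len(self.data)
        wk = np.zeros((K, self.n_prop, self.n_prop), dtype=self.ctype)
        for k in range(K):
            w = fields[k][self.sl] + 1.0
            r = self._residual(w, k)
            total += float(np.sum(r.astype(np.float64) ** 2))
            wk[k][self.sl] = self._backfilter(2.0 * r, k) * w
        spec_acc = (sp_fft.fft2(wk, axes=(-2, -1)) * self.kernels_conj).sum(axis=0)
        G = sp_fft.ifft2(spec_acc)[self.sl]
        gpsi = np.conj(G) * psi
        if amp is None:
            # d psi/d phi = psi·(i + 1/ratio) for the coupled amplitude
            grad_phi = self.highpass(
                -2.0 * gpsi.imag
                + (2.0 / self.cfg.delta_beta_ratio) * gpsi.real
            )
            return total, grad_phi.astype(self.data.dtype), None
        grad_phi = self.highpass(-2.0 * gpsi.imag)
        grad_amp = self.lowpass(2.0 * (np.conj(G) * np.exp(1j * phi)).real)
        return total, grad_phi.astype(self.data.dtype), grad_amp.astype(self.data.dtype)


def _dot(a, b):
    return float(np.vdot(a, b).real) if a is not None else 0.0


def _axpy(x, alpha, d):
    return None if x is None else x + alpha * d


def _refine_projection(phi0, amp0, problem: _ProjectionProblem, cfg: RetrievalConfig):
    """Polak–Ribière CG with Armijo backtracking on one projection.

    ``amp0`` is None in coupled-amplitude mode (single unknown φ).
    """
    phi = phi0.copy()
    amp = None if amp0 is None else problem.lowpass(amp0)

    def precond(g_phi, g_amp):
        if not cfg.preconditioned:
            return g_phi, g_amp
        z_phi = problem.precondition(g_phi, "phase")
        z_amp = None if g_amp is None else problem.lowpass(
            problem.precondition(g_amp, "amplitude")
        )
        return z_phi, z_amp

    J, g_phi, g_amp = problem.misfit_grad(phi, amp)
    z_phi, z_amp = precond(g_phi, g_amp)
    history = [J]
    d_phi = -z_phi
    d_amp = None if z_amp is None else -z_amp
    step = cfg.initial_step

    def try_step(alpha, d_phi, d_amp, slope):
        J_try = problem.misfit(phi + alpha * d_phi, _axpy(amp, alpha, d_amp))
        return J_try, J_try <= J + cfg.armijo_c1 * alpha * slope

    for it in range(cfg.iterations):
        slope = _dot(g_phi, d_phi) + _dot(g_amp, d_amp)
        if slope >= 0:  # non-descent direction: restart
            d_phi = -z_phi
            d_amp = None if z_amp is None else -z_amp
            slope = _dot(g_phi, d_phi) + _dot(g_amp, d_amp)
        def line_search(d_phi, d_amp, slope):
            # Armijo backtracking with quadratic interpolation of the
            # 1D misfit; far fewer rejected trials than plain halving
            alpha = step
            for _ in range(cfg.max_backtracks):
                J_try, ok = try_step(alpha, d_phi, d_amp, slope)
                if ok:
                    return alpha, True
                denom = J_try - J - slope * alpha
                if denom > 0:
                    alpha_q = -0.5 * slope * alpha**2 / denom
                    alpha = min(max(alpha_q, 0.1 * alpha),
                                cfg.backtrack_factor * alpha)
                else:
                    alpha *= cfg.backtrack_factor
            return alpha, False

        alpha, accepted = line_search(d_phi, d_amp, slope)
        if not accepted:
            # preconditioned steepest-descent fallback, fresh line search
            warnings.warn("line search failed; falling back to steepest descent",
                          stacklevel=2)
            d_phi = -z_phi
            d_amp = None if z_amp is None else -z_amp
            slope = _dot(g_phi, d_phi) + _dot(g_amp, d_amp)
            alpha, accepted = line_search(d_phi, d_amp, slope)
        if not accepted:
            history.append(J)  # stalled; keep the iterate
            continue
        phi = phi + alpha * d_phi
        amp = _axpy(amp, alpha, d_amp)
        step = alpha * 1.3  # mild growth: most steps accept the first trial
        # the accepted trial was the last misfit evaluation: reuse its fields
        J_new, g_phi_new, g_amp_new = problem.misfit_grad(
            phi, amp, reuse_cached=True
        )
        z_phi_new, z_amp_new = precond(g_phi_new, g_amp_new)
        zg_old = _dot(z_phi, g_phi) + _dot(z_amp, g_amp)
        beta = (
            (
                _dot(z_phi_new, g_phi_new - g_phi)
                + _dot(z_amp_new, None if g_amp is None else g_amp_new - g_amp)
            )
            / zg_old
            if zg_old > 0
            else 0.0
        )
        beta = max(beta, 0.0)
        if cfg.cg_restart > 0 and (it + 1) % cfg.cg_restart == 0:
            beta = 0.0
        d_phi = -z_phi_new + beta * d_phi
        d_amp = None if z_amp_new is None else -z_amp_new + beta * d_amp
        g_phi, g_amp = g_phi_new, g_amp_new
        z_phi, z_amp = z_phi_new, z_amp_new
        J = J_new
        history.append(J)
    return phi, amp, np.asarray(history)


def nonlinear_refine(
    phase0: PhaseMaps,
    aligned: AlignedRadiographs,
    cfg: RetrievalConfig | None = None,
) -> PhaseMaps:
    """Refine linear phase maps on the full non-linear Fresnel model.

    Runs exactly ``cfg.iterations`` outer CG iterations per projection; the
    recorded misfit history is non-increasing over accepted steps, and the
    amplitude spectrum is identically zero above the configured cutoff.
    ``iterations = 0`` returns the input maps unchanged.
    """
    cfg = cfg or RetrievalConfig()
    K, n_angles, n, _ = aligned.intensities.shape
    if cfg.iterations == 0:
        return PhaseMaps(
            phase=phase0.phase.copy(),
            amplitude=None if phase0.amplitude is None else phase0.amplitude.copy(),
            pixel_nm=phase0.pixel_nm,
            provenance="refined",
            misfit_history=None,
        )
    dtype = aligned.intensities.dtype
    phase = np.empty_like(phase0.phase, dtype=dtype)
    amplitude = np.empty_like(phase, dtype=dtype)
    histories = np.empty((n_angles, cfg.iterations + 1))
    problem = _ProjectionProblem(
        aligned.intensities[:, 0].astype(dtype),
        aligned.d_eq_mm,
        aligned.wavelength_A,
        aligned.pixel_nm,
        cfg,
        native_pixel_nm=aligned.native_pixel_nm,
    )
    for i in range(n_angles):
        if i > 0:
            problem.set_data(aligned.intensities[:, i].astype(dtype))
        if cfg.amplitude_mode == "coupled":
            amp0 = None
        elif phase0.amplitude is not None:
            amp0 = phase0.amplitude[i].astype(dtype)
        else:
            amp0 = np.exp(phase0.phase[i] / cfg.delta_beta_ratio).astype(dtype)
        phi, amp, hist = _refine_projection(
            phase0.phase[i].astype(dtype), amp0, problem, cfg
        )
        phase[i] = phi
        amplitude[i] = np.exp(phi / cfg.delta_beta_ratio) if amp is None else amp
        histories[i] = hist
    return PhaseMaps(
        phase=phase,
        amplitude=amplitude,
        pixel_nm=phase0.pixel_nm,
        provenance="refined",
        misfit_history=histories,
    )


def retrieve(
    stack: RadiographStack, cfg: RetrievalConfig | None = None
) -> PhaseMaps:
    """Full retrieval chain: resample → linear CTF inversion → CG refine."""
    cfg = cfg or RetrievalConfig()
    aligned = resample_to_common_magnification(stack)
    linear = linear_ctf_retrieval(aligned, cfg)
    return nonlinear_refine(linear, aligned, cfg)
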