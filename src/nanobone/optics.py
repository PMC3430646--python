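"""Cone-beam geometry algebra and Fresnel wave-optics forward model.

The divergent (cone) beam produced by a nano-focus is treated through the
standard equivalence with a parallel beam: a radiograph recorded at
focus–sample distance ``D1`` with the detector at ``D1 + D2`` equals, up to
the geometric magnification ``M = (D1 + D2)/D1``, a plane-wave image of the
object sampled at the object-plane pixel ``detector_pixel / M`` and
propagated over the equivalent distance ``D_eq = D1·D2/(D1 + D2)``.  The
forward model therefore projects the phantom with parallel rays, forms the
exit wave from the complex refractive index ``n = 1 − δ + iβ``, and
propagates it with the Fresnel transfer function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import fft as sp_fft
from scipy import ndimage

from .constants import (
    ANGSTROM_NM,
    HC_KEV_ANGSTROM,
    MM_NM,
    delta_density_coefficient,
)

__all__ = [
    "wavelength_from_energy",
    "magnification",
    "equivalent_distance",
    "field_of_view_um",
    "MaterialModel",
    "delta_beta_from_density",
    "OpticsGeometry",
    "ExitWave",
    "RadiographStack",
    "project_exit_wave",
    "propagate_field",
    "fresnel_propagate",
    "simulate_scan",
]


def wavelength_from_energy(energy_keV: float) -> float:
    """X-ray wavelength in Å from the photon energy in keV (hc/E)."""
    if energy_keV <= 0:
        raise ValueError(f"energy must be positive, got {energy_keV}")
    return HC_KEV_ANGSTROM / energy_keV


def magnification(d1_mm: float, d_total_mm: float) -> float:
    """Geometric magnification (D1 + D2)/D1 of the projection setup."""
    if d1_mm <= 0:
        raise ValueError(f"focus-sample distance must be positive, got {d1_mm}")
    if d1_mm > d_total_mm:
        raise ValueError("focus-sample distance exceeds focus-detector distance")
    return d_total_mm / d1_mm


def equivalent_distance(d1_mm: float, d2_mm: float) -> float:
    """Plane-wave propagation distance equivalent to the divergent geometry.

    D_eq = D1·D2/(D1 + D2); symmetric in its arguments and zero when the
    detector sits in the contact plane (D2 = 0).
    """
    if d1_mm < 0 or d2_mm < 0:
        raise ValueError("distances must be non-negative")
    if d1_mm == 0 and d2_mm == 0:
        raise ValueError("at least one distance must be positive")
    return d1_mm * d2_mm / (d1_mm + d2_mm)


def field_of_view_um(n_pixels: int, pixel_nm: float) -> float:
    """Lateral field of view in µm of ``n_pixels`` at ``pixel_nm`` sampling."""
    return n_pixels * pixel_nm * 1e-3


@dataclass(frozen=True)
class MaterialModel:
    """Optical constants of a (light-element) material at one wavelength.

    delta = C·rho·λ² with C derived from the electron-density relation
    (r_c = 2.8 fm, Z/A = 1/2, dispersion correction neglected), and
    beta = delta / (delta/beta ratio).  beta relates to the linear
    attenuation coefficient through mu = 4π·beta/λ.
    """

    rho_g_cm3: float
    lambda_A: float
    delta_beta_ratio: float
    delta: float
    beta: float
    coefficient: float

    @property
    def mu_per_nm(self) -> float:
        return 4.0 * np.pi * self.beta / (self.lambda_A * ANGSTROM_NM)


def delta_beta_from_density(
    rho_g_cm3: float,
    lambda_A: float,
    delta_beta_ratio: float,
    coefficient: float | None = None,
) -> MaterialModel:
    """Optical constants from mass density, wavelength and the δ/β ratio."""
    if lambda_A <= 0:
        raise ValueError("wavelength must be positive")
    if rho_g_cm3 < 0:
        raise ValueError("density must be non-negative")
    if delta_beta_ratio <= 0:
        raise ValueError("delta/beta ratio must be positive")
    C = delta_density_coefficient() if coefficient is None else coefficient
    delta = C * rho_g_cm3 * lambda_A**2
    return MaterialModel(
        rho_g_cm3=rho_g_cm3,
        lambda_A=lambda_A,
        delta_beta_ratio=delta_beta_ratio,
        delta=delta,
        beta=delta / delta_beta_ratio,
        coefficient=C,
    )


@dataclass(frozen=True)
class OpticsGeometry:
    """Magnified projection geometry and acquisition settings.

    The default values are those of a KB-mirror nano-imaging station:
    17 keV, four focus–sample distances between 32.6 and 47.6 mm with the
    detector fixed 525 mm from the focus, and a detector of 1500 px at an
    effective pixel of ~1 µm, giving a ~60 nm pixel in the plane closest to
    the focus.
    """

    energy_keV: float = 17.0
    d1_mm: tuple[float, ...] = (32.6, 33.6, 37.6, 47.6)
    d_total_mm: float = 525.0
    detector_pixel_um: float = 1.0
    n_detector: int = 1500
    n_angles: int = 2999
    photons: float | None = None  # photons/pixel; None = noiseless

    def __post_init__(self) -> None:
        d1 = np.asarray(self.d1_mm, dtype=float)
        if d1.ndim != 1 or d1.size == 0:
            raise ValueError("d1_mm must be a non-empty sequence")
        if np.any(d1 <= 0) or np.any(d1 >= self.d_total_mm):
            raise ValueError("require 0 < D1[k] < D1+D2 for all distances")
        if np.any(np.diff(d1) <= 0):
            raise ValueError("focus-sample distances must be strictly increasing")
        if self.energy_keV <= 0:
            raise ValueError("energy must be positive")
        if self.n_angles < 1 or self.n_detector < 2:
            raise ValueError("need at least one angle and two detector pixels")

    @property
    def n_distances(self) -> int:
        return len(self.d1_mm)

    @property
    def wavelength_A(self) -> float:
        return wavelength_from_energy(self.energy_keV)

    @property
    def d2_mm(self) -> np.ndarray:
        return self.d_total_mm - np.asarray(self.d1_mm, dtype=float)

    @property
    def magnifications(self) -> np.ndarray:
        return np.array(
            [magnification(d1, self.d_total_mm) for d1 in self.d1_mm]
        )

    @property
    def equivalent_distances_mm(self) -> np.ndarray:
        return np.array(
            [equivalent_distance(d1, d2) for d1, d2 in zip(self.d1_mm, self.d2_mm)]
        )

    @property
    def object_pixel_nm(self) -> np.ndarray:
        """Object-plane pixel size per distance (detector pixel / M)."""
        return self.detector_pixel_um * 1e3 / self.magnifications

    @property
    def common_pixel_nm(self) -> float:
        """Pixel of the plane closest to the focus (largest magnification)."""
        return float(self.object_pixel_nm.min())

    @property
    def field_of_view_um(self) -> float:
        return field_of_view_um(self.n_detector, self.common_pixel_nm)

    @property
    def angles(self) -> np.ndarray:
        """Projection angles over one complete turn, radians."""
        return np.linspace(0.0, 2.0 * np.pi, self.n_angles, endpoint=False)

    def with_common_pixel(self, pixel_nm: float) -> "OpticsGeometry":
        """Same beamline geometry with the detector pixel chosen so that the
        closest-plane (common) pixel equals ``pixel_nm``."""
        m_max = float(self.magnifications.max())
        return OpticsGeometry(
            energy_keV=self.energy_keV,
            d1_mm=self.d1_mm,
            d_total_mm=self.d_total_mm,
            detector_pixel_um=pixel_nm * m_max * 1e-3,
            n_detector=self.n_detector,
            n_angles=self.n_angles,
            photons=self.photons,
        )


@dataclass
class ExitWave:
    """Amplitude/phase modulation of the wave leaving the object.

    With the projection convention of a thin object,
    ``phase = −(2π/λ)·∫δ dl ≤ 0`` and ``amplitude = exp(−(2π/λ)·∫β dl)``
    lies in (0, 1] for attenuating matter.
    """

    amplitude: np.ndarray
    phase: np.ndarray
    pixel_nm: float

    @property
    def psi(self) -> np.ndarray:
        return self.amplitude * np.exp(1j * self.phase)


@dataclass
class RadiographStack:
    """Flat-normalized intensities for every distance and projection angle.

    ``intensities[k, i]`` is the radiograph at distance index ``k`` and angle
    ``angles[i]``, sampled at the object-plane pixel ``pixel_nm[k]`` on a
    common ``n_detector²`` grid.
    """

    intensities: np.ndarray  # [K, n_angles, ny, nx]
    angles: np.ndarray  # radians
    pixel_nm: np.ndarray  # per-distance object-plane pixel
    d_eq_mm: np.ndarray
    magnifications: np.ndarray
    energy_keV: float
    photons: float | None = None
    seed: int | None = None

    @property
    def wavelength_A(self) -> float:
        return wavelength_from_energy(self.energy_keV)

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("intensity", data=self.intensities, compression="gzip")
            f.create_dataset("angles", data=self.angles)
            f.create_dataset("pixel_nm", data=self.pixel_nm)
            f.create_dataset("D_eq_mm", data=self.d_eq_mm)
            f.create_dataset("magnification", data=self.magnifications)
            f.attrs["energy_keV"] = self.energy_keV
            if self.photons is not None:
                f.attrs["photons"] = self.photons
            if self.seed is not None:
                f.attrs["seed"] = self.seed

    @classmethod
    def from_hdf5(cls, path) -> "RadiographStack":
        with h5py.File(path, "r") as f:
            return cls(
                intensities=f["intensity"][...],
                angles=f["angles"][...],
                pixel_nm=f["pixel_nm"][...],
                d_eq_mm=f["D_eq_mm"][...],
                magnifications=f["magnification"][...],
                energy_keV=float(f.attrs["energy_keV"]),
                photons=float(f.attrs["photons"]) if "photons" in f.attrs else None,
                seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
            )


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def _rotated_projection(volume: np.ndarray, theta: float) -> np.ndarray:
    """Parallel projection of ``volume[z, y, x]`` along y after rotating the
    (y, x) plane so the detector coordinate is t = x·cosθ + y·sinθ.

    Returns an array [z, t] in units of (volume value)·(voxel count); the
    caller multiplies by the voxel size to obtain a line integral.
    """
    if abs(theta) < 1e-12:
        return volume.sum(axis=1)
    c, s = np.cos(theta), np.sin(theta)
    # output coords (z, y', x'=t) -> input (z, y = x' s + y' c, x = x' c - y' s)
    matrix = np.array([[1.0, 0.0, 0.0], [0.0, c, s], [0.0, -s, c]])
    center = (np.asarray(volume.shape) - 1) / 2.0
    offset = center - matrix @ center
    rotated = ndimage.affine_transform(
        volume, matrix, offset=offset, order=1, mode="constant", cval=0.0
    )
    return rotated.sum(axis=1)


def project_exit_wave(
    phantom,
    theta: float,
    lambda_A: float,
    delta_beta_ratio: float,
    delta_coefficient: float | None = None,
) -> ExitWave:
    """Exit wave of a phantom at projection angle ``theta`` (parallel rays).

    ``phantom`` provides ``density`` (g/cm³, axes [z, y, x] with the
    rotation axis along z) and ``voxel_size_nm``.  The phase is the negative
    line integral of δ scaled by 2π/λ; the amplitude decays with the line
    integral of β = δ/ratio.
    """
    C = delta_density_coefficient() if delta_coefficient is None else delta_coefficient
    lam_nm = lambda_A * ANGSTROM_NM
    areal_rho = _rotated_projection(
        np.ascontiguousarray(phantom.density, dtype=np.float64), theta
    ) * phantom.voxel_size_nm  # g/cm³ · nm
    delta_line_nm = C * lambda_A**2 * areal_rho
    phase = -2.0 * np.pi * delta_line_nm / lam_nm
    b_line = 2.0 * np.pi * (delta_line_nm / delta_beta_ratio) / lam_nm
    amplitude = np.exp(-b_line)
    return ExitWave(amplitude=amplitude, phase=phase, pixel_nm=phantom.voxel_size_nm)


# ---------------------------------------------------------------------------
# Fresnel propagation
# ---------------------------------------------------------------------------

def _fresnel_kernel(
    shape: tuple[int, int], d_mm: float, lambda_A: float, pixel_nm: float,
    dtype=np.complex128,
) -> np.ndarray:
    """Fresnel transfer function exp(−iπλD|f|²) on the DFT frequency grid."""
    lam_nm = lambda_A * ANGSTROM_NM
    d_nm = d_mm * MM_NM
    fy = np.fft.fftfreq(shape[0], d=pixel_nm)
    fx = np.fft.fftfreq(shape[1], d=pixel_nm)
    chi = np.pi * lam_nm * d_nm * (fy[:, None] ** 2 + fx[None, :] ** 2)
    return np.exp(-1j * chi).astype(dtype)


def safe_propagation_size(n: int, d_mm: float, lambda_A: float, pixel_nm: float) -> int:
    """Smallest FFT-friendly grid that samples the Fresnel kernel without
    aliasing (N ≥ λD/p²) and leaves room for the first Fresnel fringes."""
    lam_nm = lambda_A * ANGSTROM_NM
    d_nm = abs(d_mm) * MM_NM
    n_alias = int(np.ceil(lam_nm * d_nm / pixel_nm**2))
    n_fringe = n + 2 * int(np.ceil(np.sqrt(lam_nm * d_nm) / pixel_nm))
    need = max(n, n_alias, n_fringe)
    # power-of-two-rich sizes transform measurably faster than the
    # nearest 5-smooth length at these problem sizes
    return ((need + 63) // 64) * 64


def propagate_field(
    psi: np.ndarray,
    d_mm: float,
    lambda_A: float,
    pixel_nm: float,
    pad: str | None = "vacuum",
) -> np.ndarray:
    """Free-space Fresnel propagation of a complex field by ``d_mm``.

    ``pad='vacuum'`` embeds ``psi − 1`` in a zero (vacuum) canvas large
    enough to avoid transfer-function aliasing and fringe wrap-around, then
    crops back — appropriate for compactly supported objects.  ``pad=None``
    propagates periodically on the native grid (exact adjoint pair with its
    conjugate kernel) and warns if the kernel is undersampled.
    """
    psi = np.asarray(psi)
    if d_mm == 0:
        return psi.copy()
    ctype = np.complex64 if psi.dtype in (np.complex64, np.float32) else np.complex128
    ny, nx = psi.shape
    if pad == "vacuum":
        n_prop = max(
            safe_propagation_size(ny, d_mm, lambda_A, pixel_nm),
            safe_propagation_size(nx, d_mm, lambda_A, pixel_nm),
        )
        canvas = np.zeros((n_prop, n_prop), dtype=ctype)
        y0, x0 = (n_prop - ny) // 2, (n_prop - nx) // 2
        canvas[y0 : y0 + ny, x0 : x0 + nx] = psi - 1.0
        kernel = _fresnel_kernel((n_prop, n_prop), d_mm, lambda_A, pixel_nm, ctype)
        out = sp_fft.ifft2(sp_fft.fft2(canvas) * kernel) + 1.0
        return np.ascontiguousarray(out[y0 : y0 + ny, x0 : x0 + nx])
    if pad is not None:
        raise ValueError(f"unknown pad mode {pad!r}")
    lam_nm = lambda_A * ANGSTROM_NM
    n_req = lam_nm * abs(d_mm) * MM_NM / pixel_nm**2
    if min(ny, nx) < n_req:
        warnings.warn(
            "Fresnel kernel undersampled: grid %d < lambda*D/pixel^2 = %.0f"
            % (min(ny, nx), n_req),
            stacklevel=2,
        )
    kernel = _fresnel_kernel((ny, nx), d_mm, lambda_A, pixel_nm, ctype)
    return sp_fft.ifft2(sp_fft.fft2(psi.astype(ctype)) * kernel)


def fresnel_propagate(
    wave: ExitWave,
    d_mm: float,
    lambda_A: float,
    pad: str | None = "vacuum",
) -> np.ndarray:
    """Intensity |propagated field|² of an exit wave at distance ``d_mm``."""
    if d_mm == 0:
        return wave.amplitude**2
    out = propagate_field(wave.psi, d_mm, lambda_A, wave.pixel_nm, pad=pad)
    return np.abs(out) ** 2


# ---------------------------------------------------------------------------
# resampling between object planes
# ---------------------------------------------------------------------------

def resample_image(
    image: np.ndarray,
    in_pixel_nm: float,
    out_pixel_nm: float,
    n_out: int,
    cval: float,
    order: int = 3,
    anti_alias: bool = True,
) -> np.ndarray:
    """Sample ``image`` (pitch ``in_pixel_nm``) onto a centered ``n_out²``
    grid of pitch ``out_pixel_nm``; regions outside the input are ``cval``."""
    ratio = out_pixel_nm / in_pixel_nm
    src = image
    if anti_alias and ratio > 1.0:
        sigma = np.sqrt(ratio**2 - 1.0) / 2.0
        src = ndimage.gaussian_filter(image, sigma, mode="nearest")
    c_in = (np.asarray(image.shape) - 1) / 2.0
    c_out = (n_out - 1) / 2.0
    idx = (np.arange(n_out) - c_out) * ratio
    yy = idx[:, None] + c_in[0]
    xx = idx[None, :] + c_in[1]
    coords = np.broadcast_arrays(yy, xx)
    return ndimage.map_coordinates(
        src, np.stack(coords), order=order, mode="constant", cval=cval
    )


# ---------------------------------------------------------------------------
# scan simulation
# ---------------------------------------------------------------------------

def simulate_scan(
    phantom,
    geometry: OpticsGeometry,
    seed: int | None = None,
    delta_beta_ratio: float = 202.0,
    n_detector: int | None = None,
    dtype=np.float32,
) -> RadiographStack:
    """Simulate the multi-distance tomographic scan of a phantom.

    For every projection angle the phantom is projected once and the exit
    wave is Fresnel-propagated on the fine phantom grid over each
    distance's equivalent propagation distance; the detector then samples
    the propagated intensity at that plane's object-plane pixel
    (anti-aliased resampling emulating pixel integration) and records
    Poisson noise at ``geometry.photons`` counts/pixel (noiseless if
    ``photons`` is None).  Identical seeds give identical stacks.
    """
    n_det = geometry.n_detector if n_detector is None else n_detector
    angles = geometry.angles
    pixels = geometry.object_pixel_nm
    d_eq = geometry.equivalent_distances_mm
    lam = geometry.wavelength_A
    K = geometry.n_distances
    rng = np.random.default_rng(seed)
    ctype = np.complex64 if dtype == np.float32 else np.complex128
    out = np.empty((K, len(angles), n_det, n_det), dtype=dtype)
    voxel_nm = phantom.voxel_size_nm
    # the detector field of view (largest at the most distant plane) can
    # exceed the phantom grid; embed the exit wave in vacuum up front so
    # diffraction fringes spreading beyond the object are recorded rather
    # than truncated
    n_obj = phantom.density.shape[-1]
    n_fine = max(n_obj, int(np.ceil(n_det * pixels.max() / voxel_nm)))
    n_fine += n_fine % 2
    o = (n_fine - n_obj) // 2
    # Fresnel kernels are shared across angles; precompute once
    n_prop = max(
        safe_propagation_size(n_fine, d, lam, voxel_nm) for d in d_eq
    )
    kernels = [
        _fresnel_kernel((n_prop, n_prop), d, lam, voxel_nm, ctype) for d in d_eq
    ]
    op = (n_prop - n_fine) // 2
    canvas = np.zeros((n_prop, n_prop), dtype=ctype)
    for i, theta in enumerate(angles):
        wave = project_exit_wave(phantom, theta, lam, delta_beta_ratio)
        psi = wave.psi.astype(ctype)
        canvas[op + o : op + o + n_obj, op + o : op + o + n_obj] = psi - 1.0
        spec = sp_fft.fft2(canvas)
        for k in range(K):
            field = sp_fft.ifft2(spec * kernels[k])
            fine = np.abs(
                field[op : op + n_fine, op : op + n_fine] + 1.0
            ) ** 2
            intensity = resample_image(
                fine.astype(np.float64), voxel_nm, pixels[k], n_det, cval=1.0
            )
            if geometry.photons is not None:
                intensity = (
                    rng.poisson(np.clip(intensity, 0.0, None) * geometry.photons)
                    / geometry.photons
                )
            out[k, i] = intensity
    return RadiographStack(
        intensities=out,
        angles=angles,
        pixel_nm=pixels,
        d_eq_mm=d_eq,
        magnifications=geometry.magnifications,
        energy_keV=geometry.energy_keV,
        photons=geometry.photons,
        seed=seed,
    )
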