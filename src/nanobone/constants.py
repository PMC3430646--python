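"""Physical constants and unit conventions.

Units used throughout the package:

* distances along the beamline: mm
* X-ray wavelength: Å (1 Å = 0.1 nm)
* pixel / voxel sizes: nm
* mass density: g/cm³

All unit conversions live here so that every module agrees on them.
"""

from __future__ import annotations

import numpy as np

#: hc in keV·Å, so that lambda[Å] = HC_KEV_ANGSTROM / E[keV].
HC_KEV_ANGSTROM = 12.398

#: Classical electron radius in fm.
CLASSICAL_ELECTRON_RADIUS_FM = 2.8

#: Avogadro's number, 1/mol.
AVOGADRO = 6.02214076e23

#: Ratio of atomic number to atomic mass for light biological elements.
Z_OVER_A_LIGHT_ELEMENTS = 0.5

ANGSTROM_CM = 1e-8
ANGSTROM_NM = 0.1
FM_CM = 1e-13
MM_NM = 1e6


def delta_density_coefficient(
    r_c_fm: float = CLASSICAL_ELECTRON_RADIUS_FM,
    z_over_a: float = Z_OVER_A_LIGHT_ELEMENTS,
) -> float:
    """Coefficient C such that delta = C * rho[g/cm³] * lambda[Å]².

    Follows from delta = r_c λ² n_e / (2π) with the electron density of a
    material made of light elements, n_e = rho * N_A * (Z/A) per cm³.
    With r_c = 2.8 fm and Z/A = 1/2 this evaluates to ≈ 1.34e-6.
    """
    r_c_cm = r_c_fm * FM_CM
    return r_c_cm * ANGSTROM_CM**2 * AVOGADRO * z_over_a / (2.0 * np.pi)


def delta_from_composition(
    lambda_A: float,
    volume_cm3: float,
    atoms: list[tuple[float, float]],
) -> float:
    """Refractive index decrement from an explicit atomic inventory.

    ``atoms`` lists ``(Z_j + f'_j, count)`` pairs for the representative
    volume ``volume_cm3``; the dispersion correction f' may be folded into
    the first entry (it is negligible far from absorption edges).  This is
    the brute-force electron-density summation used as an oracle for
    :func:`delta_density_coefficient`.
    """
    n_electrons = float(sum(z * n for z, n in atoms))
    lam_cm = lambda_A * ANGSTROM_CM
    r_c_cm = CLASSICAL_ELECTRON_RADIUS_FM * FM_CM
    return r_c_cm * lam_cm**2 * n_electrons / (2.0 * np.pi * volume_cm3)
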