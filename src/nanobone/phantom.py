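"""Synthetic cortical-bone phantoms with full ground truth.

A phantom is a voxelized mass-density volume of a cylindrical specimen of
cortical bone containing three tissue compartments — osteonal tissue and
interstitial tissue separated by a thin, denser cement-line band — carved by
a lacuno-canalicular pore network.  Lacunae are flattened lenticular drops
(tapered ellipsoids), canaliculi are thin constant-radius tubes that radiate
from the lacunae, branch up to three generations deep, and never cross the
cement line.  Every structure is stored with its analytic parameters and
analytic volume so that downstream recovery can be tested against exact
ground truth.

Axes are ``[z, y, x]`` with the tomographic rotation axis along z; voxels
are isotropic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .reports import MorphometryReport

__all__ = [
    "LABELS",
    "PhantomConfig",
    "StructureRecord",
    "BonePhantom",
    "lenticular_volume_um3",
    "generate_phantom",
    "phantom_ground_truth_report",
    "write_phantom",
    "read_phantom",
]

#: Label coding shared across the package.
LABELS = {"pore": 0, "osteonal": 1, "interstitial": 2, "cement_line": 3}
COMPARTMENT_NAMES = {1: "osteonal", 2: "interstitial", 3: "cement_line"}


@dataclass
class PhantomConfig:
    """Geometry and statistics of a synthetic specimen.

    Defaults describe the scaled test specimen: a 128³ grid at 60 nm voxels
    (7.68 µm field of view) holding a bone cylinder split by a planar
    cement-line band, with lacunae scaled down so they fit the grid.
    Compartment mean densities default to the measured tissue values
    (osteonal 1.818, interstitial 1.845, cement line 1.909 g/cm³) and the
    per-voxel density fluctuation to the measured spreads.
    """

    shape: tuple[int, int, int] = (128, 128, 128)
    voxel_size_nm: float = 60.0
    specimen_radius_um: float | None = 3.2  # None: bone fills the grid
    # vacuum caps above/below the specimen: the phantom is compactly
    # supported in every direction, so the wave model's vacuum embedding
    # and the reconstruction see no out-of-field structure
    z_margin_um: float = 0.6
    # tissue densities, g/cm³
    density_osteonal: float = 1.818
    density_interstitial: float = 1.845
    density_cement: float = 1.909
    sd_osteonal: float = 0.089
    sd_interstitial: float = 0.090
    sd_cement: float = 0.097
    # lamellar modulation (sinusoid along x), optional
    lamellar_amplitude: float = 0.0
    lamellar_period_um: float = 2.5
    # cement-line band: plane x = offset, given thickness
    cement_offset_um: float = 0.0
    cement_thickness_um: float = 0.9
    # lacunae (volumes scaled to the test grid; the measured osteonal /
    # interstitial size ordering is preserved)
    n_lacunae_osteonal: int = 2
    n_lacunae_interstitial: int = 1
    lacuna_volume_osteonal_um3: float = 1.8
    lacuna_volume_interstitial_um3: float = 2.2
    lacuna_aspect: tuple[float, float, float] = (2.0, 1.4, 1.0)  # a:b:c
    lacuna_taper: float = 0.3
    # canaliculi; densities chosen to land near the observed canalicular to
    # lacunar volume ratios (~50% osteonal, a few % interstitial)
    canaliculi_per_lacuna: int = 6
    interstitial_canaliculi_per_lacuna: int = 2
    canaliculus_radius_um: tuple[float, float] = (0.12, 0.2)
    canaliculus_step_um: float = 0.25
    canaliculus_max_length_um: float = 1.2
    branching_probability: float = 0.25  # per step, at most one event per walk
    max_branch_depth: int = 3
    connect_osteonal_lacunae: bool = True
    max_placement_retries: int = 500

    def __post_init__(self) -> None:
        if self.voxel_size_nm <= 0:
            raise ValueError("voxel size must be positive")
        if not (0.0 <= self.lacuna_taper < 1.0):
            raise ValueError("lacuna taper must lie in [0, 1)")
        r_min, r_max = self.canaliculus_radius_um
        if not (0.1 <= r_min <= r_max <= 0.45):
            raise ValueError(
                "canalicular radii must lie in [0.1, 0.45] µm "
                "(diameters 0.2–0.9 µm)"
            )


@dataclass
class StructureRecord:
    """Analytic description of one pore structure.

    Lacunae store center (µm, relative to the grid center), semi-axes,
    taper and yaw; canaliculi store their centerline polyline, radius,
    parent lacuna and branch depth.  ``true_volume_um3`` is the analytic
    volume; ``voxel_count`` the voxels the structure newly carved.
    """

    kind: str  # "lacuna" | "canaliculus"
    compartment: str
    true_volume_um3: float
    voxel_count: int = 0
    center_um: tuple[float, float, float] | None = None  # (z, y, x)
    semi_axes_um: tuple[float, float, float] | None = None  # (a, b, c)
    taper: float | None = None
    yaw_rad: float | None = None
    polyline_um: list | None = None
    radius_um: float | None = None
    parent_lacuna: int | None = None
    branch_depth: int | None = None


@dataclass
class BonePhantom:
    """Ground-truth density volume, labels and structure records.

    ``labels`` uses :data:`LABELS` (0 = pore/background); ``regions`` keeps
    the tissue compartment each voxel geometrically belongs to even where a
    pore was carved (0 outside the specimen), which is the reference for
    per-compartment morphometry.
    """

    density: np.ndarray  # g/cm³, [z, y, x]
    labels: np.ndarray  # uint8
    regions: np.ndarray  # uint8
    structures: list[StructureRecord]
    voxel_size_nm: float
    seed: int | None
    lacuna_mask: np.ndarray | None = None
    canaliculus_mask: np.ndarray | None = None
    config: PhantomConfig | None = None

    @property
    def voxel_volume_um3(self) -> float:
        return (self.voxel_size_nm * 1e-3) ** 3

    @property
    def pore_mask(self) -> np.ndarray:
        """Carved lacuno-canalicular pores (excludes exterior background)."""
        return (self.labels == LABELS["pore"]) & (self.regions > 0)


def lenticular_volume_um3(a: float, b: float, c: float, taper: float) -> float:
    """Analytic volume of the tapered-ellipsoid ("lenticular drop") lacuna.

    The cross-section at normalized height u = z/c ∈ [−1, 1] is an ellipse
    with semi-axes a·s(u)·√(1−u²), b·s(u)·√(1−u²), s(u) = 1 − taper·(1+u)/2,
    so V = πabc·∫(1−u²)s(u)² du = πabc·(4/3·(1−τ) + 2τ²/5).
    """
    t = taper
    return np.pi * a * b * c * (4.0 / 3.0 * (1.0 - t) + 0.4 * t**2)


def _voxel_axes_um(shape, voxel_um):
    """Voxel-center coordinates (µm) per axis, origin at the grid center."""
    return [
        (np.arange(n) - (n - 1) / 2.0) * voxel_um for n in shape
    ]


class _Carver:
    """Accumulates pore masks while tracking which voxels are newly carved."""

    def __init__(self, phantom_shape, voxel_um):
        self.shape = phantom_shape
        self.voxel_um = voxel_um
        self.lacunae = np.zeros(phantom_shape, dtype=bool)
        self.canaliculi = np.zeros(phantom_shape, dtype=bool)
        self.z, self.y, self.x = _voxel_axes_um(phantom_shape, voxel_um)

    def _bbox(self, lo_um, hi_um):
        idx = []
        for ax, (lo, hi) in zip((self.z, self.y, self.x), zip(lo_um, hi_um)):
            i0 = int(np.searchsorted(ax, lo))
            i1 = int(np.searchsorted(ax, hi, side="right"))
            idx.append((max(i0 - 1, 0), min(i1 + 1, len(ax))))
        return idx

    def carve_lacuna(self, center, axes_um, taper, yaw):
        cz, cy, cx = center
        a, b, c = axes_um
        ext = max(a, b)
        (z0, z1), (y0, y1), (x0, x1) = self._bbox(
            (cz - c, cy - ext, cx - ext), (cz + c, cy + ext, cx + ext)
        )
        dz = (self.z[z0:z1] - cz)[:, None, None]
        dy = (self.y[y0:y1] - cy)[None, :, None]
        dx = (self.x[x0:x1] - cx)[None, None, :]
        cs, sn = np.cos(yaw), np.sin(yaw)
        xr = cs * dx + sn * dy
        yr = -sn * dx + cs * dy
        u = dz / c
        s = 1.0 - taper * (1.0 + u) / 2.0
        rhs = (1.0 - u**2) * s**2
        inside = (np.abs(u) <= 1.0) & ((xr / a) ** 2 + (yr / b) ** 2 <= rhs)
        region = self.lacunae[z0:z1, y0:y1, x0:x1]
        n_new = int(np.count_nonzero(inside & ~region))
        region |= inside
        return n_new

    def carve_tube(self, polyline, radius_um):
        n_new = 0
        for p0, p1 in zip(polyline[:-1], polyline[1:]):
            p0 = np.asarray(p0, dtype=float)
            p1 = np.asarray(p1, dtype=float)
            lo = np.minimum(p0, p1) - radius_um
            hi = np.maximum(p0, p1) + radius_um
            (z0, z1), (y0, y1), (x0, x1) = self._bbox(lo, hi)
            if z0 >= z1 or y0 >= y1 or x0 >= x1:
                continue
            pz = self.z[z0:z1][:, None, None]
            py = self.y[y0:y1][None, :, None]
            px = self.x[x0:x1][None, None, :]
            d = p1 - p0
            L2 = float(d @ d)
            if L2 == 0:
                t = np.zeros((z1 - z0, y1 - y0, x1 - x0))
            else:
                t = ((pz - p0[0]) * d[0] + (py - p0[1]) * d[1] + (px - p0[2]) * d[2]) / L2
                t = np.clip(t, 0.0, 1.0)
            qz = p0[0] + t * d[0]
            qy = p0[1] + t * d[1]
            qx = p0[2] + t * d[2]
            dist2 = (pz - qz) ** 2 + (py - qy) ** 2 + (px - qx) ** 2
            inside = dist2 <= radius_um**2
            region = self.canaliculi[z0:z1, y0:y1, x0:x1]
            n_new += int(np.count_nonzero(inside & ~region & ~self.lacunae[z0:z1, y0:y1, x0:x1]))
            region |= inside
        return n_new


def lacuna_semi_axes_for_volume(volume_um3: float, aspect, taper: float):
    """Semi-axes (a, b, c) of a lenticular lacuna with the given analytic
    volume and aspect ratio."""
    unit = lenticular_volume_um3(*aspect, taper)
    scale = (volume_um3 / unit) ** (1.0 / 3.0)
    return tuple(scale * np.asarray(aspect, dtype=float))


_lacuna_semi_axes = lacuna_semi_axes_for_volume


def voxelize_lacuna(
    semi_axes_um,
    taper: float,
    voxel_size_nm: float,
    margin_vox: int = 4,
    yaw: float = 0.0,
):
    """Voxelize one lenticular lacuna on a minimal grid.

    Returns ``(mask, true_volume_um3)`` where the mask is the analytic
    inside-test at voxel centers and the volume is the closed form of
    :func:`lenticular_volume_um3`.
    """
    a, b, c = semi_axes_um
    v_um = voxel_size_nm * 1e-3
    ext = max(a, b)
    shape = tuple(
        2 * (int(np.ceil(h / v_um)) + margin_vox) for h in (c, ext, ext)
    )
    carver = _Carver(shape, v_um)
    carver.carve_lacuna((0.0, 0.0, 0.0), (a, b, c), taper, yaw)
    return carver.lacunae, lenticular_volume_um3(a, b, c, taper)


def _tube_volume(polyline, radius_um):
    pts = np.asarray(polyline, dtype=float)
    length = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    return np.pi * radius_um**2 * length + (4.0 / 3.0) * np.pi * radius_um**3


def generate_phantom(config: PhantomConfig, seed: int | None = 0) -> BonePhantom:
    """Generate a three-compartment bone phantom with an LCN pore network.

    Deterministic for a given (config, seed).  Raises ``ValueError`` when a
    requested lacuna cannot fit its compartment ("grid too small") and
    ``RuntimeError`` when non-overlapping placement repeatedly fails.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = config.shape
    v_um = config.voxel_size_nm * 1e-3
    zc, yc, xc = _voxel_axes_um(config.shape, v_um)

    # --- compartment geometry --------------------------------------------
    yy = yc[:, None]
    xx = xc[None, :]
    if config.specimen_radius_um is None:
        inside2d = np.ones((ny, nx), dtype=bool)
        r_spec = 0.5 * min(ny, nx) * v_um
    else:
        r_spec = config.specimen_radius_um
        inside2d = yy**2 + xx**2 <= r_spec**2
    half_t = config.cement_thickness_um / 2.0
    x0 = config.cement_offset_um
    regions2d = np.zeros((ny, nx), dtype=np.uint8)
    xgrid = np.broadcast_to(xx, (ny, nx))
    regions2d[inside2d] = np.where(
        np.abs(xgrid - x0) <= half_t,
        LABELS["cement_line"],
        np.where(xgrid < x0, LABELS["osteonal"], LABELS["interstitial"]),
    )[inside2d]
    regions = np.broadcast_to(regions2d, config.shape).copy()
    z_half = (nz - 1) / 2.0 * v_um
    z_bone = z_half - config.z_margin_um
    if z_bone <= 0:
        raise ValueError("z margin leaves no specimen")
    regions[np.abs(np.asarray(zc)) > z_bone, :, :] = 0

    # --- tissue density ----------------------------------------------------
    density = np.zeros(config.shape, dtype=np.float64)
    means = {
        LABELS["osteonal"]: config.density_osteonal,
        LABELS["interstitial"]: config.density_interstitial,
        LABELS["cement_line"]: config.density_cement,
    }
    sds = {
        LABELS["osteonal"]: config.sd_osteonal,
        LABELS["interstitial"]: config.sd_interstitial,
        LABELS["cement_line"]: config.sd_cement,
    }
    noise = rng.standard_normal(config.shape)
    for lab, mean in means.items():
        m = regions == lab
        density[m] = mean + sds[lab] * noise[m]
    if config.lamellar_amplitude > 0:
        modulation = config.lamellar_amplitude * np.sin(
            2.0 * np.pi * xc / config.lamellar_period_um
        )
        density += np.where(regions > 0, modulation[None, None, :], 0.0)
    np.clip(density, 0.0, None, out=density)

    # --- lacuna placement --------------------------------------------------
    carver = _Carver(config.shape, v_um)
    structures: list[StructureRecord] = []
    margin = 2 * v_um
    z_half = z_bone  # structures stay inside the capped specimen

    def _place(compartment, n_lac, volume):
        axes = _lacuna_semi_axes(volume, config.lacuna_aspect, config.lacuna_taper)
        a, b, c = axes
        ext = max(a, b)
        if compartment == LABELS["osteonal"]:
            x_lo, x_hi = -r_spec + ext, x0 - half_t - ext
        else:
            x_lo, x_hi = x0 + half_t + ext, r_spec - ext
        if x_hi <= x_lo or c + margin > z_half or 2 * ext + margin > 2 * r_spec:
            raise ValueError(
                f"grid too small: a {volume:.3g} µm³ lacuna (semi-axes "
                f"{a:.2f}/{b:.2f}/{c:.2f} µm) does not fit the "
                f"{COMPARTMENT_NAMES[compartment]} compartment"
            )
        placed = []
        for _ in range(n_lac):
            for attempt in range(config.max_placement_retries):
                cx_ = rng.uniform(x_lo, x_hi)
                cy_ = rng.uniform(-r_spec + ext, r_spec - ext)
                cz_ = rng.uniform(-z_half + c + margin, z_half - c - margin)
                if cx_**2 + cy_**2 > (r_spec - ext) ** 2:
                    continue
                ok = all(
                    np.linalg.norm(np.array([cz_, cy_, cx_]) - np.array(p.center_um))
                    > ext + max(p.semi_axes_um[:2]) + 2 * margin
                    for p in structures
                    if p.kind == "lacuna"
                )
                if ok:
                    break
            else:
                raise RuntimeError(
                    "could not place non-overlapping lacunae after "
                    f"{config.max_placement_retries} retries"
                )
            yaw = rng.uniform(0.0, 2.0 * np.pi)
            n_vox = carver.carve_lacuna((cz_, cy_, cx_), axes, config.lacuna_taper, yaw)
            rec = StructureRecord(
                kind="lacuna",
                compartment=COMPARTMENT_NAMES[compartment],
                true_volume_um3=lenticular_volume_um3(*axes, config.lacuna_taper),
                voxel_count=n_vox,
                center_um=(cz_, cy_, cx_),
                semi_axes_um=axes,
                taper=config.lacuna_taper,
                yaw_rad=yaw,
            )
            structures.append(rec)
            placed.append(rec)
        return placed

    osteonal = (
        _place(LABELS["osteonal"], config.n_lacunae_osteonal,
               config.lacuna_volume_osteonal_um3)
        if config.n_lacunae_osteonal
        else []
    )
    interstitial = (
        _place(LABELS["interstitial"], config.n_lacunae_interstitial,
               config.lacuna_volume_interstitial_um3)
        if config.n_lacunae_interstitial
        else []
    )

    # --- canaliculi --------------------------------------------------------
    def _blocked(p, compartment):
        """Walk stops at the cement line and at the specimen boundary."""
        z_, y_, x_ = p
        if abs(z_) > z_half - margin or y_**2 + x_**2 > (r_spec - margin) ** 2:
            return True
        if compartment == LABELS["osteonal"] and x_ > x0 - half_t:
            return True
        if compartment == LABELS["interstitial"] and x_ < x0 + half_t:
            return True
        return False

    def _walk(start, direction, compartment, depth, parent, radius, budget):
        pts = [np.asarray(start, dtype=float)]
        d = np.asarray(direction, dtype=float)
        d /= np.linalg.norm(d)
        length = 0.0
        branches = []
        branched = False
        while length < budget:
            step = config.canaliculus_step_um
            nxt = pts[-1] + d * step
            if _blocked(nxt, compartment):
                break
            pts.append(nxt)
            length += step
            if (
                not branched
                and depth < config.max_branch_depth
                and len(pts) > 2
                and rng.uniform() < config.branching_probability
            ):
                branched = True
                n_children = int(rng.integers(2, 4))  # branch into two or three
                for _ in range(n_children - 1):
                    branches.append((nxt.copy(), _perturb(d, 1.0), depth + 1))
            d = _perturb(d, 0.45)
        if len(pts) < 2:
            return
        poly = [tuple(p) for p in pts]
        n_vox = carver.carve_tube(pts, radius)
        structures.append(
            StructureRecord(
                kind="canaliculus",
                compartment=COMPARTMENT_NAMES[compartment],
                true_volume_um3=_tube_volume(pts, radius),
                voxel_count=n_vox,
                polyline_um=poly,
                radius_um=radius,
                parent_lacuna=parent,
                branch_depth=depth,
            )
        )
        for start_b, dir_b, depth_b in branches:
            _walk(start_b, dir_b, compartment, depth_b, parent, radius,
                  budget * 0.6)

    def _perturb(d, kappa):
        nd = d + kappa * rng.standard_normal(3)
        return nd / np.linalg.norm(nd)

    def _surface_point(rec, direction):
        a, b, c = rec.semi_axes_um
        d = np.asarray(direction, dtype=float)
        d /= np.linalg.norm(d)
        scale = 1.0 / np.sqrt((d[0] / c) ** 2 + (d[1] / b) ** 2 + (d[2] / a) ** 2)
        return np.asarray(rec.center_um) + 0.9 * scale * d

    for comp, lacs, n_can in (
        (LABELS["osteonal"], osteonal, config.canaliculi_per_lacuna),
        (LABELS["interstitial"], interstitial,
         config.interstitial_canaliculi_per_lacuna),
    ):
        for i, rec in enumerate(lacs):
            parent = structures.index(rec)
            for _ in range(n_can):
                d = rng.standard_normal(3)
                d /= np.linalg.norm(d)
                start = _surface_point(rec, d)
                radius = rng.uniform(*config.canaliculus_radius_um)
                budget = config.canaliculus_max_length_um
                if comp == LABELS["interstitial"]:
                    budget *= 0.4
                _walk(start, d, comp, 1, parent, radius, budget)

    if config.connect_osteonal_lacunae and len(osteonal) > 1:
        radius = config.canaliculus_radius_um[1]
        for rec_a, rec_b in zip(osteonal[:-1], osteonal[1:]):
            pts = [np.asarray(rec_a.center_um), np.asarray(rec_b.center_um)]
            n_vox = carver.carve_tube(pts, radius)
            structures.append(
                StructureRecord(
                    kind="canaliculus",
                    compartment="osteonal",
                    true_volume_um3=_tube_volume(pts, radius),
                    voxel_count=n_vox,
                    polyline_um=[tuple(p) for p in pts],
                    radius_um=radius,
                    parent_lacuna=structures.index(rec_a),
                    branch_depth=0,
                )
            )

    # --- assemble ----------------------------------------------------------
    canal_only = carver.canaliculi & ~carver.lacunae
    pores = carver.lacunae | carver.canaliculi
    pores &= regions > 0  # structures never extend outside the specimen
    labels_vol = regions.copy()
    labels_vol[pores] = LABELS["pore"]
    density[labels_vol == LABELS["pore"]] = 0.0
    density[regions == 0] = 0.0
    return BonePhantom(
        density=density.astype(np.float32),
        labels=labels_vol.astype(np.uint8),
        regions=regions.astype(np.uint8),
        structures=structures,
        voxel_size_nm=config.voxel_size_nm,
        seed=seed,
        lacuna_mask=carver.lacunae & (regions > 0),
        canaliculus_mask=canal_only & (regions > 0),
        config=config,
    )


def phantom_ground_truth_report(p: BonePhantom) -> MorphometryReport:
    """Reference morphometry computed directly from the ground truth."""
    vox = p.voxel_volume_um3
    rows = []
    for i, rec in enumerate(p.structures):
        if rec.kind == "lacuna":
            rows.append(
                {
                    "id": i,
                    "compartment": rec.compartment,
                    "volume_um3": rec.true_volume_um3,
                    "voxel_volume_um3": rec.voxel_count * vox,
                }
            )
    lacunae = pd.DataFrame(rows, columns=["id", "compartment", "volume_um3",
                                          "voxel_volume_um3"])
    per_comp = {}
    for lab, name in COMPARTMENT_NAMES.items():
        tissue = p.labels == lab
        comp_mask = p.regions == lab
        lac_vox = int(np.count_nonzero(p.lacuna_mask & comp_mask)) if p.lacuna_mask is not None else 0
        can_vox = int(np.count_nonzero(p.canaliculus_mask & comp_mask)) if p.canaliculus_mask is not None else 0
        sub = lacunae[lacunae.compartment == name].volume_um3
        per_comp[name] = {
            "n_lacunae": int(len(sub)),
            "lacuna_volume_mean_um3": float(sub.mean()) if len(sub) else np.nan,
            "lacuna_volume_sd_um3": float(sub.std(ddof=1)) if len(sub) > 1 else np.nan,
            "lacunar_volume_um3": lac_vox * vox,
            "canalicular_volume_um3": can_vox * vox,
            "canalicular_lacunar_ratio_pct": (
                100.0 * can_vox / lac_vox if lac_vox else 0.0
            ),
            "density_mean_g_cm3": float(p.density[tissue].mean()) if tissue.any() else np.nan,
            "density_sd_g_cm3": float(p.density[tissue].std(ddof=1)) if tissue.any() else np.nan,
        }
    return MorphometryReport(lacunae=lacunae, per_compartment=per_comp)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_phantom(p: BonePhantom, out_dir) -> None:
    """Write density/labels as multi-page TIFF and HDF5, structures as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "density.tif", p.density)
    tifffile.imwrite(out / "labels.tif", p.labels)
    with h5py.File(out / "phantom.h5", "w") as f:
        f.create_dataset("density", data=p.density, compression="gzip")
        f.create_dataset("labels", data=p.labels, compression="gzip")
        f.create_dataset("regions", data=p.regions, compression="gzip")
        if p.lacuna_mask is not None:
            f.create_dataset("lacuna_mask", data=p.lacuna_mask, compression="gzip")
        if p.canaliculus_mask is not None:
            f.create_dataset("canaliculus_mask", data=p.canaliculus_mask,
                             compression="gzip")
        f.attrs["voxel_size_nm"] = p.voxel_size_nm
        if p.seed is not None:
            f.attrs["seed"] = p.seed
    records = [asdict(s) for s in p.structures]
    (out / "structures.json").write_text(json.dumps(records, indent=2))


def read_phantom(path) -> BonePhantom:
    """Read a phantom back from a directory written by :func:`write_phantom`
    (or directly from its ``phantom.h5``)."""
    path = Path(path)
    h5_path = path / "phantom.h5" if path.is_dir() else path
    with h5py.File(h5_path, "r") as f:
        density = f["density"][...]
        labels = f["labels"][...]
        regions = f["regions"][...]
        lac = f["lacuna_mask"][...].astype(bool) if "lacuna_mask" in f else None
        can = f["canaliculus_mask"][...].astype(bool) if "canaliculus_mask" in f else None
        voxel = float(f.attrs["voxel_size_nm"])
        seed = int(f.attrs["seed"]) if "seed" in f.attrs else None
    structures = []
    sj = (h5_path.parent / "structures.json")
    if sj.exists():
        structures = [StructureRecord(**r) for r in json.loads(sj.read_text())]
    return BonePhantom(
        density=density, labels=labels, regions=regions, structures=structures,
        voxel_size_nm=voxel, seed=seed, lacuna_mask=lac, canaliculus_mask=can,
    )
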