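"""End-to-end pipeline: phantom → simulate → retrieve → reconstruct →
segment → stats, as one reproducible run with a manifest.

One YAML/dict configuration holds a section per stage; all randomness is
derived from a single root seed through ``numpy.random.SeedSequence`` so a
run is exactly repeatable.  Every stage writes its artifact under the
output directory and the manifest records configuration, per-stage seeds,
checksums and wall times.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from . import __version__
from .lcn import morphometry, multiscale_enhance, segment_network
from .optics import OpticsGeometry, simulate_scan, RadiographStack
from .phantom import (
    BonePhantom,
    PhantomConfig,
    generate_phantom,
    phantom_ground_truth_report,
    read_phantom,
    write_phantom,
)
from .recon import DensityVolume, reconstruct_density
from .retrieval import (
    PhaseMaps,
    RetrievalConfig,
    linear_ctf_retrieval,
    nonlinear_refine,
    resample_to_common_magnification,
)
from .stats import density_anova, extract_subvolume_samples

__all__ = ["RunManifest", "run_pipeline", "default_demo_config", "ALL_STAGES"]

ALL_STAGES = ("phantom", "simulate", "retrieve", "reconstruct", "segment", "stats")


@dataclass
class RunManifest:
    """Record of one pipeline run: config, seeds, checksums, timings."""

    config: dict
    root_seed: int
    stage_seeds: dict = field(default_factory=dict)
    versions: dict = field(default_factory=dict)
    checksums: dict = field(default_factory=dict)
    wall_times_s: dict = field(default_factory=dict)
    completed: list = field(default_factory=list)
    failed_stage: str | None = None

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def default_demo_config() -> dict:
    """Small two-distance demo: 64³ phantom at 120 nm voxels, 90 angles."""
    return {
        "phantom": {
            "shape": [64, 64, 64],
            "voxel_size_nm": 120.0,
            "specimen_radius_um": 3.3,
            "lacuna_volume_osteonal_um3": 1.0,
            "lacuna_volume_interstitial_um3": 1.2,
            "canaliculi_per_lacuna": 4,
            "canaliculus_radius_um": [0.15, 0.25],
            "canaliculus_max_length_um": 1.0,
        },
        "geometry": {
            "energy_keV": 17.0,
            "d1_mm": [32.6, 33.6, 37.6, 47.6],
            "d_total_mm": 525.0,
            "n_detector": 96,
            "n_angles": 90,
            "photons": 1.0e4,
            "common_pixel_nm": 120.0,
        },
        "retrieval": {"iterations": 10},
        "reconstruction": {"pad": "edge", "apodization": "cosine",
                           "offset_mask_erosion": 2},
        "segmentation": {
            "scales_um": [0.24, 0.36],
            "density_threshold": 0.9,
            "enhancement_threshold": 0.3,
            "size_threshold_um3": 0.5,
            "opening_radius_um": 0.3,
        },
        "stats": {"subvolume_um3": 2.0},
        "stages": list(ALL_STAGES),
    }


def _load_config(config) -> dict:
    if isinstance(config, dict):
        return json.loads(json.dumps(config))  # defensive copy
    with open(config) as f:
        return yaml.safe_load(f)


def _geometry_from_config(section: dict) -> OpticsGeometry:
    section = dict(section)
    common_pixel = section.pop("common_pixel_nm", None)
    if common_pixel is not None:
        common_pixel = float(common_pixel)
    if "d1_mm" in section:
        section["d1_mm"] = tuple(float(d) for d in section["d1_mm"])
    # YAML 1.1 reads "1.0e4" as a string; coerce numeric fields
    for key in ("energy_keV", "d_total_mm", "detector_pixel_um", "photons"):
        if section.get(key) is not None:
            section[key] = float(section[key])
    for key in ("n_detector", "n_angles"):
        if section.get(key) is not None:
            section[key] = int(section[key])
    geom = OpticsGeometry(**section)
    if common_pixel is not None:
        geom = geom.with_common_pixel(common_pixel)
    return geom


def run_pipeline(config, seed: int, out_dir) -> RunManifest:
    """Execute the configured stages in order and write a manifest.

    Stages absent from ``config['stages']`` are skipped; later stages
    resume from the artifacts earlier runs left in ``out_dir``.  Stage
    failure records partial state in the manifest and re-raises.
    """
    cfg = _load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(cfg.get("stages", ALL_STAGES))
    children = np.random.SeedSequence(seed).spawn(len(ALL_STAGES))
    stage_seed = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(ALL_STAGES, children)
    }
    manifest = RunManifest(
        config=cfg,
        root_seed=seed,
        stage_seeds={s: stage_seed[s] for s in stages},
        versions={"nanobone": __version__, "numpy": np.__version__},
    )

    phantom: BonePhantom | None = None
    stack: RadiographStack | None = None
    phase: PhaseMaps | None = None
    volume: DensityVolume | None = None

    def _finish(stage: str, paths: list[Path], t0: float) -> None:
        manifest.wall_times_s[stage] = round(time.time() - t0, 3)
        for p in paths:
            manifest.checksums[str(p.relative_to(out))] = _sha256(p)
        manifest.completed.append(stage)
        manifest.to_json(out / "manifest.json")

    def _need_phantom() -> BonePhantom:
        nonlocal phantom
        if phantom is None:
            phantom = read_phantom(out / "phantom")
        return phantom

    try:
        if "phantom" in stages:
            t0 = time.time()
            pcfg = PhantomConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in cfg.get("phantom", {}).items()
            })
            phantom = generate_phantom(pcfg, seed=stage_seed["phantom"])
            write_phantom(phantom, out / "phantom")
            phantom_ground_truth_report(phantom).to_json(
                out / "phantom" / "ground_truth.json"
            )
            _finish("phantom", sorted((out / "phantom").glob("*")), t0)

        geom = _geometry_from_config(cfg.get("geometry", {}))

        if "simulate" in stages:
            t0 = time.time()
            stack = simulate_scan(_need_phantom(), geom,
                                  seed=stage_seed["simulate"])
            stack.to_hdf5(out / "scan.h5")
            _finish("simulate", [out / "scan.h5"], t0)

        rcfg = RetrievalConfig(**cfg.get("retrieval", {}))

        if "retrieve" in stages:
            t0 = time.time()
            if stack is None:
                stack = RadiographStack.from_hdf5(out / "scan.h5")
            aligned = resample_to_common_magnification(stack)
            phase = nonlinear_refine(
                linear_ctf_retrieval(aligned, rcfg), aligned, rcfg
            )
            phase.to_hdf5(out / "phase.h5")
            _finish("retrieve", [out / "phase.h5"], t0)

        recon_cfg = cfg.get("reconstruction", {})

        if "reconstruct" in stages:
            t0 = time.time()
            if phase is None:
                phase = PhaseMaps.from_hdf5(out / "phase.h5")
            if stack is None:
                stack = RadiographStack.from_hdf5(out / "scan.h5")
            p = _need_phantom()
            erosion = int(recon_cfg.get("offset_mask_erosion", 2))
            mask = p.lacuna_mask
            if mask is not None and erosion > 0:
                eroded = ndimage.binary_erosion(mask, iterations=erosion)
                if eroded.any():
                    mask = eroded
            volume = reconstruct_density(
                phase,
                angles=stack.angles,
                lambda_A=stack.wavelength_A,
                pore_mask=mask,
                pad=recon_cfg.get("pad", "edge"),
                apodization=recon_cfg.get("apodization", "ramp"),
                crop_shape=p.density.shape,
            )
            volume.to_hdf5(out / "volume.h5")
            _finish("reconstruct", [out / "volume.h5"], t0)

        seg_cfg = cfg.get("segmentation", {})

        if "segment" in stages:
            t0 = time.time()
            if volume is None:
                volume = DensityVolume.from_hdf5(out / "volume.h5")
            p = _need_phantom()
            scales_nm = [s * 1e3 for s in seg_cfg.get("scales_um", [0.12, 0.2, 0.3])]
            specimen = p.regions > 0
            enhanced = multiscale_enhance(
                volume.rho, scales_nm, volume.voxel_size_nm, polarity="dark"
            )
            seg = segment_network(
                volume.rho,
                enhanced,
                volume.voxel_size_nm,
                density_threshold=seg_cfg.get("density_threshold", 0.9),
                enhancement_threshold=seg_cfg.get("enhancement_threshold", 0.05),
                size_threshold_um3=seg_cfg.get("size_threshold_um3", 2.0),
                specimen_mask=specimen,
            )
            report = morphometry(
                seg,
                compartments=p.regions,
                density=volume.rho,
                lacuna_opening_radius_um=seg_cfg.get("opening_radius_um", 0.5),
            )
            seg_dir = out / "segmentation"
            seg_dir.mkdir(exist_ok=True)
            np.save(seg_dir / "labels.npy", seg.labels)
            report.to_json(seg_dir / "report.json")
            report.to_csv(seg_dir / "lacunae.csv")
            _finish("segment", sorted(seg_dir.glob("*")), t0)

        stats_cfg = cfg.get("stats", {})

        if "stats" in stages:
            t0 = time.time()
            if volume is None:
                volume = DensityVolume.from_hdf5(out / "volume.h5")
            p = _need_phantom()
            masks = {
                name: p.labels == lab
                for lab, name in ((1, "osteonal"), (2, "interstitial"),
                                  (3, "cement_line"))
            }
            samples = extract_subvolume_samples(
                volume.rho, masks, volume.voxel_size_nm,
                size_um3=stats_cfg.get("subvolume_um3", 8.0),
                fallback_interior=True,  # the cement band is thinner than a cube
            )
            result = density_anova(samples)
            (out / "stats.json").write_text(json.dumps(result, indent=2))
            _finish("stats", [out / "stats.json"], t0)
    except Exception:
        manifest.failed_stage = next(
            (s for s in stages if s not in manifest.completed), None
        )
        manifest.to_json(out / "manifest.json")
        raise

    manifest.to_json(out / "manifest.json")
    return manifest
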