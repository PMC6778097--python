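"""End-to-end workflow orchestration with config files and manifests.

A run chains the stages the way a vessel study uses them: obtain a lumen
mask (from a phantom preset, a mask file, or grayscale segmentation),
extract the centerline, profile the cross-sectional area, and optionally
compute shrinkage against a second profile or a joint-histogram
comparison of two registered volumes.  Every output is listed in a
manifest with a content hash, so a run with a fixed seed is fully
reproducible and verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .centerline import CenterlineParams, CenterlineResult, extract_centerline
from .cross_section import CrossSectionProfile, align_profiles, area_profile, shrinkage_profile
from .histogram import fit_multi_gaussian, gaussian_prefilter, histogram_1d, joint_histogram
from .phantom import (
    GroundTruth,
    bent_tube_spec,
    bifurcated_tube_spec,
    make_oblique_cylinder,
    make_tube,
    swelling_benchmark_spec,
)
from .segmentation import SegmentationParams, segment_lumen
from .volume_io import LumenMask, read_mask, read_volume, write_volume

logger = logging.getLogger(__name__)

PHANTOM_PRESETS = ("straight", "oblique-30", "bent", "swelling-benchmark", "bifurcation")


def make_phantom_preset(preset: str) -> tuple[LumenMask, GroundTruth]:
    """Build one of the named phantom geometries."""
    if preset == "straight":
        from .phantom import TubeSpec, straight_curve

        spec = TubeSpec(
            curve=straight_curve((32.0, 32.0, 0.0), (32.0, 32.0, 79.0)),
            radius_profile=10.0,
            grid_shape=(64, 64, 80),
        )
        return make_tube(spec)
    if preset == "oblique-30":
        return make_oblique_cylinder(30.0, 10.0, (96, 64, 96))
    if preset == "bent":
        return make_tube(bent_tube_spec())
    if preset == "swelling-benchmark":
        return make_tube(swelling_benchmark_spec())
    if preset == "bifurcation":
        return make_tube(bifurcated_tube_spec())
    raise ValueError(f"unknown phantom preset {preset!r}; choose from {PHANTOM_PRESETS}")


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run."""

    output_dir: Path
    voxel_length: float = 1.0
    seed: int = 0
    # input alternatives, in precedence order
    phantom_preset: str | None = None
    mask_path: Path | None = None
    volume_path: Path | None = None
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    centerline: CenterlineParams = field(default_factory=CenterlineParams)
    # optional comparison stages
    compare_profile: Path | None = None
    profile_offset_mm: float | None = None
    histogram_a: Path | None = None
    histogram_b: Path | None = None
    histogram_bins: int = 256
    prefilter_a_sigma: float | None = None

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if "output_dir" not in d:
            raise ValueError("config requires output_dir")
        seg = SegmentationParams(**d.pop("segmentation", {}))
        cl = CenterlineParams(**d.pop("centerline", {}))
        for key in ("mask_path", "volume_path", "compare_profile", "histogram_a", "histogram_b"):
            if d.get(key) is not None:
                d[key] = Path(d[key])
        cfg = cls(
            output_dir=Path(d.pop("output_dir")), segmentation=seg, centerline=cl, **d
        )
        for p in (cfg.mask_path, cfg.volume_path, cfg.compare_profile, cfg.histogram_a, cfg.histogram_b):
            if p is not None and not Path(p).exists():
                raise ValueError(f"configured path does not exist: {p}")
        if cfg.phantom_preset is None and cfg.mask_path is None and cfg.volume_path is None:
            raise ValueError("config needs one of phantom_preset, mask_path, volume_path")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def write_centerline_csv(result: CenterlineResult, path: Path) -> None:
    p = result.final.points
    t = result.tangents.tangents
    df = pd.DataFrame(
        {
            "k": np.arange(len(p)),
            "x": p[:, 0],
            "y": p[:, 1],
            "z": p[:, 2],
            "tx": t[:, 0],
            "ty": t[:, 1],
            "tz": t[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.8g")


def write_vtk_polyline(points: np.ndarray, path: Path) -> None:
    """Legacy-ASCII VTK polyline for 3D viewers."""
    n = len(points)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncenterline\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {n} float\n")
        for p in points:
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        fh.write(f"LINES 1 {n + 1}\n")
        fh.write(" ".join([str(n)] + [str(i) for i in range(n)]) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the output directory.

    Raises on stage failure after retaining any partial outputs already
    written; the manifest is only written on success.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    # --- input stage -------------------------------------------------
    if config.phantom_preset is not None:
        mask, truth = make_phantom_preset(config.phantom_preset)
        mask = LumenMask(mask.data, config.voxel_length, name=config.phantom_preset)
        gt_path = out / "ground_truth.csv"
        pd.DataFrame(
            truth.to_table(), columns=["t", "x", "y", "z", "r", "area", "arclength"]
        ).to_csv(gt_path, index=False, float_format="%.8g")
        mask_path = out / "mask.tif"
        write_volume(mask, mask_path)
        outputs += [gt_path, mask_path]
    elif config.mask_path is not None:
        mask = read_mask(config.mask_path, voxel_length=config.voxel_length)
    else:
        vol = read_volume(config.volume_path, voxel_length=config.voxel_length)
        mask = segment_lumen(vol, config.segmentation)
        mask_path = out / "mask.tif"
        write_volume(mask, mask_path)
        outputs.append(mask_path)

    # --- centerline --------------------------------------------------
    logger.info("extracting centerline (beta=%.2f, sigma=%.1f, mu=%.2f)",
                config.centerline.beta, config.centerline.sigma, config.centerline.mu)
    result = extract_centerline(mask, config.centerline)
    cl_path = out / "centerline.csv"
    write_centerline_csv(result, cl_path)
    res_path = out / "residuals.txt"
    np.savetxt(res_path, np.asarray(result.residual_history), fmt="%.6f")
    vtk_path = out / "centerline.vtk"
    write_vtk_polyline(result.final.points, vtk_path)
    outputs += [cl_path, res_path, vtk_path]

    # --- area profile ------------------------------------------------
    profile = area_profile(mask, result, voxel_length=config.voxel_length,
                           allow_unconverged=True)
    prof_path = out / "profile.csv"
    profile.to_csv(prof_path)
    outputs.append(prof_path)

    # --- shrinkage ---------------------------------------------------
    if config.compare_profile is not None:
        after = CrossSectionProfile.from_csv(config.compare_profile)
        offset = align_profiles(profile, after, fixed_offset=config.profile_offset_mm)
        shrink = shrinkage_profile(profile, after, offset)
        sh_path = out / "shrinkage.csv"
        shrink.to_csv(sh_path)
        outputs.append(sh_path)

    # --- joint histogram ---------------------------------------------
    if config.histogram_a is not None and config.histogram_b is not None:
        va = read_volume(config.histogram_a, voxel_length=config.voxel_length)
        vb = read_volume(config.histogram_b, voxel_length=config.voxel_length)
        if config.prefilter_a_sigma:
            va = gaussian_prefilter(va, config.prefilter_a_sigma)
        jh = joint_histogram(va, vb, n_bins=config.histogram_bins)
        jh_path = out / "joint_histogram.csv"
        np.savetxt(jh_path, jh.counts, fmt="%d", delimiter=",")
        rows = []
        for label, counts, edges in (
            ("A", jh.marginal("a"), jh.edges_a),
            ("B", jh.marginal("b"), jh.edges_b),
        ):
            fit = fit_multi_gaussian(counts, jh.centers(edges), n_components=4)
            for ci, (amp, mean, sig) in enumerate(fit.components):
                rows.append((label, ci, amp, mean, sig, fit.rss))
        fit_path = out / "gaussian_fits.csv"
        pd.DataFrame(
            rows, columns=["axis", "component", "amplitude", "mean", "sigma", "rss"]
        ).to_csv(fit_path, index=False, float_format="%.8g")
        outputs += [jh_path, fit_path]

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "voxel_length_um": config.voxel_length,
        "converged": result.converged,
        "iterations": len(result.residual_history),
        "parameters": {
            "beta": config.centerline.beta,
            "sigma": config.centerline.sigma,
            "mu": config.centerline.mu,
            "max_iter": config.centerline.max_iter,
            "median_kernel": config.segmentation.median_kernel,
            "opening_radius": config.segmentation.opening_radius,
        },
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
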