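"""Synthetic tubular phantoms with exact analytic ground truth.

These phantoms emulate the geometry of a diseased artery segment: a bent
tube with local swellings (aneurysm-like bulges), a constriction
(stenosis), and optionally a blind-ended side appendage standing in for a
bifurcation.  Each generated mask comes with the analytic centerline,
radius profile, orthogonal cross-sectional areas and arclength table, so
every downstream stage can be validated without any measured dataset.

The rasterization rule is a plain center-in-tube test: a voxel belongs to
the lumen iff the distance from its center to the nearest point of the
centerline curve is at most the local tube radius.  No antialiasing is
applied, which keeps the generator and the exhaustive test oracle
trivially identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .volume_io import LumenMask, VoxelVolume

__all__ = [
    "TubeSpec",
    "BranchSpec",
    "GroundTruth",
    "make_tube",
    "make_oblique_cylinder",
    "make_two_modality_phantom",
    "straight_curve",
    "arc_curve",
    "piecewise_linear_radius",
    "swelling_radius",
    "swelling_benchmark_spec",
    "bent_tube_spec",
    "bifurcated_tube_spec",
    "random_class_map",
    "slab_class_map",
]

CurveFn = Callable[[np.ndarray], np.ndarray]
RadiusFn = Callable[[np.ndarray], np.ndarray]

#: curve samples used for rasterization and ground truth
_N_SAMPLES = 2000


@dataclass
class BranchSpec:
    """A blind-ended cylindrical appendage attached to the parent tube."""

    attach_t: float
    direction: tuple[float, float, float]
    length: float
    radius: float

    def __post_init__(self) -> None:
        if not 0.0 < self.attach_t < 1.0:
            raise ValueError(f"attach_t must be in (0, 1), got {self.attach_t}")
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("branch direction must be nonzero")
        self.direction = tuple(d / n)


@dataclass
class TubeSpec:
    """Parametric description of a tubular lumen phantom.

    ``curve`` maps t in [0, 1] to 3D positions in voxel units, either as a
    callable or as an (n, 3) array of polyline control points.
    ``radius_profile`` is the local tube radius r(t) in voxels (callable
    or scalar).  Radii below 2 voxels are rejected: sub-voxel tubes are
    not representable on the grid.
    """

    curve: CurveFn | np.ndarray
    radius_profile: RadiusFn | float
    grid_shape: tuple[int, int, int]
    branch: BranchSpec | None = None

    def curve_fn(self) -> CurveFn:
        if callable(self.curve):
            return self.curve
        pts = np.asarray(self.curve, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
            raise ValueError("polyline curve must be an (n>=2, 3) array")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        s /= s[-1]

        def interp(t: np.ndarray) -> np.ndarray:
            t = np.atleast_1d(np.asarray(t, dtype=float))
            return np.stack([np.interp(t, s, pts[:, i]) for i in range(3)], axis=-1)

        return interp

    def radius_fn(self) -> RadiusFn:
        if callable(self.radius_profile):
            return self.radius_profile
        r = float(self.radius_profile)
        return lambda t: np.full(np.shape(np.atleast_1d(t)), r)


@dataclass
class GroundTruth:
    """Analytic truth for a phantom: centerline, radii, areas, arclengths."""

    t: np.ndarray
    centerline_points: np.ndarray  # (n, 3), voxel units
    radii: np.ndarray  # voxels
    areas: np.ndarray  # voxel^2, orthogonal section pi r^2
    arclengths: np.ndarray  # cumulative, voxels

    def __post_init__(self) -> None:
        if not (self.areas > 0).all():
            raise ValueError("ground-truth areas must be positive")
        if not (np.diff(self.arclengths) > 0).all():
            raise ValueError("arclengths must be strictly increasing")

    def to_table(self) -> "np.ndarray":
        return np.column_stack(
            [self.t, self.centerline_points, self.radii, self.areas, self.arclengths]
        )


def _sample_truth(spec: TubeSpec, n: int = _N_SAMPLES) -> GroundTruth:
    t = np.linspace(0.0, 1.0, n)
    pts = spec.curve_fn()(t)
    r = np.asarray(spec.radius_fn()(t), dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    return GroundTruth(t=t, centerline_points=pts, radii=r, areas=np.pi * r**2, arclengths=arc)


def _validate_inside(pts: np.ndarray, r: np.ndarray, grid_shape: Sequence[int]) -> None:
    # the orthogonal disc at every station must stay inside the grid; a tube
    # may run through the grid end faces along its own axis
    d = np.gradient(pts, axis=0)
    d /= np.maximum(np.linalg.norm(d, axis=1, keepdims=True), 1e-12)
    ext = r[:, None] * np.sqrt(np.clip(1.0 - d**2, 0.0, 1.0))
    dims = np.asarray(grid_shape, dtype=float)
    if (pts - ext < -1e-6).any() or (pts + ext > dims - 1 + 1e-6).any():
        raise ValueError(
            "tube exits the grid: curve must stay inside with margin >= max radius"
        )


def _point_segment_distance(
    p: np.ndarray, a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Distance from points p to segments a->b and the projection fraction."""
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom = np.where(denom > 0, denom, 1.0)
    s = np.clip(np.einsum("ij,ij->i", p - a, ab) / denom, 0.0, 1.0)
    closest = a + s[:, None] * ab
    return np.linalg.norm(p - closest, axis=1), s


def _rasterize_tube(
    pts: np.ndarray, radii: np.ndarray, grid_shape: tuple[int, int, int]
) -> np.ndarray:
    """Foreground iff the voxel center lies within r(t*) of the curve at the
    locally nearest curve point t* (distance to the sampled polyline's
    segments, radius linearly interpolated along the segment)."""
    tree = cKDTree(pts)
    r_max = float(radii.max())
    lo = np.maximum(np.floor(pts.min(axis=0) - r_max).astype(int), 0)
    hi = np.minimum(np.ceil(pts.max(axis=0) + r_max).astype(int) + 1, grid_shape)
    xs, ys, zs = (np.arange(lo[i], hi[i]) for i in range(3))
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]).astype(float)
    _, idx = tree.query(centers, workers=1)
    # refine the vertex hit to the two adjacent polyline segments
    n = len(pts)
    best_d = np.full(len(centers), np.inf)
    best_r = np.empty(len(centers))
    for lo_i, hi_i in ((np.maximum(idx - 1, 0), idx), (idx, np.minimum(idx + 1, n - 1))):
        d, s = _point_segment_distance(centers, pts[lo_i], pts[hi_i])
        r = radii[lo_i] + s * (radii[hi_i] - radii[lo_i])
        better = d < best_d
        best_d = np.where(better, d, best_d)
        best_r = np.where(better, r, best_r)
    inside = best_d <= best_r
    mask = np.zeros(grid_shape, dtype=bool)
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = inside.reshape(gx.shape)
    return mask


def make_tube(spec: TubeSpec, n_samples: int = _N_SAMPLES) -> tuple[LumenMask, GroundTruth]:
    """Rasterize a tube spec into a binary lumen mask plus its ground truth."""
    truth = _sample_truth(spec, n_samples)
    if (truth.radii < 2.0).any():
        raise ValueError("radius profile must be >= 2 voxels everywhere")
    _validate_inside(truth.centerline_points, truth.radii, spec.grid_shape)
    mask = _rasterize_tube(truth.centerline_points, truth.radii, spec.grid_shape)
    if spec.branch is not None:
        b = spec.branch
        parent_r = float(spec.radius_fn()(np.atleast_1d(b.attach_t))[0])
        if b.radius > parent_r:
            raise ValueError("branch radius must not exceed the parent radius at attachment")
        start = spec.curve_fn()(np.atleast_1d(b.attach_t))[0]
        d = np.asarray(b.direction)
        n_b = max(2, int(4 * b.length))
        bpts = start + np.linspace(0.0, b.length, n_b)[:, None] * d
        bradii = np.full(n_b, float(b.radius))
        _validate_inside(bpts, bradii, spec.grid_shape)
        mask |= _rasterize_tube(bpts, bradii, spec.grid_shape)
    return LumenMask(mask), truth


def straight_curve(start: Sequence[float], end: Sequence[float]) -> CurveFn:
    p0 = np.asarray(start, dtype=float)
    p1 = np.asarray(end, dtype=float)

    def fn(t: np.ndarray) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return p0 + t[:, None] * (p1 - p0)

    return fn


def arc_curve(
    start: Sequence[float], length: float, bend_deg: float, plane: str = "xz"
) -> CurveFn:
    """Circular arc of given length turning by ``bend_deg`` in the x–z plane.

    The tangent starts at an angle of ``-bend_deg/2`` from the z axis and
    ends at ``+bend_deg/2``, so the chord runs roughly along z.
    """
    if plane != "xz":
        raise ValueError("only the x–z bending plane is supported")
    p0 = np.asarray(start, dtype=float)
    theta = np.deg2rad(bend_deg)
    if abs(theta) < 1e-12:
        return straight_curve(p0, p0 + np.array([0.0, 0.0, length]))
    R = length / theta

    def fn(t: np.ndarray) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        phi = (t - 0.5) * theta
        phi0 = -0.5 * theta
        x = p0[0] + R * (np.cos(phi0) - np.cos(phi))
        y = np.full_like(x, p0[1])
        z = p0[2] + R * (np.sin(phi) - np.sin(phi0))
        return np.stack([x, y, z], axis=-1)

    return fn


def piecewise_linear_radius(t_knots: Sequence[float], r_knots: Sequence[float]) -> RadiusFn:
    tk = np.asarray(t_knots, dtype=float)
    rk = np.asarray(r_knots, dtype=float)

    def fn(t: np.ndarray) -> np.ndarray:
        return np.interp(np.atleast_1d(np.asarray(t, dtype=float)), tk, rk)

    return fn


def swelling_radius(
    base: float, bumps: Sequence[tuple[float, float, float]]
) -> RadiusFn:
    """Base radius plus Gaussian bumps ``(center_t, amplitude, width_t)``.

    Negative amplitudes model constrictions.
    """

    def fn(t: np.ndarray) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        r = np.full_like(t, float(base))
        for c, a, w in bumps:
            r = r + a * np.exp(-0.5 * ((t - c) / w) ** 2)
        return r

    return fn


def bent_tube_spec(
    grid_shape: tuple[int, int, int] = (64, 64, 232),
    length: float = 200.0,
    bend_deg: float = 20.0,
    radius: float = 8.0,
) -> TubeSpec:
    """Plain bent tube: constant radius, circular-arc axis."""
    cx, cy = grid_shape[0] / 2.0, grid_shape[1] / 2.0
    theta = np.deg2rad(bend_deg)
    chord = length if theta == 0 else length * np.sin(theta / 2) / (theta / 2)
    z0 = (grid_shape[2] - 1 - chord) / 2.0
    return TubeSpec(
        curve=arc_curve((cx, cy, z0), length, bend_deg),
        radius_profile=radius,
        grid_shape=grid_shape,
    )


def swelling_benchmark_spec(
    grid_shape: tuple[int, int, int] = (72, 64, 232),
) -> TubeSpec:
    """Default benchmark: 200-voxel tube, base radius 8, two swellings to
    r = 14, one constriction to r = 5, bent by 20 degrees overall."""
    spec = bent_tube_spec(grid_shape=grid_shape, length=200.0, bend_deg=20.0, radius=8.0)
    radius = swelling_radius(
        8.0,
        [(0.22, 6.0, 0.08), (0.5, -3.0, 0.06), (0.78, 6.0, 0.08)],
    )
    return TubeSpec(curve=spec.curve, radius_profile=radius, grid_shape=grid_shape)


def bifurcated_tube_spec(
    grid_shape: tuple[int, int, int] = (128, 64, 232),
    branch_length: float = 60.0,
    branch_radius: float = 3.0,
) -> TubeSpec:
    """Straight tube with a long thin blind-ended side appendage.

    The appendage emulates a bifurcation stub: it drags the initial
    per-z-slice centroids sideways into a pronounced bulge that the
    orthogonal-slice iteration must remove.  The parent is kept straight
    so the converged deviation isolates the appendage's influence, and
    the appendage is long and thin: its volume (which drives the initial
    centroid bulge) is large while its cross-section (which biases the
    few orthogonal slices where it merges with the parent section near
    the attachment) stays small.
    """
    branch = BranchSpec(
        attach_t=0.45,
        direction=(0.9, 0.0, 0.436),
        length=branch_length,
        radius=branch_radius,
    )
    return TubeSpec(
        curve=straight_curve((40.0, 32.0, 16.0), (40.0, 32.0, 215.0)),
        radius_profile=8.0,
        grid_shape=grid_shape,
        branch=branch,
    )


def make_oblique_cylinder(
    angle_deg: float,
    radius: float,
    grid_shape: tuple[int, int, int],
    n_samples: int = _N_SAMPLES,
) -> tuple[LumenMask, GroundTruth]:
    """Straight cylinder tilted by ``angle_deg`` from z in the x–z plane.

    The ground-truth orthogonal cross-section is pi r^2 irrespective of
    the tilt, whereas a naive per-z-slice count inflates by 1/cos(angle).
    """
    if not 0.0 <= angle_deg < 60.0:
        raise ValueError(f"angle_deg must be in [0, 60), got {angle_deg}")
    a = np.deg2rad(angle_deg)
    d = np.array([np.sin(a), 0.0, np.cos(a)])
    nz = grid_shape[2]
    margin = radius + 2.0
    # run the axis through the grid center, spanning as much z as the margin allows
    half_len = (nz - 1 - 2 * margin) / (2 * np.cos(a))
    center = np.array([grid_shape[0] / 2.0, grid_shape[1] / 2.0, (nz - 1) / 2.0])
    p0, p1 = center - half_len * d, center + half_len * d
    spec = TubeSpec(curve=straight_curve(p0, p1), radius_profile=radius, grid_shape=grid_shape)
    return make_tube(spec, n_samples)


def shrinkage_pair_specs(
    voxel_length: float = 10.0,
    segment_scales: Sequence[float] = (0.85, 0.65, 0.35),
    crop_offset_mm: float = 0.5,
) -> tuple[TubeSpec, TubeSpec, dict]:
    """Before/after tube pair emulating preparation-induced shrinkage.

    The "after" tube reproduces a cropped portion of the "before" tube
    with its cross-sectional area scaled segment-wise by
    ``segment_scales`` (radius scaled by the square root), emulating
    e.g. paraffin embedding that shrinks the lumen non-uniformly.  The
    crop removes ``crop_offset_mm`` from the upstream end, so profile
    alignment must recover that offset.  Gentle radius bumps on the
    baseline give the correlation-based alignment features to lock onto.

    Returns (before_spec, after_spec, info) with info holding the
    segment boundaries in mm and the expected shrinkage percentages.
    """
    length = 180.0  # voxels
    crop = crop_offset_mm * 1000.0 / voxel_length  # voxels
    scales = np.asarray(segment_scales, dtype=float)
    # first segment extended so it stays measurable after the crop
    if len(scales) == 3:
        seg_edges = np.array([0.0, 80.0, 130.0, 180.0])
    else:
        seg_edges = np.linspace(0.0, length, len(scales) + 1)

    def r_before_s(s: np.ndarray) -> np.ndarray:
        t = np.asarray(s, dtype=float) / length
        bumps = 2.0 * np.exp(-0.5 * ((t - 0.3) / 0.09) ** 2) + 1.5 * np.exp(
            -0.5 * ((t - 0.7) / 0.08) ** 2
        )
        return 10.0 + bumps

    def scale_s(s: np.ndarray) -> np.ndarray:
        idx = np.clip(
            np.searchsorted(seg_edges, np.asarray(s, dtype=float), side="right") - 1,
            0,
            len(scales) - 1,
        )
        return scales[idx]

    grid_before = (64, 64, int(length) + 32)
    grid_after = (64, 64, int(length - crop) + 32)
    before = TubeSpec(
        curve=straight_curve((32.0, 32.0, 16.0), (32.0, 32.0, 16.0 + length)),
        radius_profile=lambda t: r_before_s(np.atleast_1d(t) * length),
        grid_shape=grid_before,
    )
    after_len = length - crop
    after = TubeSpec(
        curve=straight_curve((32.0, 32.0, 16.0), (32.0, 32.0, 16.0 + after_len)),
        radius_profile=lambda t: (
            np.sqrt(scale_s(np.atleast_1d(t) * after_len + crop))
            * r_before_s(np.atleast_1d(t) * after_len + crop)
        ),
        grid_shape=grid_after,
    )
    info = {
        "voxel_length": voxel_length,
        "segment_edges_mm": (seg_edges * voxel_length / 1000.0).tolist(),
        "expected_shrinkage_pct": (100.0 * (1.0 - scales)).tolist(),
        "crop_offset_mm": crop_offset_mm,
    }
    return before, after, info


# ---------------------------------------------------------------------------
# two-modality tissue phantom


def random_class_map(
    shape: tuple[int, int, int], proportions: Sequence[float], seed: int
) -> np.ndarray:
    """Voxel-wise i.i.d. class labels 0..n-1 with the given proportions."""
    p = np.asarray(proportions, dtype=float)
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    return rng.choice(len(p), size=shape, p=p).astype(np.int32)


def slab_class_map(shape: tuple[int, int, int], proportions: Sequence[float]) -> np.ndarray:
    """Spatially coherent class map: contiguous z-slabs with the given proportions."""
    p = np.asarray(proportions, dtype=float)
    p = p / p.sum()
    edges = np.round(np.cumsum(np.concatenate([[0.0], p])) * shape[2]).astype(int)
    out = np.zeros(shape, dtype=np.int32)
    for lab in range(len(p)):
        out[:, :, edges[lab] : edges[lab + 1]] = lab
    return out


def make_two_modality_phantom(
    class_map: np.ndarray,
    means_a: Sequence[float],
    sigmas_a: Sequence[float],
    means_b: Sequence[float],
    sigmas_b: Sequence[float],
    seed: int,
    shared_noise: bool = False,
    outlier_fraction: float = 0.0,
    outlier_scale: float = 8.0,
    noise_correlation: float = 0.0,
) -> tuple[VoxelVolume, VoxelVolume]:
    """Draw two registered volumes from per-class Gaussian intensity models.

    Each voxel's intensity in modality A (resp. B) is drawn from the
    Gaussian of its tissue class; the two modalities are independent
    unless ``shared_noise`` reuses the same standard-normal draws (which
    concentrates the joint histogram on the class diagonal).  A nonzero
    ``outlier_fraction`` replaces that fraction of voxels with
    heavy-tailed noise (``outlier_scale`` times the class sigma),
    emulating the non-Gaussian speckle of tomographic reconstructions
    that a Gaussian prefilter is meant to suppress.  A positive
    ``noise_correlation`` gives the Gaussian background noise a spatial
    correlation length (in voxels, unit variance preserved), as in real
    reconstructions where noise is not white.  The same seed always
    reproduces the same pair bit for bit.
    """
    class_map = np.asarray(class_map)
    n_classes = len(means_a)
    if not (len(sigmas_a) == len(means_b) == len(sigmas_b) == n_classes):
        raise ValueError("means/sigmas must all have the same length")
    if any(s <= 0 for s in sigmas_a) or any(s <= 0 for s in sigmas_b):
        raise ValueError("all sigmas must be > 0")
    present = np.unique(class_map)
    expected = np.arange(n_classes)
    if not np.array_equal(present, expected):
        missing = sorted(set(expected) - set(present.tolist()))
        raise ValueError(f"class labels {missing} absent from class_map")
    if not 0.0 <= outlier_fraction < 1.0:
        raise ValueError("outlier_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    za = rng.standard_normal(class_map.shape)
    zb = za if shared_noise else rng.standard_normal(class_map.shape)
    if noise_correlation > 0.0:
        from scipy import ndimage as _ndi

        # L2 norm of the smoothing kernel, to restore unit variance
        probe = np.zeros((int(8 * noise_correlation) + 9,) * 3)
        probe[tuple(s // 2 for s in probe.shape)] = 1.0
        norm = np.sqrt((_ndi.gaussian_filter(probe, noise_correlation) ** 2).sum())
        za = _ndi.gaussian_filter(za, noise_correlation) / norm
        zb = za if shared_noise else _ndi.gaussian_filter(zb, noise_correlation) / norm
    if outlier_fraction > 0.0:
        hit = rng.random(class_map.shape) < outlier_fraction
        za = np.where(hit, za * outlier_scale, za)
        zb = np.where(hit, zb * outlier_scale, zb)
    ma, sa = np.asarray(means_a, float), np.asarray(sigmas_a, float)
    mb, sb = np.asarray(means_b, float), np.asarray(sigmas_b, float)
    vol_a = ma[class_map] + sa[class_map] * za
    vol_b = mb[class_map] + sb[class_map] * zb
    return (
        VoxelVolume(vol_a, 1.0, name="modality_A"),
        VoxelVolume(vol_b, 1.0, name="modality_B"),
    )
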