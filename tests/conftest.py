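"""Shared phantom fixtures.

Heavy objects (rasterized phantoms and their extracted centerlines) are
session-scoped: the geometry is deterministic, so every test sees the
same object and the expensive extraction runs once.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial import cKDTree

import lumenline as L
from lumenline.phantom import (
    TubeSpec,
    bent_tube_spec,
    bifurcated_tube_spec,
    shrinkage_pair_specs,
    straight_curve,
    swelling_benchmark_spec,
)


def interior_deviations(points: np.ndarray, truth) -> np.ndarray:
    """Distances from centerline points to the analytic curve, excluding
    points that project onto the curve endpoints (end-cap stations have
    no orthogonal counterpart on the parametric curve)."""
    tree = cKDTree(truth.centerline_points)
    d, idx = tree.query(points)
    interior = (idx > 0) & (idx < len(truth.centerline_points) - 1)
    return d[interior]


def truth_lookup(points: np.ndarray, truth):
    """(distance, radius, area, interior flag) of the nearest curve sample."""
    tree = cKDTree(truth.centerline_points)
    d, idx = tree.query(points)
    interior = (idx > 0) & (idx < len(truth.centerline_points) - 1)
    return d, truth.radii[idx], truth.areas[idx], interior


@pytest.fixture(scope="session")
def straight_tube():
    spec = TubeSpec(
        curve=straight_curve((32.0, 32.0, 0.0), (32.0, 32.0, 79.0)),
        radius_profile=10.0,
        grid_shape=(64, 64, 80),
    )
    return L.make_tube(spec)


@pytest.fixture(scope="session")
def straight_result(straight_tube):
    mask, _ = straight_tube
    return L.extract_centerline(mask)


@pytest.fixture(scope="session")
def oblique30():
    return L.make_oblique_cylinder(30.0, 10.0, (96, 64, 96))


@pytest.fixture(scope="session")
def oblique30_result(oblique30):
    mask, _ = oblique30
    return L.extract_centerline(mask)


@pytest.fixture(scope="session")
def bent_tube():
    return L.make_tube(bent_tube_spec())


@pytest.fixture(scope="session")
def bent_result(bent_tube):
    mask, _ = bent_tube
    return L.extract_centerline(mask)


@pytest.fixture(scope="session")
def swelling_tube():
    return L.make_tube(swelling_benchmark_spec())


@pytest.fixture(scope="session")
def swelling_result(swelling_tube):
    mask, _ = swelling_tube
    return L.extract_centerline(mask)


@pytest.fixture(scope="session")
def branch_tube():
    return L.make_tube(bifurcated_tube_spec())


@pytest.fixture(scope="session")
def branch_result(branch_tube):
    mask, _ = branch_tube
    return L.extract_centerline(mask)


@pytest.fixture(scope="session")
def branchless_result():
    spec = bifurcated_tube_spec()
    spec.branch = None
    mask, _ = L.make_tube(spec)
    return L.extract_centerline(mask)


@pytest.fixture(scope="session")
def shrinkage_scenario():
    """Before/after profiles of the segmental-shrinkage phantom pair."""
    before_spec, after_spec, info = shrinkage_pair_specs()
    mask_b, truth_b = L.make_tube(before_spec)
    mask_a, truth_a = L.make_tube(after_spec)
    res_b = L.extract_centerline(mask_b)
    res_a = L.extract_centerline(mask_a)
    l_um = info["voxel_length"]
    prof_b = L.area_profile(mask_b, res_b, voxel_length=l_um)
    prof_a = L.area_profile(mask_a, res_a, voxel_length=l_um)
    return {
        "before": prof_b,
        "after": prof_a,
        "info": info,
        "truth_before": truth_b,
        "res_before": res_b,
    }
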