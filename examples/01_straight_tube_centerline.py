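"""Extract the centerline of a straight tube phantom.

The trivial geometry shows the termination contract: when the lumen is
parallel to the z-axis, the per-slice centroids already are the
centerline, and the algorithm stops at the first residual check.
"""

import numpy as np

import lumenline as L
from lumenline.phantom import TubeSpec, straight_curve

spec = TubeSpec(
    curve=straight_curve((32.0, 32.0, 0.0), (32.0, 32.0, 79.0)),
    radius_profile=10.0,
    grid_shape=(64, 64, 80),
)
mask, truth = L.make_tube(spec)
result = L.extract_centerline(mask)

dev = np.hypot(result.final.points[:, 0] - 32.0, result.final.points[:, 1] - 32.0)
print(f"converged: {result.converged} after {len(result.residual_history)} iteration(s)")
print(f"residual history (voxel): {[round(r, 4) for r in result.residual_history]}")
print(f"max deviation from the true axis: {dev.max():.4f} voxel")
# One iteration with a near-zero residual means the initial per-slice
# centroid centerline was already self-consistent; the deviation confirms
# it coincides with the analytic tube axis.
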