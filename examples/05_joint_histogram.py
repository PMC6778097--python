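"""Joint-histogram comparison of two registered imaging modalities.

A four-class tissue phantom (embedding medium, fibrous tissue, vessel
wall, residual plaque) is imaged by two synthetic modalities with
different contrasts. The joint histogram clusters per class; the
marginal histograms are decomposed into four Gaussians. With noisy
overlapping classes, a sigma = 2 Gaussian prefilter restores four
separable peaks, mirroring how a prefilter rescues a noisy tomogram.
"""

import numpy as np
from scipy.signal import find_peaks

import lumenline as L
from lumenline.phantom import make_two_modality_phantom, slab_class_map

cm = slab_class_map((48, 48, 48), (0.4, 0.3, 0.2, 0.1))
va, vb = make_two_modality_phantom(
    cm, [20, 50, 80, 110], [3] * 4, [15, 45, 75, 105], [3] * 4, seed=2
)
jh = L.joint_histogram(va, vb, n_bins=64)
print(f"joint histogram: {jh.counts.shape[0]}x{jh.counts.shape[1]} bins, "
      f"{jh.n_voxels} voxels, marginals exact: "
      f"{np.array_equal(jh.marginal('a'), L.histogram_1d(va, edges=jh.edges_a)[0])}")

counts, edges = L.histogram_1d(va, n_bins=128, percentile_range=(0, 100))
fit = L.fit_multi_gaussian(counts, 0.5 * (edges[:-1] + edges[1:]), 4)
print("fitted class means :", np.round(fit.means, 2), " (true: 20 50 80 110)")
print("fitted class sigmas:", np.round(fit.sigmas, 2), " (true: 3)")

# overlapping-class volume: one broad hump until prefiltered
cm2 = slab_class_map((64, 64, 64), (0.25,) * 4)
vo, _ = make_two_modality_phantom(
    cm2, [20, 35, 50, 65], [8] * 4, [20, 35, 50, 65], [8] * 4,
    seed=3, outlier_fraction=0.05, noise_correlation=1.0,
)
vf = L.gaussian_prefilter(vo, 2.0)
c_raw, e = L.histogram_1d(vo, n_bins=128)
c_flt, _ = L.histogram_1d(vf, edges=e)
dist = max(1, int(7.5 / (e[1] - e[0])))
n_raw = len(find_peaks(c_raw, distance=dist, prominence=0.05 * c_raw.max())[0])
n_flt = len(find_peaks(c_flt, distance=dist, prominence=0.05 * c_flt.max())[0])
print(f"separable peaks before prefilter: {n_raw}, after sigma=2 prefilter: {n_flt}")
# Four peaks after filtering means each tissue class is segmentable by
# intensity again, as in the filtered-modality comparison.
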