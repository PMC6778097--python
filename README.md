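# lumenline

Centerline-based quantification of blood-vessel lumina in 3D tomographic
volumes.

Atherosclerotic arteries are bent, locally swollen or constricted, and
may carry side branches — so the lumen is not a cylinder and is rarely
parallel to the scan axis. Counting segmented voxels per z-slice then
overestimates the cross-sectional area by 1/cos θ of the local tilt, and
classical skeletonization is unreliable on such shapes. `lumenline`
implements a dedicated pipeline for this problem:

1. **Segmentation preprocessing** — cubic median filtering (default
   kernel 15), seeded region growing, and large-radius morphological
   opening (a 20-voxel Euclidean ball) to strip debris from
   contaminated lumina.
2. **Iterative centerline extraction** — starting from per-slice
   centroids c₀,ₖ, the algorithm repeatedly (i) computes unit tangents
   τᵢ,ₖ by second-order finite differences, (ii) resamples planar slices
   orthogonal to each tangent by trilinear interpolation, (iii)
   re-centers each point on the nearest foreground component of its
   slice, giving candidates c_j,k, and (iv) applies the relaxation
   update

       c_{i+1,k} = (1 − β) c_{j,k} + β c_{i,k},    β = 0.5 (default)

   followed by Gaussian smoothing (σ = 20 samples) along the curve.
   The loop stops when the residual ρ = Σₖ d(c_{i−1,k}, c_{i,k})/N_k —
   the mean pointwise displacement between iterates — falls below
   μ = 0.3 voxel.
3. **Cross-section profiling** — lumen areas measured in the planes
   orthogonal to the final tangents, reported against arclength in mm.
4. **Shrinkage analysis** — two profiles (e.g. formalin-fixed vs.
   paraffin-embedded) are aligned by cross-correlation and compared as
   shrinkage% = 100·(1 − A_after/A_before) per station.
5. **Joint-histogram modality comparison** — bivariate histograms of two
   registered volumes and multi-Gaussian decompositions of the
   marginals, including the σ = 2 Gaussian prefilter that makes
   overlapping tissue-class peaks separable.

A phantom generator (bent tubes, swellings, constrictions, bifurcation
appendages, two-modality tissue volumes) provides exact analytic ground
truth, so every stage is testable without any measured dataset.

## Worked example

A cylinder of radius 10 voxels tilted 30° from the z-axis
(`examples/02_oblique_cylinder_area.py`):

```
true orthogonal area  : 314.2 voxel^2
pipeline profile area : 310.7 voxel^2
naive per-z-slice area: 358.0 voxel^2
inflation ratio       : 1.1522  (1/cos30 = 1.1547)
```

The per-z-slice count carries the full 15 % obliquity error; the
centerline-orthogonal profile recovers π r² to about 1 %.

On the bifurcation phantom (`examples/03_bifurcation_convergence.py`)
the side appendage drags the initial centerline 3.3 voxels off the
parent axis; the relaxation removes the bulge and converges once the
residual drops below μ:

```
iteration 0: max deviation from parent axis 3.35 voxel  (initialization)
iteration 1: max deviation from parent axis 1.33 voxel,  residual 0.434
iteration 2: max deviation from parent axis 0.73 voxel,  residual 0.185
converged: True
```

The other scripts in `examples/` cover the straight-tube termination
contract, segmental shrinkage recovery (15/35/65 % within 1.5 points
after automatic 0.5 mm alignment), and the joint-histogram stack.

## Command line

```bash
lumenline phantom --preset swelling-benchmark -o ph/
lumenline segment vol.tif --seeds 32,32,40 --tolerance 0.3 --median 15 -o mask.tif
lumenline centerline ph/mask.tif --beta 0.5 --sigma 20 --mu 0.3 -o cl/
lumenline profile ph/mask.tif --centerline cl/ --voxel-length 1.3 -o profile.csv
lumenline shrinkage before.csv after.csv -o shrink.csv
lumenline jointhist A.tif B.tif --bins 256 --prefilter-a 2 -o hist/
lumenline run config.yaml
```

Exit codes: 0 success, 2 configuration error, 3 stage failure. `run`
executes a YAML-configured pipeline and writes a manifest with content
hashes of every output.

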