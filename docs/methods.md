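# Methods

## Model and assumptions

The segmenter assumes a piecewise-near-constant image: regions are
characterized by homogeneous intensity separated by step edges, and every
1D profile through the image inherits that structure.  The central object
is the 1D local center of mass

    C_n = Σ_m w_{m,n} m / Σ_m w_{m,n},   w_{m,n} = exp(−|D_m − D_n|),
    D_n = α Σ_{i=1..n} |f_{i+1} − f_i|^p,   f_{N+1} := f_N,

which maps every sample to (approximately) the centroid of its interval.
Two properties make it usable as a clustering primitive: the centroid of a
1D interval always lies inside the interval, so it is a reference point
unique to that interval, and the whole profile `C` is computable in O(N).
Segmentation in 2D/3D never computes a true 2D/3D center of mass (which may
fall outside a non-convex region); it aggregates 1D CMs along many
orientations instead.

Label propagation then treats the per-pixel CM candidates as a directed
graph and runs two regimes of synchronous updates over it: a stochastic
copy phase that breaks the symmetry of the all-unique initial labeling and
coarsens the partition quickly, and a deterministic mode phase that
consolidates to a fixed point.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `alpha` | edge sensitivity (dimensionless, scales the squared step per unit contrast) | — (must be chosen) | `alpha·|step|^p` is the edge mass of one step; values ≥ ~50 fully isolate an interval, but noise accumulates as `alpha·E|Δnoise|^p` per sample, so noisy images need moderate values. `alpha = 20` works well for unit-contrast images normalized to [0, 1] with noise σ ≈ 0.05. |
| `p` | exponent on absolute differences | 2 | 1, 2, 3 all supported; 2 is the recommended setting. |
| `shifted` | edge-integral convention (see below) | `False` | segmentation settings in this repo use `True`. |
| `angular_resolution` | orientation spacing, degrees | 10 | 2D: K = round(180/r) exactly. 3D: calibrated spiral sampling (K = 177 at 10°, 43 at 20°). |
| `phase1_iterations` (`t`) | stochastic copy iterations | 200 | too small leaves the partition fragmented (especially in non-convex regions); 300 suffices for the benchmark phantoms. |
| `max_iterations` | total cap | 1000 | phase 2 typically fixes within 10–40 iterations after phase 1. |
| `seed` | one seed for all randomness | 0 | consumed in fixed order: candidate thinning → initialization → phase-1 draws; runs are bit-reproducible. |
| `normalization` | `minmax` / `stddev` / `none` | `minmax` | `stddev` divides by the image SD then rescales the maximum to 1 (single-image reading of a cohort-level rule). |

## Edge-integral convention

With `D_n` summing differences up to `i = n`, the edge between samples `n`
and `n + 1` is already inside `D_n`, so the last sample of a flat run
*left* of a strong edge is grouped with the right-hand interval
(`[0,0,0,1,1,1]` at `alpha = 100` yields `C = [1.5, 1.5, 4.5, 4.5, 4.5,
4.5]`).  The `shifted=True` variant sums to `i = n − 1` and groups every
sample with its own side.  The default (`shifted=False`) keeps the
conventional form; for image segmentation, however, the unshifted form
gives *every* boundary pixel a CM across the edge (a systematic one-pixel
shell around every region), and these shell pixels act as conduits through
which labels leak between regions — on the 48³ two-ellipsoid benchmark the
mean Dice drops from 1.00 (shifted) to ≈ 0.6–0.8 (unshifted).  All
documented segmentation settings therefore use `shifted=True`.

## Numerical choices

- **Overflow-safe recursion.**  The split sums `Σ e^{±D_m}(…)` overflow for
  large `alpha`.  The implementation uses shift-invariant recursions over
  ratios `e^{D_n − D_{n+1}} ≤ 1` (forward `P, Q`, backward `S, T`;
  `C = (P+S)/(Q+T)`), algebraically identical but with every exponent
  non-positive.  Verified against the brute-force double sum to ≤ 1e−8 per
  sample over 200 random draws with `alpha` up to 5000, and finite up to
  `alpha = 1e6`.
- **CM snapping.**  The real-valued line CM is snapped to the nearest line
  sample; ties at .5 break toward the lower index.
- **Digital lines.**  Per orientation the grid is sheared along the driving
  axis (largest direction component) with nearest-integer cross-axis
  offsets: disjoint lines of Chebyshev-adjacent pixels that partition the
  grid exactly, so each pixel is processed once per orientation and the
  O(KN) bound holds.  Sample spacing along a line is treated as 1; the
  candidate distance `d_k` is measured in true Euclidean pixel units.
- **Hemisphere sampling.**  Deterministic Fibonacci-spiral points on the
  upper hemisphere with a small equatorial margin (a quarter of the nominal
  resolution) so that no two orientations are near-antipodal; the point
  count is calibrated by fixed-point iteration so the mean nearest-neighbor
  angle matches the requested resolution.
- **Mode tie-breaking.**  Ties prefer the pixel's current label when it is
  among the tied modes, otherwise the label held by the lowest-indexed tied
  candidate pixel.  Both rules are position-based, so phase 2 is
  deterministic *and* equivariant under relabeling (a value-based rule such
  as "smallest label" would make the final partition depend on the initial
  label permutation).
- **Termination.**  Synchronous mode dynamics can sustain period-2 orbits
  (a handful of mutually referencing pixels swapping labels forever).  The
  loop detects `L_t = L_{t−2} ≠ L_{t−1}` and re-updates just the cycling
  pixels sequentially with the same mode rule until quiet, then resumes
  synchronous iteration; convergence is only ever declared when a full
  synchronous step changes nothing, so a reported fixed point is a genuine
  fixed point.  If the resolver cannot settle the orbit the run honestly
  reports `converged=False` at the cap.
- **Degenerate inputs.**  Constant images normalize to all zeros (with a
  warning) and segment into orientation-symmetric central-candidate
  partitions; single-sample signals return `C = [1]`; `alpha = 0` is
  rejected by the public validator but the internal recursion handles it
  (global-centroid limit `C_n = (N+1)/2`).

## Synthetic benchmarks

The phantom generators produce piecewise-constant geometry (disks,
rectangles, C-shapes in 2D; ellipsoids, boxes in 3D) on a constant
background with additive i.i.d. Gaussian noise, plus ground-truth label
maps.  The benchmark conditions are: 128×128 with two disks, contrast 1,
noise σ = 0.05 (2D); 48³ with two ellipsoids, same contrast and noise (3D).
Documented segmentation settings for both: `alpha = 20`, `p = 2`,
`shifted=True`, `t = 300`, cap 600 (2D, resolution 2°) or 900 (3D,
resolution 20°).  Under these settings the mean Dice over the foreground
regions (background excluded) is 1.00 across all tested seeds, with
phase 2 reaching a fixed point around iteration 310–340.

What the phantoms do *not* emulate: textured or shaded regions, smooth
intensity gradients, partial-volume edges, spatially correlated or Rician
noise, and anisotropic voxels.  Passing these benchmarks demonstrates the
correctness of the machinery (CM computation, candidate construction,
propagation, evaluation) and robustness to moderate additive noise — not
clinical-grade accuracy on real MR data, where intensity inhomogeneity and
weak boundaries make the problem far harder.

## Known limitations

- Highly non-convex regions may converge to an over-segmented local
  optimum; more phase-1 iterations alleviate but do not guarantee escape.
- `alpha` and `t` are manual; no automatic selection is provided.
- Distances assume isotropic pixels/voxels; anisotropic volumes should be
  resampled beforehand (the reader warns but proceeds).
- Runtime is dominated by the per-orientation CM field at large K and by
  phase-2 mode computation on large candidate pools.
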