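# Methods

`qdaseg` segments brain tumors in single-channel 3D MRI slice-by-slice in
three phases: morphological preprocessing, intensity clustering refined by
a quantum-inspired dragonfly swarm, and a geodesic level-set evolution
that turns the tumor-cluster boundary into the final contour.  A seeded
synthetic phantom supplies ground truth for every stage.

## Preprocessing

Each axial slice goes through three steps, in order.

**Skull stripping.**  Otsu's threshold (computed exactly over the value
histogram, maximizing between-class variance over all cuts between
consecutive distinct intensities) binarizes the slice.  The foreground is
eroded with a disk of radius `morph_radius` (default 3 px) to detach
brain tissue from the bright skull/scalp rim, the largest connected
component is kept, dilated back, and interior holes are filled.  The
result is a single simply-connected brain mask; slices with no usable
foreground (volume extremes) are flagged and passed through empty rather
than raising.

**Anisotropic diffusion.**  Perona–Malik explicit scheme, 4-neighbour
fluxes, exponential conductance `c(g) = exp(-(g/kappa)^2)` with
`kappa = 30` on an 8-bit scale, step weight `lam = 0.14` (within the 2D
stability bound `lam <= 0.25`), 10 iterations, replicated boundaries.
Constant images are exact fixed points and the discrete max principle
holds.

**Histogram equalization.**  Classic CDF equalization computed from, and
applied to, brain-mask pixels only (background zeros would dominate the
CDF), mapped onto [0, 255]; out-of-mask pixels are untouched and the
mapping is monotone.

A deliberate design point: the *clustering and level-set stages consume
the diffused slice, not the equalized one*.  Global equalization by
construction flattens the histogram — each tissue's output band is
proportional to its pixel mass — so the narrow white-matter/tumor gap
(which carries almost no mass) collapses, making a small tumor mode
unrecoverable by K=4 clustering and drowning the edge indicator in
amplified noise gradients.  The equalized slice is kept as the
display-contrast product.

## Clustering: k-means seed + quantum dragonfly refinement

K = 4 clusters stand in for CSF/background, grey matter, white matter and
tumor.  K-means runs on the brain-mask intensities with Lloyd iteration
(mean updates, Euclidean assignment with ties to the lowest index,
farthest-pixel empty-cluster repair).  Seeding is deterministic: the
globally optimal 1D weighted k-means over the distinct intensity levels
(binned to at most 512 levels), computed by dynamic programming over
contiguous partitions.  Those seeds are a Lloyd fixed point, so on small
inputs the procedure returns the exhaustive-partition optimum; on pixel
data Lloyd refines the binned solution.  The squared-error energy is
asserted non-increasing at every step; the reported `objective` is the
within-cluster absolute-distance sum (intensity units).

The dragonfly swarm then refines the centroid vector.  Each of the `N =
20` agents carries the full K-vector of candidate centroids; the scalar
update equations apply coordinate-wise.  Per iteration, an agent with
neighbors (Euclidean ball whose radius grows linearly from a quarter of
the intensity range to the full range) combines separation, alignment,
cohesion, food attraction and enemy distraction, each weighted by the
canonical adaptive schedule (random per-iteration scaling decaying over
the run; inertia weight annealed 0.9 → 0.4).  Cohesion is implemented as
attraction to the neighborhood center, `mean(X_j) - X_i`; the repulsive
sign that appears in some statements of the operator is available behind
`printed_cohesion_sign`.  The enemy operator is `X_enemy + X_i` as
printed in the original formulation.

**Quantum computing mechanism (QCM).**  Two Newtonian behaviors are
replaced by a qubit encoding: a value `x` in `[lo, hi]` is quantized to
`q = (2x - (hi+lo))/(hi-lo)` in [-1, 1], mapped to the amplitude pair
`beta = sin(pi (q+1)/4)`, `alpha = sqrt(1 - beta^2)` (a smooth bijection
between the scalar and a unit-norm pair, required because the gate
rotates amplitudes while the update needs a scalar), rotated by the 2×2
rotation gate, and dequantized by the exact inverse.  The gate angle
magnitude is `theta = 0.02*pi`; its sign points the rotated amplitude
toward the food (best-so-far) solution's quantized value.  The inertia
term passes the previous step through this quantize–rotate–dequantize
chain before multiplication by the inertia weight, so a zero angle
reduces exactly to the plain inertia update.  Neighborless agents take
the QCM Lévy update: rotate the quantized *position*, dequantize, then
add a Mantegna Lévy step (`beta = 1.5`, 0.01 scaling) times the position,
clamped to bounds.

Gaussian mutation (`x' = x (1 + k r)`, `k = 1`, per-agent probability
0.1) is accepted greedily — a mutant replaces its parent only when
fitness improves — preserving the monotone best-fitness trace.  The food
position is elitist (never worsens); the enemy is the current worst.

**Fitness.**  Operationally (no ground truth at segmentation time) the
fitness of a centroid vector is the mean absolute quantization error of
the pixels against their nearest candidate centroid, normalized by the
intensity range — a rate in [0, 1], lower is better.  A supervised mode
computes MAPE between actual classes and the 1-based ascending-centroid
cluster index (instances with class 0 are excluded); it exists for
validation on labeled phantoms only.

The loop stops after `T = 100` iterations or when the best fitness
improves by less than 1e-6 over 15 iterations.  Since the swarm is seeded
with the k-means solution and updates are elitist, the final fitness
never exceeds the seed's.

**Tumor candidacy.**  The tumor cluster defaults to the brightest
centroid (contrast-enhanced appearance); an outlier rule (farthest from
the brain mean) is available.  Two rules decide that a slice has *no*
tumor, a question the segmentation-time pipeline must answer per slice:
(i) the tumor centroid must be separated from its nearest neighbor
centroid by at least `min_separation = 5` pooled within-cluster standard
deviations — a quantile split of a single noise mode produces gaps of
only ~1–3 sd, a genuinely distinct hyperintense population far more; and
(ii) candidate connected components must lie between `min_area = 20` px
(clustering speckle) and `max_area_fraction = 0.08` of the brain mask (on
tumor-free slices the brightest cluster degenerates to a whole
normal-tissue class, which dwarfs a plausible whole-tumor cross-section
at this slice resolution; the bound is configurable for unusually large
lesions).  Multiple surviving lumps are all retained.

## Contour initialization and level-set evolution

The cleaned tumor mask is converted to a signed distance field phi
(negative inside, exact Euclidean distance transform; the zero level set
lies on the mask boundary).  Ordered boundary points are available via
Moore-neighbor tracing, including inner boundaries around holes.

The evolution is the explicit geodesic active-contour update

    phi <- phi + dt [ g (Wc kappa + Wa nu) |grad phi| + grad g . grad phi ]

with edge indicator `g = 1/(1 + |grad(G_sigma * I)|^2)` (`sigma = 1.5`
px), curvature `kappa = div(grad phi / |grad phi|)` by central
differences (1e-8 norm guard), the balloon term upwinded on the sign of
the speed, and the edge-attraction term `grad g . grad phi` upwinded
componentwise (the characteristics of `phi_t = v . grad phi` travel
along `-v`, so a positive velocity component takes the forward
difference).  Under the inside-negative convention a *positive* balloon
speed raises phi and therefore shrinks the contour; the default `nu =
+0.3` pulls the initialization onto the tumor edge, and the attraction
term holds it on the `g` minimum.  Dropping the attraction term
(`include_advection_term=False`) yields the pure balloon–curvature flow.

The time step defaults to the stability value `dt = 1/(6 Wa Wc)`,
overridable.  Every `reinit_every = 80` iterations phi is rebuilt as a
signed distance to its *interpolated* zero contour: marching squares
locates the contour with subpixel accuracy and distances are taken to a
midpoint-densified polyline.  A mask-based reinitialization would snap
the contour to the pixel grid and erase any motion slower than half a
pixel per reinit interval; the subpixel variant keeps the scheme within
2% of the analytic curvature-flow radius law r(t) = sqrt(r0^2 - 2t) on a
radius-30 circle down to r = 10 at default settings.  Reinitializing
much more often accumulates the chord-inscription bias of the polyline
(O(kappa h^2 / 8) per reinit), which is why the interval is 80 rather
than a conventional 10–20.  Convergence is declared when fewer than 0.1%
of inside pixels change over a 10-iteration window; `max_iters = 1000`.

The initialization is trusted as-is (`init_dilation = 0`): the cluster
boundary on well-separated data already sits on the intensity edge, and
a dilated contour parks in the blurred edge zone where `g` is small and
refuses to shrink back.  Dilation remains available when an
outside-in approach is wanted.  After evolution, components smaller than
`min_area` (residue the flow shrank below lesion size) are removed and
the mask is intersected with the brain mask.

## Evaluation metrics

Voxelwise confusion counts give accuracy, recall, precision, specificity
and Dice; zero-denominator rates are reported as undefined (None with a
flag), never as 0.  Accuracy may be restricted to a domain mask (e.g.
brain only) since whole-volume accuracy is inflated by background true
negatives.  HD95 extracts the 4-connected boundary voxels of both masks,
takes directed nearest-neighbor distances both ways (scaled by voxel
spacing when available), and combines the two 95th percentiles (linear
interpolation) by max.

## Synthetic phantom

A concentric-ellipsoid head model on a (240, 240, 155) grid by default
(axes 0.42/0.42/0.46 of the volume extent): a skull shell (normalized
radius 0.92–1), CSF layer (0.80–0.92), grey ring (0.62–0.80) and white
core.  Tissue means 0/40/100/150/230/210 (background/CSF/grey/white/
skull/tumor) with sds 2/5/6/6/7/8 on an 8-bit scale — a hyperintense
tumor consistent with contrast-enhanced imaging, validated at
construction to lie outside ±2 sd of every other tissue.  Tumors are
star-convex lumps (smooth low-order radial perturbation of an ellipsoid
sharing the head's z-anisotropy, irregularity amplitude 0.3) placed
wholly inside white matter without mutual overlap (bounded retries,
`PlacementError` otherwise); radii default to 12–18 px in-plane, the
1.2–3.6 cm whole-tumor diameters typical of clinical volumes.  Voxel
intensity is `(mean + sd·g1) · (1 + a·B) + noise_sd·g2` with `B` a
separable low-frequency cosine field in [-1, 1] (`a = 0.1` emulating
coil inhomogeneity at a scale diffusion does not remove) and `noise_sd =
6`.  Everything is deterministic given the seed.

What the phantom does *not* emulate: Rician noise statistics, partial
volume effects, k-space/motion artifacts, multi-modal contrasts, and
anatomically realistic cortical folding.  Passing tests therefore
demonstrate correctness of the pipeline mechanics and robustness to
Gaussian noise and smooth bias — not clinical-grade performance on real
scans.

## Reproducibility and problem sizes

All randomness flows from `numpy.random.default_rng` seeds; the pipeline
derives per-slice seeds from `SeedSequence((global_seed, slice_index))`,
so identical config + seed give bit-identical segmentation volumes.  The
test suite and the acceptance script exercise end-to-end segmentation on
240×240×20 phantom volumes (the full in-plane acquisition grid with a
20-slice window around the tumor), mixture recovery on 8 000-point
4-component mixtures over 10 seeds, and the curvature-flow law on a
101×101 grid — sizes chosen so the whole suite completes in a couple of
minutes on one CPU while keeping every quantity at the full per-slice
problem size.

## Known limitations

- Whole-tumor (single-class) segmentation only; no sub-region labeling.
- Slice-wise independence: no 3D regularization across slices (an
  optional warm start seeds slice k's swarm from slice k−1's centroids).
- The tumor-candidacy rules assume a hyperintense, reasonably compact
  lesion; very large (>8% of brain cross-section) or hypointense tumors
  need `max_area_fraction` / `tumor_strategy` adjustments.
- The area/separation gates and the brightest-cluster rule were designed
  for single-channel contrast-like intensities; multi-modal fusion is out
  of scope.
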