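# Methods

This note records the models implemented in `microcalc`, the parameters
that matter, the design choices made where the method description left
the design open, and what the synthetic studies do and do not show.

## Coordinate and intensity conventions

All stages work on 0-based (row, col) grids with row 0 at the top.
Mini-MIAS ground truth, whose y origin is at the bottom-left, is
converted once at parse time (`row = H − 1 − y`) and never again.  The
truth circle is inclusive: centroid distance ≤ radius counts as inside.
Images are non-negative 2-D grids; 8/16-bit integer rasters keep their
dtype through read/write round trips.  The default physical scale is
0.07 mm per pixel; every pixel-denominated default below refers to that
scale and should be rescaled for other digitisations.

## The three-region form filter

The filter is built from the negated Laplacian of Gaussian; the value at
offset (x, y) is

    log_value(x, y, σ) = -(1/πσ²) · ((x²+y²−2σ²)/(2σ⁴)) · exp(−(x²+y²)/(2σ²)),

positive at the origin with zero crossing on r² = 2σ².  The kernel has

* **region 1** (r < R1): the LoG values themselves.  σ defaults to
  R1/√2, so the positive lobe exactly spans the core.  This tie is a
  design choice — the method calls for a core "with the shape of the
  positive part" of the LoG sized to the smallest micro, without fixing
  σ numerically.
* **region 2** (R1 ≤ r ≤ R2): exactly zero.
* **region 3** (r > R2): α · log_value(r − ΔR), i.e. the negative tail
  translated **radially** outward by ΔR = R2 − R1.  A Cartesian shift
  would destroy rotational symmetry; the radial reading keeps the
  kernel a function of r only.  α is computed on the discrete grid as
  (sum of core weights)/(−sum of raw tail values), which makes the
  null-sum condition exact up to float rounding.  Because the
  translation spreads the tail over longer circumferences, α < 1.

Default geometry from the micro size range (0.1–1.0 mm diameters):
R1 = round(0.15 mm / spacing) and R2 = round(0.5 mm / spacing), i.e.
2 px and 7 px at 0.07 mm.  The kernel halfwidth defaults to
⌈R2 + 3σ⌉, enough for the translated tail to decay inside the kernel.
Convolution uses reflect padding (no spurious border response at the
breast edge).  The scale-tolerance property — peak response constant
within 10% for disks with radius in [R1, R2] — holds *exactly* for
centred disks, since such a disk covers the whole positive core and
otherwise only null-annulus pixels.

Segmentation thresholds are not part of the published design; the
default is the 99.7% quantile of the in-mask response (intensity-scale
invariant), with absolute and z-score modes available.  Components use
8-connectivity and an area band [1, 400] px by default.  The breast
mask for real images is Otsu thresholding + largest connected component
+ hole filling — a standard stand-in, isolated behind one function,
since the original system's breast delimitation is undocumented.

## Features and normalization

Nine features per object, in fixed column order: x, y, area, perimeter,
eccentricity, mean, standard deviation, skewness and kurtosis of the
pixel intensities.

* Perimeter is the crack length: the count of exposed 4-neighbour pixel
  edges.  Deterministic, integer, and consistent across resolutions.
* Eccentricity comes from the second central moments of the pixel
  positions with each pixel treated as a unit square (adding 1/12 to
  both diagonal moments).  This keeps the value strictly below 1 for
  one-pixel-wide bars and exactly 0 for symmetric shapes.
* Intensity skewness and kurtosis use the population-moment forms
  m₃/m₂^1.5 and m₄/m₂² (kurtosis not excess).  Zero-variance objects
  get std = skew = kurt = 0, keeping degenerate candidates neutral.

Normalization maps each feature through (x − min)/(max − min) with
min, max = mean ∓ 4σ, where mean and σ (ddof = 1) are computed over the
objects of the image being clustered — per-image normalization, since
no global training population exists.  Values beyond the ±4σ window
(possible for outliers) are clipped to [0, 1]; a constant feature
(σ = 0) maps to 0.5 for every object.  The same rule is applied to all
nine components, including x and y.

## Fuzzy c-means (FCM and FCM-WF)

Both variants minimise J_m = Σᵢⱼ uᵢⱼ^m ‖Xᵢ − Cⱼ‖² with Euclidean
distance in the normalized space, all components equally weighted.
`spatial_only` restricts to (x, y); `with_features` uses all nine.
Defaults: fuzzifier m = 2 (the conventional choice; the method leaves m
open), relative objective tolerance 1e−5, 300 iterations max.  The
initial membership matrix is row-wise uniform on the K-simplex from a
seeded generator; "reaching the absolute minimum" is read as
convergence of the alternating scheme (a local minimum), since the
K-search loop itself treats runs as seed-dependent.  A point coinciding
with centroids splits its membership equally over them; a dead centroid
(zero membership column) is re-seeded at a random data point.
Defuzzification is argmax with ties to the lowest cluster index.

## Cluster-count estimation

Constraints: a pathological cluster has ≥ 3 micros (`min_micros`) and
extent ≤ 250 px at 0.07 mm (`max_extent_px`, rescaled by 0.07/spacing
otherwise).  Extent is the maximum pairwise centroid distance in raw
pixel coordinates.  One round runs the clustering `n_loop` = 50 times
at the current K_ini; each run is defuzzified and scored
W = K_ini − N_down + N_up, counting every requested cluster with fewer
than 3 members (including empty ones) in N_down and every oversized
kept cluster in N_up.  Oversized clusters are flagged, not split — the
raised K_ini of the next round is what resolves them.  The 3σ rejection
is applied once per round.  Stop when |W̄ − K_ini| < 3σ_W (read as
W̄ = K_ini when σ_W = 0, since a strict inequality against zero never
fires); otherwise restart from K_ini = ⌈W̄ + 3σ_W⌉.  Rounding: floor
for N/3, ceil for the restart, half-up for the final K = round(W̄).
Two guards protect termination: the restart value is capped strictly
below the current K_ini (the Eq-4 count can otherwise oscillate), and
the search stops after 20 rounds returning the best estimate so far
with `converged=False`.

**Resolving power.**  The only signal that drives K downward is
undersized defuzzified clusters.  An isolated blob of six or more
points supports a stable fuzzy split into two ≥ 3-member halves, which
the pruning rule cannot distinguish from two genuine clusters; the
count search therefore resolves the exact cluster number only when
clusters hold ≤ 5 micros (an even split then violates the 3-micro
minimum).  The count-recovery studies use 5-micro clusters for this
reason.  They also run the estimator in `spatial_only` mode: the
residual-cluster rules are purely spatial, and on small objects
(~13 px) the sampling noise of skewness/kurtosis dilutes spatial
compactness enough to misdirect an occasional 9-D run.  On full
pipeline images (with noise candidates present) the estimator runs in
the 9-D mode and the final count includes the healthy residual
clusters, as it should.

## Injection simulator

The simulator stands in for the unavailable clinical image sets; its
defaults are one-time choices of realistic values at 0.07 mm scale.

* **Background**: band-limited Gaussian noise blurred at
  `texture_scale_px` = 40 and scaled to amplitude 8, plus white grain of
  sd 2, around base level 120 (8-bit scale); the breast mask is a half
  ellipse anchored to the left edge covering ≈ 60% of the frame.
* **Mother cluster**: M ≥ 4 disk-like micros, radii uniform on
  [1, 3] px, centres Gaussian with spread 30 px kept ≥ 10 px apart
  (distinct spots), per-pixel elevations uniform on [20, 60].
* **Injection**: micros are drawn without replacement; the first is
  stamped at a random in-mask anchor and each next one at the position
  preserving its displacement (angle and distance) from the previously
  placed micro, so the injected subset is a rigid translate of the
  template subset.  n is uniform on [P, M] with P = half-up
  round(0.8·M).  Elevations get a single multiplicative rescale so the
  injected mean elevation equals the template's, times the
  local-to-global background brightness ratio (intensity matched to the
  surrounding parenchyma).  Placements leaving the mask are redrawn up
  to a retry cap.

What the simulator does **not** reproduce: real parenchymal texture
(ducts, vasculature, pectoral muscle), film digitisation artefacts,
non-disk micro morphologies, and the intensity statistics of biopsied
lesions.  Passing tests on these images show the pipeline's mechanics —
scale-tolerant detection, feature-based separation, count estimation —
not clinical performance; detection metrics measured here do not
transfer to hospital data.

## Evaluation

Ground truth is either the exact injected positions (objects matched
greedily one-to-one within 2 px — the images carry exact coordinates,
so the tolerance only absorbs centroid discretisation) or a MIAS-style
circle (every in-circle object is truth).  The predicted cluster
containing the most true micros is the reconstruction, ties broken by
fewer noise members; TP/FP/FN/TN are counted at object granularity and
feed sensitivity = TP/(TP+FN), accuracy = (TP+TN)/total,
FP-per-image = FP/(all segmented objects) and precision = TP/(TP+FP),
with zero-denominator cases reported as undefined.  The paired harness
runs both clustering spaces at the same K and seed on the same scene
and reports both merit figures.  One true cluster per image is assumed
(the simulator injects one); multi-truth images are evaluated one
circle at a time.

## Study sizes

The synthetic studies are sized to run in seconds while keeping the
statistics meaningful: 30 paired-merit scenes, 10 seeds per cluster
count in {1, 2, 3} (with a second start point at N/4 for the
start-independence check), 200 draws per template size for the
injection count rule, and a 6-image batch of 512×512 simulated
mammograms for the full-pipeline metrics.

## Known limitations

* The count estimator's exact-recovery regime is small clusters (see
  above); for larger clusters it over-counts by reporting stable
  sub-clusters, a property of the residual-count rule itself.
* Per-image normalization makes features incomparable across images;
  this mirrors the method but precludes pooled training.
* The MIAS circle-as-truth convention makes in-circle noise objects
  indistinguishable from true micros, inflating apparent sensitivity on
  such data.
* The breast mask is a generic intensity-based stand-in and will fail
  on images where the background is not darker than tissue.
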