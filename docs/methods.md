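# Methods

This note documents the models, conventions and numerical choices behind
`lacuna3d`, what the synthetic phantoms do and do not emulate, and the known
limitations of the procedure.

## The quantification procedure

**Segmentation.** One global threshold per volume: the exact arithmetic
mean of all voxel intensities (float64 accumulation). Voids are voxels
*strictly below* the threshold — mineralized matrix is X-ray attenuating
and therefore bright, voids dark; the strict inequality makes a constant
volume yield no voids. The threshold is computed over the full volume,
which presumes a bone-filled field of view; an optional restriction mask
exists for volumes containing exterior air. Histogram-based "mean"
auto-thresholds in interactive tools iterate on a quantized (8-bit)
histogram and may differ from the exact voxel mean by a fraction of a gray
level on quantized data. A fixed numeric threshold can be supplied instead
(the "one shared threshold for all samples" protocol); every run report
records which was used.

**Labeling.** 6-connectivity (face adjacency) only; 18/26-connectivity
would merge diagonally touching objects and inflate per-object volumes,
making counts incomparable across tools. Components touching the volume
border are retained by default (no border exclusion is part of the
counting procedure; an `exclude_border` option exists and is recorded in
the report when used — note that retaining border objects slightly
overcounts objects truncated by the field of view). Labels are
canonicalized to first-voxel raster order so identical masks always
produce identical label maps.

**Volume windows.** Counting keeps labels with volume in [10, 2000] μm³,
morphometry in [20, 2000] μm³. Bounds are inclusive on both sides; the
source protocol says "between" without specifying open/closed, and the
phantom generator deliberately avoids planting objects at the bounds so
the choice is not load-bearing in validation. Object volume is voxel count
times voxel volume (no meshing), which keeps the conservation identity
Σ_labels V = V_void exact.

**Concentration.** Retained labels per mm³ of analyzed volume. The
denominator is the full scan volume by default; a segmented-bone-volume
denominator is available (`mean_threshold(within=...)` machinery) for
fields of view that are not bone-filled. For the study-like scans the two
coincide to within the void fraction (~1–2%).

**Feret morphometry.** Geometry is computed on the component's *cell
corner* cloud: each surface voxel (a void voxel with at least one
6-neighbor outside the component) contributes the 8 corners of its cell in
physical μm. Calipers therefore measure the extent of occupied cells, a
single voxel has nonzero extent, and interior voxels can be dropped
without changing the convex hull. F_max is the exact maximum pairwise
distance over convex-hull vertices (ties broken toward the
lexicographically smallest vertex pair, so the axis is deterministic).
F_min⊥ projects the cloud onto the plane orthogonal to the achieved F_max
direction and takes the rotating-calipers minimum width of the projected
hull (exact for convex polygons: the minimum width is attained with one
edge flush). Degenerate projections (collinear, e.g. a one-voxel-wide rod)
are guarded to one voxel edge length so ψ_A = F_min⊥/F_max stays in
(0, 1]. For a single voxel this convention gives F_max = √3·s and
F_min⊥ = √2·s (the width of the cube's hexagonal shadow), hence
ψ_A = √(2/3) ≈ 0.816. An alternative reading of "minimum Feret" — the
global minimum caliper over all 3D directions, not restricted to the
orthogonal plane — is available (`min_feret_mode="global3d"`, a
Fibonacci-sphere scan) and recorded in output metadata when used.

Corner-cloud calipers are validated against an independent 1° angular
brute-force scan; the observed gap is below 0.3% of F_max (tolerance set
at 1%, the scan's own grid error being of order (Δθ)·F_max at width-curve
kinks).

## The phantom generator

Phantoms emulate the statistical structure of duplicate micro-CT scans of
four bone types, at ~0.85–1 μm voxels and ~10⁻³–10⁻² mm³ desk-scale
domains:

| preset | concentration /mm³ | mean volume μm³ (SD) | mean ψ_A (SD) |
|--------|-------------------:|---------------------:|--------------:|
| `ip` (inner petrous) | 95,000 | 130 (100) | 0.46 (0.11) |
| `op` (outer petrous) | 55,000 | 280 (190) | 0.46 (0.11) |
| `t` (mastoid)        | 28,000 | 190 (170) | 0.47 (0.11) |
| `f` (femur)          | 27,000 | 130 (90)  | 0.37 (0.10) |

Concentrations and shape statistics follow the published per-sample scale
for these bone types; the `ip`:`f` ratio 95/27 ≈ 3.5 reproduces the
"about three-fold" petrous-vs-femur regime.

**Lacunae.** Ellipsoids. Volumes are log-normal (right-skewed, as observed
volume histograms are) truncated by rejection to 20–2000 μm³; the
log-normal is a modeling choice — no distributional fit is published.
Aspect ratios c/a are normal, truncated to (0, 1]. The middle semi-axis is
b = c + u·(a−c) with u ~ U(0,1): tri-axial proportions beyond c/a are
unconstrained by any published measurement, so this is an explicit
modeling choice. Orientations are uniform on SO(3); centers uniform with
rejection.

**Packing guarantees.** Accepted ellipsoids keep their bounding spheres
disjoint with a 2-voxel separation margin, stay one voxel clear of the
domain border, and keep (canal radius + a + margin) clearance from canal
axes. Additionally, each candidate is *digitization-validated*: rasterized
alone on the target lattice it must form a single nonempty 6-connected
component with voxel volume strictly inside (10, 2000) μm³; failing
candidates are re-placed (sub-voxel position changes the digitization),
re-oriented, and eventually re-drawn. Without this validation, thin
ellipsoids near the 20 μm³ floor can digitize to fewer than 10 voxels at
1 μm spacing or fragment into 6-disconnected pieces, and planted count
would no longer equal recovered count on a clean phantom. With it, count
recovery is an exact (integer) test. Packing aborts with the achieved
count after a bounded number of rejections.

**Canals.** Straight cylinders spanning the domain along x, radius 4 μm by
default, each > 2000 μm³ by construction (validated at construction time)
so the upper cutoff must reject them. Real vascular canals branch and
curve; nothing downstream depends on that.

**Rasterization.** A voxel is void iff its center (at (i+0.5)·s) lies
inside a planted body. The two-level clean grid (bone 200, void 0) makes
the mean threshold exact: the mean lies strictly between the levels, so
the recovered mask equals the planted mask voxel-for-voxel.

**Degradation.** Gaussian blur with physical-unit σ (converted per axis by
the spacing; reflective boundaries, so the global mean is preserved)
followed by additive zero-mean white Gaussian noise. This emulates the
contrast loss and noise of plastic-embedded scans, not full CT physics: no
beam hardening, ring artifacts, correlated reconstruction noise, or
partial-volume gray levels beyond the blur.

**What passing tests show.** Exact recovery on clean phantoms validates
the chain's bookkeeping (segmentation polarity, connectivity, windowing,
concentration arithmetic) — it does not validate segmentation against real
partial-volume boundaries, real lacuna shapes (which are not perfect
ellipsoids), canalicular connections between lacunae (below resolution
here), or real noise structure.

## Degradation robustness and the limits of mean thresholding

With blur of one voxel and white noise at one-fifth of the bone–void
contrast (contrast-to-noise ratio 5), the *mean* threshold fails
structurally on bone-filled volumes, and the package makes no attempt to
hide this. The mean sits below the bone level by f·C (void fraction times
contrast), i.e. by only f·CNR ≈ 0.08 noise-SDs at the study-like void
fraction f ≈ 0.016. The bone-voxel false-positive rate is then
Φ(−f·CNR) ≈ 48%, far above the ~31% site-percolation threshold of the
6-connected lattice: false-positive voxels form a spanning cluster that
absorbs the true lacunae and is rejected by the > 2000 μm³ cutoff. In 20
seeded replicates the mean-threshold pipeline recovers the planted
concentration within 10% in none of them. This is a property of mean
thresholding at low void fraction, not of the implementation; the
dedicated test asserting within-10% recovery under the mean threshold at
CNR 5 is expected to fail and documents the regime honestly. For the rate
Φ(−f·CNR) to drop low enough that spurious clusters stay below the 10 μm³
floor, f·CNR ≳ 1.7 is needed — CNR ≈ 100 at these void fractions.

Under the *shared fixed threshold* protocol (midpoint of the two levels),
the same degraded phantoms are recovered within 10% in 20/20 replicates
(median error ~4%, driven by blur pushing the smallest lacunae under the
10 μm³ floor). The analysis cohort therefore counts its degraded mastoid
replicates with the fixed threshold, and `scripts/acceptance.py` reports
both protocols side by side.

## Numerical choices and conventions

- Axis order (z, y, x), z = slice index; spacing (s_z, s_y, s_x) in μm;
  anisotropic spacing supported everywhere (all geometry in physical μm).
- Explicit spacing always overrides file metadata; volumes written by the
  package embed spacing in a JSON TIFF description tag.
- Sample SD uses the n−1 denominator; means/SDs over fewer than 2 records
  are NaN and the record count is reported alongside.
- Summary statistics (volume, ψ_A) are computed on the 20–2000 μm³ window.
- Histograms use half-open bins [e_i, e_{i+1}); values at or beyond the
  last edge are excluded (and conservation is tested including the
  out-of-range remainder).
- ψ_A recovery bias: at 0.5 μm voxels the mean measured ψ_A of a planted
  population exceeds the planted mean c/a by ≈ +0.03 (corner-cloud
  digitization inflates the thin axis relatively more); at 0.9–1 μm voxels
  the bias reaches ≈ +0.05. Population ψ_A comparisons across samples at
  equal spacing are unaffected; absolute comparisons should use spacing
  ≲ c/4.
- Validation problem sizes: clean-recovery phantoms use 200³ voxels at
  1 μm (0.008 mm³) and 150³ for group comparisons; these are desk-scale
  stand-ins for the ~0.4 mm³ study scans, chosen so hundreds of objects
  per volume keep sampling error on means below the tested tolerances.
  Full-scale scans (~8×10⁸ voxels) should be processed tiled; the labeling
  stage here treats each input volume as one connected domain.

## Known limitations

- Mean thresholding is only appropriate for bone-filled fields of view
  with good contrast-to-noise (see above); it is kept because it is the
  reproducible, parameter-free baseline the counting protocol specifies.
- Deep-learning segmentation variants are out of scope.
- The ellipsoid shape model cannot represent bean- or plate-shaped
  lacunae; ψ_A statistics transfer, higher-order shape descriptors do not.
- Border-touching objects are counted as whole objects (edge effect of
  order object-diameter / domain-size; ~2–4% at the validation scales).
- No hypothesis testing between groups is provided — the comparison
  deliverable is the fold-change table.
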