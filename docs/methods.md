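# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind `plstk`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Frames and rectification

Three frames appear in the chain:

* **instrument frame** — what the scanner records: origin at the optical
  centre, axes fixed to the tilted instrument;
* **rectified (local) frame** — origin still at the scanner, +Z up; obtained
  by the passive rotation `R = R_z(κ)·R_y(φ)·R_x(ω)` with right-handed axis
  rotations in degrees, default pose (ω, φ, κ) = (0, 60, 90). The ground
  surface then sits near z = −(mast height);
* **reference frame** — a projected CRS (EPSG:3067 where georeferenced),
  reached by the Helmert transform.

The Euler composition order `R_z·R_y·R_x` is a convention of this package;
it is validated by the physical constraint that the default pose rotates the
60°-tilted scene ground-horizontal (property-tested on synthetic scenes,
where ≥ 99 % of ground returns must land within ±1 m of z = −30 m).
Extraction of (pitch, roll, yaw) from a fitted rotation uses the same
convention; at gimbal lock (|φ| = 90°) κ is reported as 0 by convention and
the remaining angle absorbs the coupled degree of freedom.

Scan angles are derived **in the instrument frame** (range = ‖p‖, θ = polar
angle from +Z in [0°, 180°], φ_az = azimuth from +X toward +Y in [0°,
360°)): they describe instrument geometry, so deriving them after rotation
would entangle them with the pose. A point at the exact origin gets
(0, 0, 0) and a log warning. Ranges are rotation-invariant, which is
property-tested.

## Helmert georeferencing

The 7-parameter similarity `p' = t + μ R p` is fitted to n ≥ 3 non-collinear
control pairs in closed form: centroid alignment, orthogonal Procrustes via
SVD (with the determinant sign correction so det R = +1), and the ratio
scale `μ = Σᵢ sᵢ dᵢ / Σ‖Δsource‖²`. This attains the global optimum of the
squared-residual loss — identical to iterative linearization at
convergence — with no initialization. Collinearity is detected from the
second singular value of the cross-covariance. Fit quality is reported as
overall RMSE and per-axis RMSE of the target residuals. Under isotropic
Gaussian noise σ the expected fitted RMSE is below σ (7 parameters absorb
part of 3n residual dof); the Monte-Carlo check asserts the mean RMSE over
100 draws lies in [0.5σ, 2σ].

## Voxel resampling

Cells are half-open cubes `[i·s, (i+1)·s)` anchored at `floor(min)` of the
(filtered) cloud, so indices are deterministic and never negative for the
default origin. Per non-empty cell the retained point is the *input point*
nearest the centroid of the cell's points (never a synthetic position); ties
break to the lowest input index; output order is by retained-point input
index. Intensity/reflectance/deviation become per-cell arithmetic means;
return counters and geometric attributes keep the retained point's own
values. Consequences that the suite verifies: output count equals an
independent hash-of-floor-indices oracle, the operation is idempotent at a
fixed grid, every output coordinate exists in the input, and Σ(mean·count)
of averaged attributes equals the input sum to 1e-9 relative.

Noise thresholds (keep reflectance ≥ min, deviation ≤ max, both inclusive)
have no defaults: usable values depend on instrument and atmosphere, so the
thresholds are off until set explicitly, and setting one without the
corresponding attribute column is an error rather than a silent no-op.

## Stem detection

**Classification.** For each candidate point the neighbourhood covariance is
eigendecomposed; with sorted eigenvalues λ1 ≥ λ2 ≥ λ3, the point is a stem
point iff the neighbourhood has ≥ 5 points, linearity (λ1−λ2)/λ1 ≥ 0.6, and
the dominant eigenvector is within 15° of the local terrain normal (plane
fit to DTM support within 1 m; +Z shortcut on flat terrain).
Neighbourhoods are **multi-scale** (ball radii 0.5 m and 1.0 m, a point
qualifying at either): at ranges of tens of metres an angular grid samples a
stem as a few horizontal arc rows, and a 0.5 m ball can contain so few rows
that the dominant direction flips horizontal, while a 1.0 m ball alone
drags crown-base foliage into the neighbourhoods of short-stemmed spruces.

By default classification is evaluated only for points 0.3–10 m above
ground (`search_z_band`): the ground sheet and upper canopy cannot pass the
linearity/verticality gates, and skipping them keeps per-point PCA
tractable on multi-million-point scenes (set `None` to evaluate all
points; the contract tests do).

**Clustering and cylinder fitting.** Stem points are grouped by 3-D
single-linkage connectivity at 0.5 m. Connectivity is deliberately 3-D, not
planimetric: the silhouette edge of a conifer crown is a dense, near-
vertical chain of returns that passes the PCA gates and *projects
planimetrically onto the stem axis* — 2-D linkage would fuse it with the
stem and poison the fit, while in 3-D it stays on the crown shell, metres
away. Groups of ≥ 50 points are fitted with a least-squares cylinder
(parameters: two axis tilt angles, planimetric intercept, radius;
Levenberg–Marquardt refinement of Σ(distᵢ−r)², initialized from the given
direction and an algebraic circle fit in the orthogonal plane). Fits with
radius > 0.5 m or inlier RMSE > 5 cm are rejected — the clustering-by-
cylinder-fitting idea is precisely that non-stem structures do not fit a
stem-like cylinder. Clusters whose fitted axes fall within the link
distance are merged and refitted (restoring the coupling between clustering
and reconstruction); a merge is kept only if the joint fit stays plausible.
The stem ground position is the axis ∩ DTM intersection (fixed-point
refinement, exact on flat terrain); stems beyond 200 m (3-D) of the scanner
are discarded.

All numeric defaults in `StemDetectionConfig` are this package's choices,
exposed as first-class config values.

## Coarse buffers and normalization

Each stem gets every point within 3.5 m planimetric distance (boundary
inclusive), full height; overlapping buffers share points. Buffers are not
clipped vertically. Height normalization subtracts the nearest-DTM-support
ground elevation; points farther than 5× the DTM resolution from any
support raise an error listing the count, and the operation is exactly
invertible given the same DTM.

## Layer-by-layer fine segmentation

Layers are half-open slabs `[j·t, (j+1)·t)` of thickness t = 0.5 m over the
height-normalized buffer. DBSCAN (ε = 0.4 m, min_samples = 5) runs on each
layer's (x, y) projection. Per-layer cluster centroids are grouped across
layers by planimetric proximity (link 0.5 m); a group becomes a tree seed
when it spans ≥ 4 distinct layers, its least-squares 3-D line through the
member centroids is within 15° of vertical, and its apex is a **local
maximum of the canopy**: fewer than min_samples points within 1.0 m
(planimetric) rise more than 0.5 m above the topmost centroid. The last
gate uses the z-maxima of the cloud to separate true tree tops from the
mid-air stacks that appear where two adjoining crowns merge into a single
DBSCAN cluster (a handful of higher points is tolerated as atmospheric
noise). Seeds are numbered 1, 2, … in decreasing apex height.

The sweep then labels every remaining point, bottom-up by default (stems
anchor identity near the ground, where trees are most separated; top-down is
available). Within a layer, unlabelled points are processed in ascending
input index; each is classified by fuzzy k-NN (k = 10, fuzzifier m = 2,
3-D distances by default, 2-D optional) against *all* points labelled so
far — seeds, previous layers, and earlier points of the current layer —
maximizing label evidence and making the iteration deterministic for a
fixed config. A point whose nearest labelled neighbour is farther than
1.5 m stays unassigned (label 0) rather than force-assigned, mirroring how
curated datasets exclude unsalvageable points. Memberships use
`w = d^(−2/(m−1))`; a query coincident with labelled points takes their
label(s) with full weight; membership vectors sum to 1 (property-tested to
1e-12).

In the pipeline, near-ground points (normalized z < 0.3 m) are removed
from buffers before fine segmentation: the coarse cylinder necessarily
contains the ground ring, which is not tree structure and would otherwise
be spread over the trees as commission.

## Per-tree attributes, quality, catalogue

* **Height** = percentile(z, 99.95, linear interpolation between order
  statistics) − ground at the tree location (nearest DTM support to the stem
  ground position), clamped at 0. The percentile method (linear
  interpolation) is this package's choice.
* **Scanner distances**: 3-D distance to the highest point retained by the
  percentile cut (crown top) and to (E, N, ground) (stem base).
* **Point density** = count / area of the planimetric convex hull; reported
  missing for degenerate footprints. The footprint definition is this
  package's choice and is scale-covariant (density scales as 1/s² under
  planimetric scaling, which is tested).
* **Quality levels**: seg-failed → 0; (commission, omission) = (T,T) → 1,
  (F,T) → 2, (T,F) → 3, (F,F) → 4. Automatic scoring against per-point
  truth uses tolerances commission > 5 % foreign points, omission > 10 %
  missing points (config values; an expert-label CSV path is also
  supported, and with neither source non-empty segments default to 4).
* **Scan selection**: wind < 3 m/s and RH < 90 % strict, any precipitation
  or snow rejects.
* **Filenames** `YYMMDD_HHMMSS_treeID_Quality` with unpadded ids; a parser
  provides the inverse. The catalogue is a GeoJSON FeatureCollection (one
  3-D point feature per tree with species, height, quality, distances,
  density, file list), serialized with sorted keys and fixed separators so
  identical inputs give byte-identical output.

## Validation operations

Stem maps are compared by greedy ascending-distance mutually-exclusive
pairing within a 2 m gate (robust to sub-metre disparities), then mean
planimetric distance and per-axis RMSE over signed disparities.
Cloud-to-cloud consistency reports the mean nearest-neighbour distance and
the fraction within a threshold (default 0.15 m), direction a→b by design
with a symmetric (worse-of-both) variant. Completeness scoring feeds the
commission/omission booleans into the quality mapping; with both tolerances
at 0 it reduces to strict set equality.

## Synthetic scenes: what they emulate, and what they do not

The generator emulates the acquisition geometry: scanner 30 m above ground,
tilted 60° down, an 87° × 151° window sampled on a regular angular grid,
maximum range 200 m, first-return-only occlusion, 5 mm Gaussian range
noise, and a 3/1/1/0 pine/spruce/birch/unidentified species mix. The
vertical window is anchored just below the horizon (upper edge at 1.5°
depression): a long-range line scanner covers well above its tilted
boresight, and a window centred on the boresight could never observe
distant crown tops. The instrument-scale angular resolution (0.006°,
~10⁸ rays) is coarsened to 0.05° by default, which preserves the geometry
at desk scale.

Trees are analytic primitives: a vertical stem cylinder (radius 0.08–0.25 m
by species) topped by a cone (pine, crown base 0.45 h; spruce, 0.15 h) or an
ellipsoid (birch), heights 5–22 m by species; "unidentified" trees are bare
stems. Placement is rejection sampling with ≥ 2 m spacing (explicit
positions and per-tree parameter overrides are available for controlled
experiments). Crown surfaces are **porous** (gap fraction 0.3): fully
opaque shells would self-occlude the lower stem of low-crowned spruces at
steep viewing angles, contradicting the observed detectability of such
trees; conifer canopy gap fractions of 20–50 % are typical. Foliage hits
additionally slide up to a few decimetres deeper along the ray (half-normal,
σ = 0.3 m), giving crowns volume without a radiative-transfer model.
Attributes are synthesized per class (distinct reflectance/deviation means
for ground, stem, foliage, outliers; amplitude as an integer function of
reflectance); 0.1 % of points are uniform frustum outliers. Everything is
driven by one seed; repeat generation is byte-identical.

Not emulated: multiple returns per pulse, full-waveform radiometry, wind
motion, snow, understory vegetation, branch-level structure, leaf-on/off
phenology. Passing tests therefore show the chain recovers *geometrically
ideal* trees under the right acquisition geometry; they do not certify
performance on real canopies, where crown interpenetration and understory
make both detection and segmentation harder.

Two intrinsic effects of the geometry are worth knowing:

* a small, low-crowned spruce at long range can present only a few dozen
  stem returns to the single oblique view and is then genuinely
  undetectable — the analogue of the trees a curated PLS dataset excludes
  or down-flags;
* the 99.95th-percentile height of a *cone-tipped* crown sits a fixed
  ~0.1–0.2 m below the true apex regardless of sampling density (the
  trimmed fraction scales with total points exactly as the apex point
  density does), so the height-accuracy condition is exercised on a
  blunt-topped (ellipsoid-crowned) tree at close range, where the
  estimator, not the sampling, limits the error.

## Pipeline and reproducibility

Stage order: read → scan attributes (instrument frame) → rectify →
[Helmert georeferencing, when control points are given — the DTM support
and scanner position are transformed with the cloud] → [voxel resampling,
off by default] → stem detection → reference matching → coarse buffers →
normalization → fine segmentation → attributes/quality → files + catalogue
+ manifest. Species and persistent tree identity come from matching
detected stems to the reference stem map (gate 2 m); unmatched detections
are excluded from the dataset, as in curated PLS practice. The YAML config
is validated against a published schema (unknown keys and missing inputs
fail before any work); the manifest records a config hash, package version
and per-stage point bookkeeping (buffer points = assigned + unassigned +
other trees + ground-cut, exactly). No wall-clock values enter any output,
so a re-run on identical inputs is byte-identical; the acceptance script
runs the pipeline twice and checks this.

Problem sizes used by the test suite and acceptance script: the default
study scene uses 10 trees on a 50 m × 50 m plot at the 0.05° grid
(~4 × 10⁶ points); the adjoining-crowns segmentation condition uses two
conifers 2.8 m apart with crown radii pinned at 1.4 m (just touching) in a
restricted 60° × 30° window; the height condition uses one birch at 24 m on
a 0.02° grid. Unit tests use desk-scale grids (0.1°–0.3°) and analytic
fixtures.

## Known limitations

* Uncompressed LAS only; LAZ requires an external codec and is out of scope
  (a `.laz` path raises a clear error). DTMs are read from LAS or CSV/XYZ
  points; raster formats are not supported.
* The Helmert step is a single global similarity; no per-scan drift model,
  no ICP fine registration.
* Fine segmentation has no leaf/wood separation and no cross-scan label
  tracking (cross-scan identity is carried by stem positions upstream).
* Automatic completeness scoring needs per-point truth labels and is
  therefore a synthetic-data/benchmark instrument; on real data the
  expert-label pathway applies.
* The fuzzy k-NN sweep is O(u²) in the worst case within a layer; very
  thick layers on dense buffers pay for the exact iterative semantics.
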