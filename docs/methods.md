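# Methods

## Inputs and geometric model

A study is a basal-to-apical stack of short-axis slices.  Each slice carries
an endocardial and an epicardial contour (simple polygons, vertices in mm,
image coordinate frame) plus pixel spacing `(dx, dy)`, a through-plane span
(thickness + gap) and the raster grid shape.  Pixel `(row, col)` has its
centre at `((col+0.5)·dx, (row+0.5)·dy)`.  A pixel belongs to the myocardium
iff its centre lies inside the epicardial polygon and outside-or-on the
endocardial one (papillary muscles therefore count as cavity).  The
co-registered scar raster is binary; scar pixels outside the myocardium are
clipped on load with a warning.  LV mass is the summed myocardial voxel
volume times 1.05 g/cm³ (standard myocardial density).

Regional reporting uses the AHA 17-segment model.  Slices are partitioned
into contiguous basal/mid/apical thirds by count, remainder assigned
basal-first then mid (11 slices → 4/4/3).  Basal and mid levels have six 60°
sectors, the apical level four 90° sectors, all half-open `[start, end)` and
counted counterclockwise from the anterior RV insertion angle, which is a
required input (it is not auto-detected).  The apical cap (segment 17) is
not an angular sector: short-axis chords are undefined there, so the cap is
reported as scar present/absent on the most apical slice and excluded from
quartile bins and totals (bins therefore always sum to the total count of
scarred sectoral segments).

## Global burden

`percent_scar = 100 · Σ V_scar / Σ V_myo` with per-slice voxel volumes, so
stacks with heterogeneous spans are volume-weighted correctly;
`scar_mass = percent_scar/100 · lv_mass` by construction, which makes the
conservation identity exact (the same voxel sums appear on both sides).

## Chord model (STLB / SMST)

Rays start at the endocardial centroid of each slice, at uniform midpoint
angles — `n_chords` per sector (default 60, i.e. 1° spacing at the basal and
mid levels).  Each ray's wall segment runs between its outermost endocardial
and epicardial crossings (vectorized ray/polygon-edge intersection); rays
failing to cross both contours are dropped with a warning.  Each chord is
sampled at `n_samples` (default 200) equidistant midpoints.

Sample classification is area-consistent rather than nearest-pixel: the
binary scar mask is first extended outside the myocardium by
nearest-myocardial-pixel (distance transform), then sampled bilinearly, and
the chord's scar length is the wall length times the mean sampled value.
The extension removes the systematic half-pixel loss where chords touch the
raster edge of the wall at the endo/epi borders (without it, transmurality
is biased by `≈ h·(2d−1)/w` for a lesion of depth `d`, wall `w`, pixel `h`);
the bilinear kernel removes most of the zero-mean quantization jitter of
point lookups.  With these choices a fully scarred wall reads exactly 100 %.

**STLB** is the thickness-weighted mean over the segment's chords, pooled
across the slices of its level: `100 · Σ scar_length / Σ wall_length`.  An
unweighted per-chord mean is available (`weighted_stlb=False`).

**SMST** is a maximum statistic, and a maximum amplifies raster noise: the
per-angle transmurality profile of a constant-depth lesion fluctuates with
sd ≈ 3 pp at 1 mm pixels / 10 mm wall, decorrelating over ≈ 1.5° of angle,
so the raw max over 60 chords overshoots truth by 5–6 pp.  SMST is therefore
read from a regularized profile built in three steps:

1. **Iterated bilateral filter** along angle (Gaussian window σ_φ = 20°,
   range gate σ_r = 5 pp, 6 fixed-point iterations, periodic): averages
   quantization noise within plateaus of locally constant depth while
   preserving genuine lesion edges (range-gated), converging toward a
   piecewise-constant profile.
2. **Reprojection correction**: the pixelation error is deterministic given
   the grid, so it can be predicted — constant-depth rings at depths
   0.1 … 1.0 are rasterized on the same grid, their measured profiles give
   the expected moiré at each angle, and that bias (interpolated at the
   locally estimated depth) is subtracted before a second filter pass.  The
   correction only applies where the first-pass profile is locally flat
   (range < 6 pp over ±10°), because the local depth estimate is unreliable
   at lesion edges.
3. **Clamp from below by STLB**: a maximum can never be smaller than a
   weighted mean of the same quantity, so the estimator enforces
   `SMST ≥ STLB` per segment.

Per-chord raw scar lengths remain available through `cast_chords` (used by
the dense-sampling oracle tests); the regularization affects only the SMST
channel.

## Area and mass estimators (STAB / WIT)

**STAB** is the pixel-count ratio `100 · scar area / myocardial area` in the
segment, areas summed over the segment's slices.  The normalization is by
the myocardial area actually present in the sector (an assumption; the
nominal AHA sector area is not used).  **WIT** is the intensity-weighted
scar-mass fraction: `100 · Σ_scar w_p m_p / Σ_segment m_p` with voxel masses
`m_p` and a linear ramp weight clamped to `[0, 1]` between the remote and
core calibration intensities (core ≤ remote is a calibration error).  The
ramp is a declared, isolated model of partial volume; with no intensity
channel `w_p = 1` and WIT collapses to the plain scar-mass fraction, which
equals STAB exactly under uniform voxel volumes.  This is how the package
resolves the tension between a binary scar definition and an
intensity-weighted estimator: the intensity channel is optional, and the
binary path is the reference behavior.

## Quartiles and presence

Transmuralities are binned into 1–24 / 25–49 / 50–74 / ≥ 75 %, half-open at
the lower edges except 75, which is inclusive upward because ≥ 75 % defines
transmural scar.  Zero is excluded from all bins; values in (0, 1) count
into the first bin, so bins always sum to the number of scarred segments.
A segment "has scar" with ≥ 1 scar pixel; an optional minimum-area filter
(mm², default off) can raise that threshold.

## Diagnostic layer

Condition-positive is the clinical endpoint (appropriate ICD therapy);
test-positive is an index strictly above the cut-off (sample median, or a
stated threshold).  Ties at the median fall in the at-or-below group, which
reproduces the published "> 20 g" vs "≤ 20 g" group sizes.  Percentages are
rounded half-up to integers alongside the raw fractions; one published NPV
(90 % for the scar-mass cut) is not reproducible from its own counts
(34/38 = 89.47 % → 89) and is reported here as the raw fraction.  Fisher's
exact test sums hypergeometric probabilities ≤ the observed table's (with
the conventional `1 + 1e-7` tie gate), by direct enumeration (n ≤ 10⁴).

## Phantoms and what passing tests show

Phantoms are stacks of identical concentric circular annuli (256-vertex
polygons) with wedge scars growing radially from the endocardium — chosen
precisely because closed forms exist for every metric; anatomical realism
(crescent-shaped walls, through-plane variation, acquisition artifacts,
surface-coil bias) is deliberately absent.  Wedges compose by union; the
local depth is the max over covering wedges, and the truth module integrates
the piecewise-constant depth profile analytically per sector (never reading
the rasters).  Intensity noise and partial-volume ramps touch only the
intensity channel, so binary-path truths stay exact.

Validated operating envelope at the default 1 mm resolution (10 mm wall):
all four estimators agree with truth within 2 pp, and within 0.5 pp at
0.5 mm pixels, for lesions that are resolvable — angular features ≳ 10° and
depths ≳ 1.5 pixels away from the wall faces.  Below those scales the raster
itself does not carry the information: a 6° transmural needle (≈ 2.6 px
wide) reads SMST ≈ 94–99 instead of 100, and a wedge sliver overlapping a
sector by < 5° can be missed entirely by the chord channel.  Passing tests
therefore demonstrate correctness of the measurement pipeline on clean
geometry, not robustness to segmentation error or acquisition physics.

The toy cohort draws scar mass lognormal(meanlog 3.0, sdlog 0.5) — median
20 g, CV ≈ 0.53 — with logistic event probability
`expit(−3.05 + 0.077·mass)` (≈ 8 % higher odds per gram, event rate ≈ 21 %),
matching the scale of the ICD population this tool targets.  It feeds only
the 2×2 layer.  Under β = 0 the median split is uninformative
(sens ≈ 1 − spec), and the exact-test p-values are *valid* (super-uniform)
but, being discrete and conservative, not uniform in distribution — a KS
test against uniformity rejects them even at n = 2000 per cohort, which is
why the suite asserts super-uniformity rather than uniformity.

## Numerical choices and degenerate inputs

* Rasterization is a pixel-centre test via shapely; the oracle cross-check
  uses matplotlib's independent point-in-polygon routine.
* Chord casting uses the outermost ring crossings, making it well defined
  for mildly non-convex (star-shaped) contours; all-chords-dropped is an
  error, individual drops are warnings.
* Estimator outputs are clamped to [0, 100] against float round-off.
* Zero-thickness walls, endo outside epi, non-simple polygons, empty
  myocardium, < 3 slices (AHA mapping), non-increasing z, core ≤ remote
  intensity calibration, and negative 2×2 counts all raise typed errors.
* Identical slices (same geometry, masks and settings) are computed once and
  reused; outputs are bit-reproducible for fixed inputs and settings.

## Known limitations

* Transmurality is resolution-limited as quantified above; at clinical LGE
  resolutions (~1.5–2 mm in-plane) the quantization floor scales
  accordingly.
* The chord model assumes the endocardial centroid sees the whole wall
  (star-shaped contours); strongly concave walls would need a medial-axis
  chord model.
* STAB normalization by present myocardial area, the slice-third level
  assignment, and the linear WIT ramp are declared conventions; other
  software may differ, and per-segment values are only comparable under the
  same conventions.
* The apical cap carries no transmurality here; tools that report a
  17th-segment transmurality will disagree on totals.
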