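# Methods

This note documents the models, estimators, defaults and numerical choices
behind `retinamosaic`, and what the synthetic-data tests do and do not show
about real microscopy data.

## Point patterns and windows

All mosaic statistics operate on a `PointPattern`: soma coordinates in µm
inside an explicit polygonal `Window`. The window defines the mean density
(n / area) and is where matched null models are generated — density
matching is undefined without a region, so when an analysis has no traced
retina outline the convex hull of the observed somas (or any user polygon)
must be supplied explicitly. Patterns are validated at construction:
points strictly inside the window, no duplicates within 0.01 µm.

## Generators

All generators take one integer seed and use a private
`numpy.random.Generator`; identical spec + seed reproduces coordinates
bit-for-bit. There is no global random state.

* **Uniform (binomial).** Rejection sampling from the window's bounding
  box, so accepted points are exactly uniform over the polygon.
* **Hard-core.** Sequential dart throwing: uniform candidates rejected
  within one exclusion diameter (default 14 µm, a soma diameter) of an
  accepted point. Requested packings above half the window area are
  rejected up front; otherwise a budget of 1000 candidates per requested
  point guarantees termination, and exhausting it raises an error rather
  than silently returning fewer points. This is the matched null model:
  random positions, physical soma size, same count, same window.
* **dmin mosaic.** As above, but each candidate draws its own exclusion
  from Normal(dmin_mean, dmin_sd) floored at 0 (with dmin_mean > dmin_sd
  the clipped mass is negligible). With dmin_sd = 0 the candidate stream
  is identical to the hard-core generator, so the outputs coincide
  exactly. This is the standard positive control for a regular mosaic.
* **Neuron trees.** Primary dendrites leave the soma at evenly spaced
  jittered angles; each tip marches outward in 15 µm steps (direction =
  radial direction + a per-tip angular offset + N(0, 0.15 rad) jitter),
  bifurcating with probability 0.18 per step, and terminates clipped onto
  the circle of the requested field radius. Growth is therefore guaranteed
  to stop, and the arbor's radial extent equals the requested radius by
  construction. Because the convex hull of finitely many tips underfills
  its enclosing circle by ~6% (inscribed-polygon geometry), a population
  whose *measured* equivalent-circle field diameter should average 324 µm
  is generated with `field_radius = M1_FIELD_RADIUS_UM = 172 µm`; with the
  default 162 µm radius the measured mean is ~307 µm.
* **Images.** Constant background plus per-ROI constant intensities
  (pixel-center membership), optional Gaussian noise, clipped to the
  16-bit range.

What the generators do *not* emulate: labeling efficiency, soma-size
variation, local density gradients within a window, tissue distortion from
flat-mounting, non-Gaussian camera noise, or out-of-focus light. Passing
tests therefore demonstrate estimator correctness and sensitivity at
realistic scales — not robustness to every imaging artifact.

## Nearest-neighbor regularity

RI = mean/SD of nearest-neighbor distances, sample SD (n−1). At n ≥ 100
the alternative population-SD convention changes RI by under 1%. RI is
invariant under similarity transforms. A perfect lattice (SD = 0) yields an
infinite-regularity flag, not an exception. The edge-free random reference
is √(π/(4−π)) ≈ 1.913; a torus-distance variant (`torus_nn_distances`)
verifies this closed form at n = 10,000 within 2%.

**No edge correction, deliberately.** Cells near the window boundary lack
neighbors on one side, which inflates both the mean and the SD of NN
distances and biases RI slightly downward in bounded windows (~−3% for 120
cells in a 4.5 mm² half-disc, ~−6% for 500 cells in 3×3 mm, relative to
1.913). The matched null is generated in the same window and inherits the
identical bias, so observed-vs-null comparisons remain fair. At the scale
of ~120-cell mosaics the hard-core null averages RI ≈ 1.90 ± 0.17 (SD
across replicates) — bounded-window values of this quantity reported from
half a dozen retinas scatter by ±0.07 in the mean alone.

## Density recovery profile

All ordered pairs (i → j, i ≠ j) are tallied into half-open annuli
[r, r+Δ), Δ = 20 µm to 400 µm by default; distances exactly r_max are
excluded. Density per bin is pair count / (n × annulus area), Rodieck's
estimator; ordered pairs divided by n equals unordered pairs × 2 / n, and
the raw `pair_counts` are kept on the result so either normalization is
recoverable.

Without edge correction the estimator's expectation under uniformity is
not flat but λ·(n−1)/n·γ̄(r)/|W|, where γ̄ is the window's isotropized set
covariance — for an L×L square, γ̄(r)/L² = 1 − 4r/(πL) + r²/(πL²), a 15%
deficit at r = 390 µm when L = 3 mm. The test suite asserts this closed
form directly (the profile is "flat" only relative to it), and checks
5%-flatness in a 15×15 mm window where the deficit stays below the band.
Null-model comparisons are unaffected: both curves carry the same factor.

**Exclusion zone.** The reference level is the mean bin density over the
outer half of the profile; the zone is the initial contiguous run of bins
below 50% of that reference, reported as the upper edge of its last bin
(0 if the first bin already meets the criterion). The 50% criterion is a
package convention — the field reports exclusion zones without a standard
numeric rule, and a depleted zone alone is not proof of regularity. At
20 µm bins the zone estimate is floor-limited: a 14 µm soma-scale
exclusion is sub-bin and reads as ≤ 20 µm. At sparse densities
(~13 cells/mm², ~120 cells) single-digit pair counts make the first bins
noisy; recovery simulations at that scale still localize 100–200 µm
spacing rules to within one bin in ≥ 80% of seeds.

## Coverage and retina maps

CF = density × π(d/2)² with d in mm; linear in density, quadratic in
diameter. The field diameter estimator is the equivalent-circle diameter
of the convex hull (of a traced outline, or of dendritic node positions
for morphologies) — the literature reports mean diameters without naming
an estimator, so this testable convention is used throughout. Which
density enters CF is the caller's choice; for a population occupying only
part of the retina, the density of the occupied region (e.g. convex-hull
area of the somas) is the meaningful one.

Hemisphere splits project points onto the dorsal axis (unit vector, +y by
convention) relative to the optic nerve; points exactly on the split line
count as dorsal (fixed tie rule, measure-zero on data). Dorso-ventral
profiles bin those projections in 100 µm strips over the window's full
extent — counts always sum to n — and per-bin densities divide by the
window∩strip area computed exactly from the polygon. Population
subtraction claims, for each subtraction point, its nearest unclaimed
point within the match radius; unmatched points warn and are reported in
the result metadata.

## Sholl analysis and morphometrics

Morphologies are SWC trees validated for a single root, resolvable
parents, connectivity and acyclicity. Sholl crossings are exact: each
edge, projected en face to (x, y), contributes the real roots in (0, 1] of
the quadratic |p₀ + t·d − soma|² = r². Counting roots in (0, 1] — not
[0, 1] — makes a node lying exactly on a circle count once (it is the
parent edge's t = 1), and a tangency (double root) counts once. Radius 0
is defined as the number of primary dendrites. The default grid is 10 µm
steps to 400 µm; the profile shape is insensitive to steps ≤ 25 µm for
~160 µm arbors.

Morphometric conventions (tree-theoretic, since the field's plugin
conventions are unpublished): junctions = dendritic nodes with ≥ 2
children, endpoints = dendritic leaves, branches = maximal unbranched
paths (= root children + junction children); the soma is excluded from
junction and endpoint counts. Soma diameter = 2 × root radius; field
diameter = hull equivalent-circle diameter of non-root nodes (0 for
degenerate collinear arbors).

## Fluorescence quantification

Pixels belong to an ROI when their centers lie inside the polygon —
deterministic and consistent between the image generator and the
measurement, so noiseless fixtures round-trip exactly. F/Fo divides ROI
mean by background mean; the background region must be supplied explicitly
(no auto-selection), and a non-positive background is a diagnosed error.
The dense-innervation call is strictly F/Fo > 1.5, so 1.5 itself is
negative. F/Fo and the call are invariant under any global gain k > 0.

Cross-section profiles sample a 30 µm-wide mask at 0.75 µm stations along
its axis (bilinear interpolation; 0.75 µm is sub-pixel at typical confocal
scales), average across the width, then average stations in groups of 8
into 6 µm bins. A 750 µm mask holds exactly 1000 stations / 125 bins; a
650 µm mask holds 866 stations, and the 2 stations beyond the last full
bin are dropped from the binned values (they remain in
`station_values`). The binned mean equals the station mean whenever the
length divides evenly.

## Problem sizes and determinism

The test suite and the acceptance script run at the scale of the data they
emulate: ~120-cell mosaics in 4.5–9 mm² windows, 100-replicate null
ensembles, n = 10,000 torus patterns for the closed-form limit, 100-tree
and 100-instance oracle sweeps. The whole suite completes in well under a
minute. Every stochastic computation derives its seeds from one explicit
integer (via `numpy.random.SeedSequence` where a family of independent
streams is needed), so all reported numbers are exactly reproducible.

## Known limitations

* No edge-corrected estimators (by design, see above); absolute RI and
  DRP values from bounded windows are biased relative to edge-free theory
  and should only be compared against matched nulls.
* The exclusion-zone rule is a convention; borderline profiles (first bin
  hovering near 50% of the reference) flip between 0 and one bin.
* Sholl analysis is 2-D (en face); stratification depth is out of scope.
* The coverage factor inherits whatever density definition the caller
  supplies; occupied-region vs whole-retina density can differ severalfold
  for restricted populations.
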