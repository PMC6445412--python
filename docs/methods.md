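# Methods

## The model

The quantity of interest is the dioptric defocus experienced at each
point of the retina of a right eye under a given viewing condition.  It
is modelled as the element-wise sum of three 400×400 dioptric field maps
sampled at 0.1°/pixel over the central 40°×40°:

1. **Scene defocus** `E(x, y) = 1/d_gaze − 1/d_obj(x, y)` — the vergence
   mismatch between the accommodative plane and the scene content in each
   visual direction.  Scene maps are recorded in visual-field coordinates
   and flipped upside-down and left-right into the retinal frame,
   mirroring the optical inversion of the retinal image.
2. **Eye power** — the peripheral-refraction surface of the eye, sign
   inverted so values reflect power rather than refraction.
3. **Lens power** — the effective on-eye power profile of a multifocal
   contact lens, obtained by over-refraction subtraction; an all-zero
   (blank) matrix for the naked eye.

All analysis maps share one frame: retinal coordinates of a right eye,
`+x` = nasal retina, `+y` = superior retina, pixel centres at
`((c − 199.5)·0.1°, (199.5 − r)·0.1°)`.  Positive combined values denote
relatively myopic defocus (focal plane in front of the retina).  This
sign convention is a package choice — written into every map sidecar —
because defocus maps have no universally agreed sign.

The full design crosses 3 scene archetypes × 3 optical conditions
(naked eye, near-centre multifocal, distance-centre multifocal) × 4
peripheral-refraction profile classes, i.e. 36 condition maps built from
10 baseline inputs.

## Peripheral-refraction shell

Refraction is sampled along 5 horizontal parallels (elevations −20°,
−10°, 0°, +10°, +20°) with 81 azimuth samples spanning ±40° and a
nominal 4 repeated scans per point; only the spherical equivalent M (D)
is carried.  Per point, repeats are averaged and the sample SD (ddof=1)
computed; points with SD > `sd_threshold` (default **1.0 D**) are
removed as unreliable and flagged MISSING, never zero-filled.  A
parallel with more than 50 % missing points aborts with a quality error.

**Classification** uses the equatorial parallel only.  With `N`, `T` the
mean M over the nasal and temporal outer edge zones (|azimuth| in
20–40°) and `C` the mean over the central ±10°, and threshold
`tau` (default **0.25 D**, one clinical refraction step — the notion of
"more positive" needs a numeric criterion and none is standard):

| label | rule |
|---|---|
| RPH | `N − C ≥ τ` and `T − C ≥ τ` |
| RPM | `C − N ≥ τ` and `C − T ≥ τ` |
| NPS | `N − C ≥ τ` and `N − T ≥ τ` |
| TPS | `T − C ≥ τ` and `T − N ≥ τ` |

evaluated in that order (symmetric classes take precedence over skewed
ones); anything else is INDETERMINATE.  Zone *means* rather than single
edge points are used — the mean is robust to the removal of individual
filtered points in the edge zone.

**Surface fit.**  Only the central ±20° of each parallel feeds the map
(41 nodes at 1°); the outer zones serve the classifier alone.  MISSING
nodes are first filled by 1-D linear interpolation along their own
parallel (never across parallels, which are 10° apart and may differ
systematically).  The 5×41 node grid is then interpolated by a
tensor-product cubic spline (`scipy` `RectBivariateSpline`, smoothing
0): an *interpolating* fit whose testable contract is exact node
reproduction (< 1e-6 D).  A global cubic polynomial across the 5
elevation nodes was rejected because 5 constraints overdetermine 4
coefficients — it could not reproduce the nodes it is fitted to.  A
spline through 5 nodes of any quadratic (or cubic) generating surface
reproduces that surface exactly, which the parameter-recovery tests
exercise.

**Scan-table convention.**  On disk, scan tables use the instrument's
visual-field convention (azimuth positive toward the nasal visual field,
elevation positive upward); the reader negates both angles so in-memory
grids are retinal (for a right eye, the nasal visual field images onto
the temporal retina and the upper field onto the inferior retina).  Both
grids are symmetric, so this is a pure relabelling.

## Lens profiles

The on-eye power profile is `on_wear − naked` per meridian point, with
MISSING propagating from either input.  Lens power maps are built with
the same surface-fit contract.  Theoretical symmetric designs are
mirror averages per parallel, `s(θ) = (f(θ) + f(−θ))/2` — idempotent,
exactly mirror-symmetric, and meridian-mean preserving.  Only azimuthal
symmetry is imposed (the asymmetries of interest are nasal–temporal);
rotationally averaged designs were a considered alternative but would
couple parallels that were measured independently.

## Segmentation

Pixel-centre eccentricity `d` splits the central 20° disc into four
5°-wide rings, half-open at the inner edge (`5(k−1) < d ≤ 5k`).
Quadrants are the 90° sectors centred on the retinal axes and bounded by
the ±45° diagonals (the corneal-topography reading of superior /
inferior / nasal / temporal segments).  On the half-offset pixel grid
some pixel centres lie exactly on a diagonal; each of the four diagonal
rays is assigned to one adjacent sector (NE→superior, SE→nasal,
SW→inferior, NW→temporal), so the 16 regions partition the disc exactly
and every ring has four identical quadrant counts (1965, 5892, 9815,
13747 pixels).  Membership tests use exact integer arithmetic in
half-pixel units; the masks are reproducible to the pixel.  Map corners
(`d > 20°`) are stored but excluded from all statistics.

The reference mean counts for the innermost and outermost rings are
1961 and 13737 pixels.  Those values are reproduced *exactly* by a grid
with 401 samples per axis (−20°…+20° inclusive, one pixel on the fovea),
rings `lo < d ≤ hi`, and quadrant mean = ring count / 4.  On the 400×400
half-offset grid used here no boundary rule reaches them exactly; the
frozen convention above comes closest (+0.20 % and +0.07 %).  Excluding
diagonal pixels outright was rejected: it biases the innermost-ring mean
by −1.8 %.

## Synthetic data

No public data exist for any input class, so generators emulate each:

* **Scenes** — archetype layouts of disc-shaped content patches over a
  background plane: OFFICE (gaze 0.5 m on near work, desk patch in the
  inferior field at 0.55 m, walls at 3 m), CORRIDOR (gaze 3 m, walls at
  2.2–4 m — a low-variance, near-uniform field), LIVING_ROOM (gaze 2 m,
  mixed near/far patches).  The dioptric map is Gaussian-smoothed
  (default 1–1.5°) and pixel noise added (default 0.10–0.15 D).
  Archetypes emulate qualitative structure (near-work fields dominated
  by positive defocus below gaze; far fields near zero) — their value
  *distributions* cannot be validated against the original recordings.
* **Shells** — noiseless mean
  `M(θ, φ) = M₀ + a·θ² + skew(θ) + b·φ²` with a half-cosine skew ramp
  rising over the outer 20° of the skewed side (no functional form for
  skewed profiles is standard; the half-cosine is smooth and
  one-sided), plus i.i.d. Gaussian per-scan noise.  The default noise
  SD of 0.26 D matches the pooled post-filter repeat SD of the
  measurements this emulates; defaults produce each profile class with
  ≥ 2τ margin.  Central M defaults to −3.25 D (a mid-range myope).
* **Lens scans** — naked scans plus an analytic radial profile:
  near-centre `c + add·exp(−r²/t²)`, distance-centre
  `c + add·(1 − exp(−r²/t²))`, with `c = −0.25 D`, adds 2.25/2.50 D,
  transition radius 12°, optional decentration and a linear
  nasal–temporal tilt emulating on-eye asymmetry.  Repeats inherit the
  naked scans' noise, so noiseless subtraction round-trips exactly.

What passing tests show: the pipeline's algebra, filtering,
classification, interpolation and statistics behave as specified on
inputs with the stated structure.  What they do not show: that real
scenes, eyes or lenses have that structure — generator archetypes are
stylised, the noise is i.i.d. Gaussian (real scan errors are spatially
correlated), and lens flexure/tear-film optics are not modelled.

## Statistics

* **Kruskal-Wallis** — tie-corrected H, chi-square upper tail, df = k−1
  (via `scipy.stats.kruskal`; brute-force rank oracles in the tests).
  All-identical pooled data yields H = 0, p = 1 by convention.
* **Mann-Whitney U** — exact enumeration when min(n) ≤ 8 with no ties
  (exactness is cheap there), otherwise the normal approximation with
  tie-corrected variance and *no* continuity correction, so identical
  samples give p = 1 exactly.
* **Benjamini-Hochberg** — the literal step-up, returning both reject
  flags and the realised critical p-value `(i*/m)·q` (implemented
  directly because the critical value is part of the output contract;
  cross-checked against `statsmodels` in tests).
* **Post-hoc after KW** — Dunn z-statistics on mean-rank differences
  with pooled tie-corrected variance.  Familywise control by default
  refers `√2·|z|` to the studentized-range distribution with k groups
  and infinite df (Tukey-Kramer on mean ranks — the default of the
  numerical environment the original region analysis was run in); Holm
  step-down on the raw normal p-values is a selectable alternative.
  The corrected per-comparison critical p-value is reported as an
  output, never supplied as an input.  Simulated familywise error under
  the global null (3 groups × n = 50, 2000 replicates) is ≈ 0.05 and
  asserted ≤ 0.07.
* **Region-wise analysis** — for each ring×quadrant region and each
  combination of the two held factors, the varied factor's groups are
  compared (KW + post-hoc) and non-significant contrasts collected.

**Pseudo-replication caveat.**  Regions contribute 1965–13747 pixels as
if independent observations, so even small mean differences (≳ 0.1 D at
the noise levels used) are "significant"; neighbouring pixels of an
interpolated surface are in truth highly dependent.  This analysis
reproduces that convention deliberately — the comparison scheme is the
object of study — and the tests therefore probe *pattern* (which regions
lose significance when a lens's power cancels locally), not calibrated
error rates on real retinas.

## Numerical choices and problem sizes

* All randomness flows through `numpy.random.default_rng(seed)`;
  identical specs and seeds give bit-identical outputs.
* Map CSV I/O writes `%.17g`, round-tripping to < 1e-9 D.
* Region-mask membership uses exact integer half-pixel arithmetic — no
  floating-point boundary ambiguity.
* Test problem sizes: 100 random shells per class for classifier
  recovery; 500 random small instances (n ≤ 12) for rank-test oracle
  equivalence; 2000 replicates for the familywise-error simulation; the
  end-to-end check uses one scene × one subject × three optics at full
  400×400 resolution.  These sizes give stable pass/fail behaviour at
  interactive runtimes.

## Known limitations

Only the right eye is modelled; left-eye support would need a mirrored
nasal/temporal convention.  Only spherical-equivalent defocus is
carried — no astigmatic (J0/J45) or higher-order-aberration maps.  The
surface fit interpolates 5 parallels; vertical structure between
parallels is purely spline-implied.  Scene archetypes are stylised
stand-ins for recorded environments.  Accommodation, lens translation
over blinks and cyclotorsion are not modelled.
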