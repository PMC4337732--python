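# Methods

## The analysis model

`retinocorr` quantifies how the spatial pattern of correlated BOLD-like
signal across visual areas relates to retinotopy, in three tiers.

**Eccentricity binning and radial profiles.**  Surface nodes carrying
retinotopic coordinates (eccentricity e in degrees of visual angle, signed
hemifield polar angle θ ∈ [−90°, +90°], 0 = horizontal meridian, +90 =
upper vertical meridian) are restricted to the central 0.50°–12.50° and
partitioned into 12 bins with fixed log-scaled boundaries (0.50, 0.84,
1.24, 1.71, 2.27, 2.93, 3.71, 4.63, 5.73, 7.02, 8.55, 10.36, 12.50°).
Intervals are half-open with the last bin closed, so the list exactly
covers the analyzed range.  Per run, Pearson correlations between bin-mean
timeseries form a 12×12 matrix per region pair; matrices are averaged over
runs element-wise on r.  Cells are grouped by ranked radial distance
|i − j| (0 = iso-eccentricity, 11 = foveal vs peripheral-most) and
averaged; for self-pairs the identical-series diagonal is excluded.  The
display normalization d_X = 1 − (r₀ − r_X) preserves slopes.  Group
inference on the per-subject linear slope of mean r against distance uses
a label-shuffling permutation test: each of 10,000 iterations applies one
shared shuffle of the distance labels to every subject, refits slopes, and
records the group mean; the observed mean slope is compared with the
2.5%/97.5% quantiles (two-tailed α = 0.05).  An "eccentricity effect" is a
mean slope below the 2.5% quantile — the direction-specific reading used
throughout, since the question is always whether correlations *decrease*
with radial distance.

**Topographic model regression.**  Each hemifield is divided into 36 bins
(6 eccentricity divisions — merged pairs of the 12 analysis bins — × 6
polar-angle divisions of 30°).  The observed 36×36 correlation matrix C is
fit by OLS over vectorized cells as a weighted sum of four predictors plus
an intercept: NSE (instrumental noise), RF (pRF overlap), Ecc and Pol
(widespread ramps).  Missing cells are dropped pairwise from all terms.
Robust (bi-square) fitting is not implemented as a separate path; OLS is
the single estimator.

- *NSE*: every node's series replaced by white noise, smoothed along the
  cortical sheet with a 3.5 mm FWHM Gaussian (the BOLD point-spread scale
  at 3 T), passed through the same preprocessing, binned, and correlated;
  several surrogates are averaged (default 5).
- *RF*: node pRFs are isotropic Gaussians g(x,y) normalized to unit
  integral on a Cartesian visual-field grid (0.1° step, ±20° extent — the
  extent leaves the largest σ = 5.8° at 12.5° eccentricity ~1.3σ of tail
  beyond the grid edge, a truncation error below 1e−3, verified against a
  half-step oracle in tests).  σ(e) is linear per area through the sizes
  at 0.5° and 12.5°: V1 (0.4°, 1.6°), V2 (0.48°, 2.3°), V3 (1.0°, 4.15°),
  hV4 (1.2°, 5.8°); V3A–B and VO1–2 are excluded from predictor
  construction for lack of published sizes.  Bin response fields are means
  of member pRFs, renormalized; overlap is ∫min(F_A, F_B)/∫max(F_A, F_B)
  (a function-level Jaccard index, bounded [0, 1] and symmetric; the
  alternative ∫min/(∫A+∫B−∫min) is available via `metric="jaccard"`).
- *Ecc/Pol*: 1 − Δ/Δmax on ranked division indices; iso-sets get exactly
  1.  For inter-hemisphere polar angle there is no iso-polar pair: the
  angular path runs through the nearer vertical meridian, so the minimum
  distance is 1 and values are 1 − d/6 ∈ [0, 5/6].
- *Homotopic RF*: one hemisphere's response fields are reflected about the
  vertical meridian (x → −x) before overlap.
- *Cholesky control*: a target local correlation structure is
  ridge-regularized to positive definiteness (smallest power of ten on the
  diagonal), factored, used to color white noise into per-bin latent
  series inherited by member nodes, sheet-smoothed at the point-spread
  scale, and re-binned — bounding how much unmodeled spatial blur could
  inflate local connectivity.

**Residual analysis.**  Local predictors are regressed out first and the
residuals are correlated with each widespread predictor separately, so all
shared local/widespread variance is attributed to the local model — a
conservative test for widespread structure.  Correlations are Fisher
z-transformed for one-sample and paired two-tailed t-tests, with
Benjamini–Hochberg FDR applied within each condition.  Variance
comparisons use incremental R² of nested OLS fits (RF beyond NSE;
Ecc + Pol beyond NSE + RF).

## Preprocessing

Per run: drop the initial 21.6 s (rest) or 19.5 s (movie) of volumes
(floor(s/TR): 12 at TR 1.8 s, 13 at TR 1.5 s); clip samples beyond ±2.5 SD
of each node's mean (a simple, testable despike with the same intent as
curve-fit despiking); remove linear and quadratic trends by least squares;
band-pass 0.01–0.1 Hz with a 2nd-order Butterworth applied
forward-backward (zero phase, so correlations are not lag-distorted);
regress out six motion traces, their temporal derivatives, and
white-matter/ventricle traces.  Global-mean removal is off by default.
The band-pass/detrend order follows the enumeration order of the cleaning
steps; detrending is idempotent, and the pipeline's effect on the
eccentricity analysis is verified to be sign- and significance-preserving
with nuisance regression on or off.

## The synthetic generator

No public dataset carries the needed per-node retinotopic coordinates plus
timeseries, so the package ships a generator whose ground truth is known.

**Sheets.**  Each area/hemisphere is a rectangular grid (default 24
eccentricity columns; dorsal and ventral quadrants of V1–V3 are separate
sheets meeting only at the fovea).  Sheet x maps to log-eccentricity
uniformly over [log 0.5, log 12.5] — emulating cortical magnification, so
log-spaced bins receive equal node counts; 24 columns also guarantee every
one of the 12 unequal-width published bins is populated.  Sheet y maps
linearly to polar angle over the quadrant (or hemifield) range.  Default
sheet extent is 40 mm × 20 mm, putting the default grid spacing near the
3.5 mm point-spread scale, as on real flattened early visual cortex.

**Signal mixture.**  Node i receives
y_i = w_rf·s_i + w_ecc·u(e_i) + w_pol·v(θ_i) + w_homo·h_i + nuisance + noise,
each component unit-variance so weights are comparable:

- s_i: a shared spatiotemporal white-noise "movie" (0.25° pixels, ±14°)
  filtered through node i's unit-norm pRF; pairwise correlation equals
  cosine pRF overlap.  Because published pRF sizes are ≥0.4° even at the
  fovea, this coupling genuinely leaks across the vertical and horizontal
  meridians for foveal and meridian-adjacent bins — a property of the
  Gaussian pRF model itself, strongest for areas with large peripheral
  pRFs.  Specificity tests therefore use V1, where the non-overlap premise
  across quadrants holds best.
- u: a Gaussian-process latent field over log-eccentricity
  (squared-exponential covariance, correlation length 1.0 log-degrees —
  chosen so correlation decays smoothly over the ~3.2 log-unit analyzed
  range, giving near-linear rank-distance decay without hard bin edges),
  sampled on a 64-point grid per timepoint and linearly interpolated to
  nodes; shared across areas, quadrants, and hemispheres.
- v: the analogous field over polar angle (correlation length 30°), drawn
  independently per hemifield.
- h: a white-noise series per (area, sheet position), shared by the two
  hemispheres' mirror-symmetric nodes (reflection about the vertical
  meridian maps (e, θ) onto (e, θ) in the other hemifield).
- nuisance: six integrated-and-smoothed motion traces scaled to a peak
  displacement of `motion_amp` mm (capped at 1.0 mm, mirroring the
  head-motion inclusion criterion), their derivatives, and smoothed
  white-matter/ventricle traces, injected with per-node random loadings.
- noise: white per node, smoothed along each sheet with the 3.5 mm FWHM
  point-spread kernel, re-standardized, scaled by `noise_sd`.

For the movie condition the signal latents are drawn once and shared
across runs (stimulus-locked); rest runs get fresh draws.  Only
stimulus-locked signal can survive inter-run correlation, which is the
basis of the stimulus-dependence dissociation.

**Defaults as study conditions.**  TR 1.8 s (rest) / 1.5 s (movie);
T = 333 (~10 min at TR 1.8; tests and the demo study use T = 300, i.e.
9 min, to keep runtimes modest); 2 runs; 10 subjects; weights
(w_rf, w_ecc, w_pol, w_homo) = (1.0, 0.7, 0.3, 0.5) with unit noise for
mixed-source demos — a regime where local coupling is strongest, the
eccentricity gradient is clearly present, and polar-angle coupling is
weak, matching the qualitative ordering the analysis is designed to
resolve.  Single-source parameter-recovery runs set exactly one weight
to 1.  Generator-only pRF sizes for V3A–B (1.2°, 5.0°) and VO1–2
(1.5°, 6.0°) are synthetic stand-ins continuing the hierarchy trend; the
predictor module still refuses these areas.

**What the generator does not emulate** — hemodynamic convolution,
physiological (cardiac/respiratory) spectra, folded cortical geometry and
volumetric blurring, subject-specific retinotopy distortions, and
attention effects.  Passing tests therefore show that the *analysis
machinery* recovers what it is designed to recover under its own
assumptions, not that real cortex behaves this way.

## Numerical choices and edge cases

- Bin and wedge boundary conventions: half-open eccentricity intervals
  (last bin closed); meridian wedges remove by strict inequality (nodes
  at exactly 30°/45° are kept).
- Empty or constant bins become missing (NaN) cells and propagate
  through averaging, profiles (distance levels with no cells are dropped
  from fits), and regression (pairwise deletion).
- Exactly collinear predictors raise an error naming the pair; condition
  numbers above 1e6 warn.
- Residual correlations against numerically constant residuals (exactly
  explained data) are reported missing rather than meaningless.
- The near/far contrast used for the instrumental control splits the
  distance range into halves (0–5 vs 6–11; 1–5 vs 6–11 when the identical
  diagonal is excluded), using every distance level at balanced power.
- All randomness flows from one master seed through per-stage
  `SeedSequence`-derived generators keyed by stage labels; identical
  configs are bit-reproducible.
- Problem sizes in the test suite (192 nodes/area/hemisphere, T = 300,
  2 runs, 10 subjects, 5 noise surrogates) are the package's demo scale:
  large enough for every qualitative effect to be resolvable, small
  enough to iterate on.

## Known limitations

- The pRF-overlap coupling makes "non-overlapping representations" a
  matter of degree: for areas with large pRFs (V3, hV4), weak
  cross-quadrant and cross-hemisphere coupling is a *true* consequence of
  the Gaussian overlap model, so specificity statements are cleanest in
  V1 and should not be read as exact nulls elsewhere.
- Ecc/Pol predictors use ranked division distances, not degree
  differences (matching the ranked radial-distance treatment); a
  degree-difference variant would weight the log-scaled divisions
  differently.
- The inter-hemisphere polar-angle distance runs through the nearer
  vertical meridian; other conventions (e.g., through the lower meridian
  only) would change the Pol predictor for inter-hemisphere fits.
- Group statistics assume subjects share one node table (synthetic
  subjects do); co-registration of real subjects is out of scope.
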