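# Methods

This note documents the models and procedures implemented in `tractspan`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data generator does and does not emulate.

## The analysis

The package analyses features of white matter bundles — microstructure
(FA, MD, AD, RD, ICVF, ISOVF, OD averaged over a tract), macrostructure
(ten shape features of the streamline bundle), and cortical morphology
probed at streamline endpoints — as functions of age from birth to late
life, in a study design where four cohorts (infant, development, young
adult, aging) partition the age axis with essentially no overlap. The
stages, in order:

1. feature extraction (shape features from tractograms; scalar-map
   sampling),
2. continuity-based harmonization of a cohort-specific acquisition offset,
3. covariate-adjusted restricted cubic spline (C-RCS) trajectory modelling
   with subject-level bootstrap,
4. association analyses: cross-feature correlations within pathway and
   cohort, cross-pathway rate coupling, development-versus-aging rate
   coupling, and anterior-posterior gradients of rates.

## Bundle shape features

A bundle is a set of ordered 3D polylines in world RAS+ millimetres with a
reference voxel grid (voxel centres at integer indices, membership by
half-open voxel intervals). The ten features:

* **length** — per-streamline arc length (sum of segment lengths), averaged
  over streamlines (mm).
* **span** — per-streamline straight-line endpoint distance, averaged (mm).
* **curl** — length / span, 1 for a straight bundle, growing with
  curvature; undefined (NaN, not an error) for closed loops.
* **volume** — occupied-voxel count x voxel volume (mm^3). A voxel is
  occupied iff a streamline vertex maps into it after segments are
  densified below half the smallest voxel size; this vertex-membership
  rule (rather than exact segment-box intersection) matches common
  tractography practice and differs negligibly at these resolutions.
* **endpoint volume** — same rule applied to first/last vertices only.
* **diameter** — the bundle approximated as a cylinder:
  `2 sqrt(volume / (pi length))` (mm); **elongation** = length / diameter.
* **surface area** (total, head, tail) — exposed voxel faces under
  6-connectivity x face area (mm^2). Exposed-face counting is exact and
  deterministic on the occupancy mask, which makes it testable on analytic
  fixtures (a unit voxel has area 6, a 1x1x10 rod 42); it is a dialect
  choice relative to toolboxes that use mesh-based areas.
* **head/tail** assignment: streamlines are first co-oriented against a
  reference streamline, then the end cluster whose centroid is smaller
  along the dominant displacement axis is the head (the most
  left/posterior/inferior end in RAS), ties broken x then y then z. Whether
  span should be computed per-streamline-then-averaged or between
  end-centroids is a genuine convention choice; the per-streamline mean is
  used and documented here.

Tractogram I/O goes through `nibabel.streamlines` (TRK with its voxel grid
header, TCK in world mm).

## Scalar sampling

Tract averages are unweighted means over the occupied-voxel set — not
weighted by streamline visitation — with NaN voxels excluded and the
excluded fraction reported. Endpoint probing reads the map at the voxel
containing each streamline's first and last point (nearest-voxel, no
interpolation, matching endpoint-map tools), averages the two ends, then
averages over streamlines; a one-sided NaN uses the finite end, a
two-sided NaN drops the streamline (counted). Cortical maps are undefined
off the ribbon, so this NaN policy is load-bearing: mid-brain pathways
without associated cortex propagate as missing cells, never as zeros.

## Harmonization by continuity

When one cohort's acquisition shifts every feature additively and cohorts
share no age overlap, covariate-overlap methods (ComBat) are unusable. The
estimator assumes the underlying trajectory is continuous across cohort
boundaries: at each boundary age b (defaults 22 and 36 y for the
young-adult cohort), a linear model value ~ age is fit separately to
target-cohort rows on their side of b within a `window` (default 5 y) and
to neighbour-cohort rows on the other side; the discrepancy is the
difference of the two predictions at b, and the offset is the mean
discrepancy over boundaries. Subtracting it from the target cohort restores
continuity.

Properties worth knowing:

* exact (to numerical precision) when the trajectory is locally linear
  within the window;
* for a curved trajectory the bias is bounded by `max|f''| window^2 / 8`
  per side (Taylor remainder of the boundary-value extrapolation), and the
  two sides largely cancel when curvature is smooth across the boundary —
  both bounds are tested;
* estimated per bundle x feature by default (pooling across bundles is an
  option);
* additive, not multiplicative, because the phenomenon being corrected is
  an offset.

The minimum rows per window (`min_n`, default 5) guards the linear fits; at
full study scale a 5-year window contains dozens of sessions per side.

## C-RCS trajectory model

Each bundle x feature series is fit by ordinary least squares to

    value = b0 + b1 B1(age) + ... + b_{k-1} B_{k-1}(age) + g 1[sex=F] + e

with Harrell's restricted cubic spline basis over k = 6 knots at ages
2, 4, 22, 35, 75 and 90 years: B1(age) = age and, for j = 1..k-2,

    Bj+1(a) = [ (a-t_j)+^3 - (a-t_{k-1})+^3 (t_k-t_j)/(t_k-t_{k-1})
                + (a-t_k)+^3 (t_{k-1}-t_j)/(t_k-t_{k-1}) ] / (t_k-t_1)^2 .

The basis is twice continuously differentiable and exactly linear outside
the boundary knots (tested numerically); the `(t_k-t_1)^2` normalisation
keeps the design well conditioned. Sex enters as an additive indicator —
the covariate-adjustment convention here is additive terms, and sex is the
default covariate set. Predictions evaluate covariates at the observed
fraction female by default, so curves represent the cohort mean (a single
sex or an arbitrary fraction is configurable).

Derived quantities:

* **difference per year** — the analytic derivative of the fitted spline
  (truncated-square terms), cross-checked against finite differences;
* **percent difference per year** — 100 x derivative / fitted value, NaN
  where the curve crosses zero;
* **extremum** — dense-grid scan (default step 0.1 y, bounding age error at
  half a step) for the global interior maximum (peak) or, failing that,
  interior minimum; a curve whose extremes sit on the range boundary is
  classified `none` (no well-defined peak). The scan is preferred over
  derivative root-finding because it is robust to multiple local extrema;
* **cohort-binned rates** — mean percent difference per year over the grid
  within fixed bins (infant 0-5, development 5-21, young adult 22-35,
  aging 36-100 y), clipped to the fitted age range.

**Bootstrap.** Uncertainty comes from resampling *subjects* with
replacement (all sessions of a drawn subject travel together), because the
infant cohort is longitudinal and sessions of one subject are not
exchangeable rows. Each replicate refits the model — the replicate design
is a row-selection of the full design matrix, so refits are cheap — giving
pointwise 95% percentile bands and a percentile CI of the extremum age over
replicates that found the same extremum type as the point fit
(percentile-of-argmax construction). Rank-deficient replicates are dropped
and counted, with an error if more than 10% drop. The desk default is
B = 200 replicates; B = 10,000 reproduces the full-scale design and is a
single config value away.

## Association analyses

* **Feature correlations** (per pathway x cohort): Pearson r over sessions
  for every feature pair, or partial correlation (both features
  residualized on age and sex) — Pearson rather than rank correlation
  throughout, matching the linear-correlation convention of the analysis
  this pipeline implements. Two-sided p-values use the t transform with
  n - 2 (partial: n - 2 - #controls) degrees of freedom; the implementation
  is cross-checked against `pingouin.partial_corr` in the tests.
* **FDR**: Benjamini-Hochberg step-up at q = 0.05, applied within one
  matrix (the upper triangle is the family; the choice of family is a
  documented convention). NaN p-values are excluded from the family and
  never rejected. The implementation is verified against a brute-force
  enumeration of the step-up definition.
* **Rate coupling**: Pearson correlation over pathways between the binned
  rates of two features within a cohort, pairwise NaN dropping (preserves
  complete pairs when cortical features are missing for mid-brain
  pathways), minimum 3 complete pathways per pair.
* **Development vs aging**: for one feature, Pearson correlation across
  pathways between development-bin rates and aging-bin rates.
* **Anterior-posterior gradients**: OLS fits of per-pathway rates against
  the bundle's MNI y centroid, linear and quadratic, reporting the
  highest-order term's p-value. Centroid coordinates are user input (the
  synthetic study has no MNI geometry).

## Synthetic data generator

The generator is the ground truth against which every stage is tested. It
emulates:

* four cohorts partitioning 0-100 years (infant 0.03-6.1, development
  5.5-21.9, young adult 22-37, aging 36-100), ages uniform within bounds
  (the simplest density covering the fitting domain; the real age
  distributions are not published per-year),
* smooth nonlinear truth curves per bundle x feature from three families
  (rise-and-decline `c0 + c1 a exp(-c2 a)`, quadratic, cubic-spline control
  points), with deterministic per-bundle amplitude variation so pathways
  genuinely differ in their rates,
* an additive acquisition offset confined to the young-adult cohort, an
  additive sex effect (sex assigned 50/50 — per-cohort sex ratios are not
  published), and i.i.d. Gaussian residual noise,
* longitudinal infant subjects: per-subject session counts drawn from a
  configurable range (1-5 at full scale), session ages spaced by 0.5-1.5 y
  increments — enough structure to make bootstrap-by-subject meaningful,
* parametric bundles (straight tube, circular arc, fan) with analytically
  known length, span, curl, chord and cylinder volume, and deterministic
  scalar volumes (constant, axis gradient, two-region).

It does **not** emulate realistic diffusion signal, anatomy, scanner
physics, motion, spatially correlated noise, heteroscedasticity across age,
or realistic age densities. Passing tests therefore demonstrate that the
estimators recover the structure they target under clean, known conditions
— not that real acquisitions are free of effects the generator omits.

Desk-scale defaults are 100 subjects per cohort and B = 200; the published
cohort sizes (388/622/1062/717 pass-QA sessions) are available as a preset
for reconciliation.

## Numerical choices and degenerate inputs

* Voxel membership: `floor(v + 0.5)` in continuous voxel coordinates
  (centres at integers), half-open intervals; densification below half the
  smallest voxel size.
* Closed-loop bundles: span ~ 0 gives curl = NaN; head/tail splitting of a
  degenerate bundle is an error.
* Rank deficiency in a fit names the collinear design columns. Note a real
  degeneracy of the restricted basis: if the data span only ages above all
  interior knots, several basis columns coincide on the support and the fit
  correctly refuses.
* Extremum grid step 0.1 y; percentile quantiles are linear-interpolated
  (numpy default).
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical inputs and seed give byte-identical
  tables and hash-identical pipeline outputs (the run manifest stores
  SHA-256 of every numeric output).

## Problem sizes used in the shipped checks

The repository's own verification scales the study down: peak-age recovery
uses 20 simulated studies of 2000 sessions; bootstrap CI coverage uses 100
studies of 400 subjects with B = 200; harmonization recovery uses 20
studies of 200 subjects per cohort; the end-to-end determinism check runs
5 bundles x 4 features at 60 subjects per cohort with B = 50. These sizes
were chosen so that the whole suite verifies estimator behaviour (bias,
RMSE, coverage, exactness) at desk scale while every knob scales to the
full design by configuration.

## Known limitations

* The boundary-continuity offset estimator assumes a smooth trajectory and
  an additive, age-constant offset; a multiplicative or age-varying site
  effect would be mis-corrected.
* OLS ignores the within-subject correlation of infant sessions for point
  estimation (the bootstrap's resampling unit restores honest uncertainty);
  a mixed model is out of scope by design.
* Voxel-based volume and surface area are resolution-dependent and biased
  upward by roughly half a voxel of dilation around the true envelope —
  visible in the tube fixture, where the measured volume sits a few percent
  above the analytic cylinder.
* The extremum CI is a percentile-of-argmax bootstrap; argmax is a
  non-smooth functional and its bootstrap can undercover for very flat
  curves (coverage is verified on the simulated conditions shipped here).
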