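# Methods

This note documents the models implemented in `nichetrack`, their
assumptions, the defaults that matter, and the design choices made where the
methodology was genuinely open.  It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Geometry

All distances are great-circle on a sphere of radius 6371 km.  Trajectories
are planarised with an azimuthal equidistant projection centred at the
track's first fix, which makes distance from the origin exact; net squared
displacement computed in that plane therefore equals squared great-circle
distance from the origin, in km².  Steps *between* arbitrary fixes (trip
distance, hourly speed) use the haversine distance directly rather than the
projection, since migration steps can span large latitude ranges.

## Continuous-time correlated random walk filter

**Model.**  Velocity on each planar axis is an Ornstein–Uhlenbeck process
with autocorrelation rate β (h⁻¹) and noise intensity σ (km h⁻³ᐟ²);
position is its integral.  Axes are independent.  Over a step Δt the exact
discrete transition is

    F = [[1, (1 − e^{−βΔt})/β], [0, e^{−βΔt}]]

with the corresponding exact process-noise covariance (closed forms in
`crw.transition_matrices`).  Each fix is the true position plus isotropic
Gaussian error whose SD depends on its Argos location class; the defaults
are the standard accuracy tiers LC3 0.25, LC2 0.5, LC1 1.5, LC0 5.0 km, all
configurable and held fixed during fitting unless a common scale factor is
profiled (`estimate_meas_sd=True`).

**Linear, not extended.**  The filter runs on planar-projected coordinates,
where the observation model is linear.  At the spatial scale of a single
migratory track the projection linearises the spherical geometry, so no
extended filter is needed.

**Fitting and smoothing.**  The Gaussian prediction-error log-likelihood
from the Kalman recursion is maximised over (log β, log σ) with L-BFGS-B;
the log transform enforces positivity.  Initial state: position at the
first fix, velocity 0, diffuse variances 10⁴ km² (position) and 25 km²/h²
(velocity).  Error-reduced positions are the Rauch–Tung–Striebel smoother
output; positions at unobserved times are obtained by inserting those times
as missing observations (prediction only, no update), so interpolation and
extrapolation fall out of the same recursion and extrapolation variance
grows with distance from the data.  Tests verify the recursion against a
closed-form joint-Gaussian log-density on short tracks (10⁻⁸ relative),
that smoother variances never exceed filter variances, and that smoothing
reduces the median position error of Argos-corrupted synthetic tracks.

**Limitations.**  One behavioural state only (no migration/residency
switching); measurement error isotropic within a class; no parameter
uncertainty propagated into the smoothed positions.

## NSD sigmoid phenology models

The single (spring-only) and double (annual) logistic forms are given in the
README.  The annual curve *subtracts* the autumn limb so that it rises to
the plateau δ and returns toward zero — the rise–plateau–return shape that
an annual NSD series of a successful round trip actually has.  For
well-separated midpoints the curve is ≈ δ between θ_s and θ_a and ≈ 0
outside the migration season.

**Fitting.**  Trust-region nonlinear least squares (`scipy.optimize.
least_squares`, `trf`) with analytic Jacobians; the response is scaled by
max(NSD) so residuals are O(1); logistic terms are evaluated with `expit`
(no overflow however steep the limb).  Bounds: δ > 0, φ ∈ [10⁻³, 100] days,
midpoints within the observed span plus a buffer.

**Initialisation.**  δ₀ = max(NSD); θ₀ = the linear-interpolated crossing of
δ₀/2 (rising limb; the falling limb symmetrically for θ_a); φ₀ = the
interpolated quartile span (t₇₅ − t₂₅)/(2 ln 3), clipped to the bounds, with
5 days as fallback when no crossings exist.  The data-driven φ₀ matters:
reference fits include limbs as steep as φ_s = 0.08 day sampled daily, where
a fixed multi-day start value is two orders of magnitude off scale, while
the quartile rule starts within a factor of ~3 and the optimiser recovers
every reference parameter set to machine precision (the acceptance suite
checks 0.1% / 0.5%).

**Convergence flagging.**  A fit is flagged non-converged (never an
exception) when the optimiser fails, when the fitted plateau exceeds 4× the
observed maximum (the series never reached its asymptote), when the
midpoint falls far outside the data, or for a double fit when θ_s ≥ θ_a or
no falling limb exists.  Flat/degenerate series are flagged before fitting.

**Derived metrics.**  √δ (km) is the model-based migration distance; 2φ
(days) the duration surrogate.  For a logistic limb the time between
fractions q and 1−q of the plateau is 2φ·ln((1−q)/q); the quartile span is
2φ·ln 3 ≈ 2.2φ, and both 2φ and the analytic quantile crossings
t(q) = θ + φ·ln(q/(1−q)) are exposed rather than conflated.

**Timing rule.**  Visual/interactive determination of departure and arrival
is replaced by a deterministic rule: departure and arrival are the analytic
crossings of frac·δ and (1−frac)·δ on each limb, frac = 0.025 by default.
Crossings outside the observed span are flagged censored.  On synthetic
birds with a known migration onset the rule recovers the onset within 3
days in ≥ 90% of seeds (acceptance suite).

## Movement metrics

Hourly speed uses only steps whose time gap lies in the closed window
[30, 60] min (the duty cycle produces bursts of hourly fixes, so qualifying
steps exist year-round); speed = haversine step length / gap.  Seasonal
summaries average per-animal means — the animal is the sampling unit, which
avoids pseudo-replication from unequal step counts — with a normal 95% CI
across animals (undefined and flagged for a single animal).
Observed-vs-model regressions are ordinary least squares returning slope,
intercept and R².

## Climatic-niche overlap

**Ordination.**  The climate table (tmin, tmax in °C; precipitation in mm;
wind in m s⁻¹) is extracted at thinned (one random fix per day, seeded)
occurrence locations by nearest raster cell.  A PCA on the centred,
unit-variance pooled table (both seasons' backgrounds + occurrences) defines
the PC1–PC2 plane; the background of each season is all raster cells of that
season's region.

**Occupancy grids.**  On a shared R × R grid (R = 100) covering the pooled
score range plus a 10% margin, the occurrence density o and background
environment density e are product-Gaussian kernel densities evaluated at
cell centres.  Bandwidths follow Scott's rule per axis computed on the
occurrence set, and the *same* bandwidth is used for o and e: the corrected
occupancy is the ratio o/e, and a ratio of kernel estimates with unequal
bandwidths diverges in the tails (the wider kernel always wins), which
would put the occupancy maximum on kernel-tail noise at the support edge.
The support is further restricted to cells holding the top 95% of the
occurrence kernel mass (the conventional 5% occupancy-contour threshold)
in both corrected and uncorrected modes, and e is thresholded at 10⁻¹⁰ of
its maximum; outside these, z = 0.  z is rescaled to max 1.

**Indices.**  With p₁, p₂ the occupancies normalised to sum 1 over all
cells, D = 1 − ½ Σ|p₁ − p₂| and I = 1 − ½ Σ(√p₁ − √p₂)².  Both live in
[0, 1], equal 1 iff the normalised occupancies coincide, and 0 for disjoint
supports.  I ≥ D is *not* asserted anywhere (it is not guaranteed); the
tested property is that both decrease monotonically as one niche is
translated away from the other, and that D is stable (< 0.02) between
R = 100 and R = 200 on smooth niches.  The availability-corrected mode is
the default (it compares *selection* rather than raw occurrence, removing
differences in what climate is available in each region); the uncorrected
mode is retained for sensitivity analysis.

**One-variable overlap.**  For a single variable (wind speed) the overlap
is the shared area ∫ min(d₁, d₂) of the two 1-D kernel densities on a
common grid, each normalised to unit area.

## Synthetic data: what it emulates and what it does not

The trajectory generator places a winter range on the subtropical Gulf
coast and a summer range ~1700 km away on the northern plains.  Within a
range the bird relaxes toward the range centre (time scale 2 days) with
Gaussian steps of 4 km/day¹ᐟ²; from the spring onset (day 110 by default)
the attraction centre travels toward the summer range at 150 km/day and
returns from the autumn onset (day 270).  Sampling emulates the transmitter
duty cycle: bursts of 6 hourly fixes every 48 h for most of the year and
every 240 h from mid-June through September.  Argos classes are drawn with
probabilities (LC3, LC2, LC1, LC0) = (0.2, 0.3, 0.3, 0.2) and isotropic
error SDs (0.25, 0.5, 1.5, 5.0) km.  Within-range motion is a plain
attracted random walk, not a fitted movement model: the analyses consume
only the NSD shape (flat–rise–plateau–fall) and step statistics, which this
produces, so passing tests validate the analysis chain, not any biological
realism of small-scale movement.

Climate rasters are cellwise Gaussian draws per variable (precipitation and
wind truncated at zero by redrawing): winter tmin 4 ± 1, tmax 16 ± 1 °C,
precipitation 130 ± 12 mm, wind 3.33 ± 0.40 m/s; summer tmin 12 ± 1, tmax
27 ± 1 °C, precipitation 65 ± 8 mm, wind 3.26 ± 0.34 m/s.  Temperature and
precipitation separations of 4–11 SD make the two seasonal niches disjoint
in PC space (D = I = 0.00), while the wind distributions overlap ~0.9 —
the structure the overlap analysis is meant to resolve.  Real WorldClim
fields have spatial autocorrelation, topographic gradients and non-Gaussian
precipitation; none of that is emulated, so the synthetic tests say nothing
about extraction at real-raster resolution.

An "identical climate" control draws both seasons from the winter
generator; the corrected D then reflects only kernel sampling noise and
sits near 0.85 at study-scale occurrence counts (~2000), which is what the
end-to-end control test asserts (> 0.8).

## Problem sizes and determinism

Every generator draws from `numpy.random.default_rng` seeded from its
configuration, so all outputs are reproducible bit-for-bit; the pipeline
writes all numeric reports at 6 significant digits and is byte-identical
under a fixed seed.  The test suite uses 20-seed replicate studies for the
filter (tracks of 250–400 fixes) and 50 synthetic birds for the timing
rule; recovery checks on the sigmoid models use 0.1-day (spring) and daily
(annual) sampling, matching the scales at which the reference fits are
tabulated.
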