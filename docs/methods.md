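# Methods

This note records the models implemented, the defaults and why, the
numerical choices, and what the synthetic world does and does not
establish.

## Geodesy

Coordinates are WGS84 decimal degrees; bearings degrees clockwise from true
north; all internal angle arithmetic in radians. Spherical formulae
(haversine, destination point, initial bearing) use a mean Earth radius of
6,371,000 m. Between-fix distances use Vincenty's inverse formula on the
WGS84 ellipsoid (a = 6,378,137 m, f = 1/298.257223563), iterated to 1e-12
on the auxiliary longitude with a 200-iteration cap; the rare
near-antipodal non-convergence falls back to the spherical value with a
warning. At the package's working scale (pairs under 10 km at mid
latitudes) spherical and ellipsoidal distances agree to well under 0.5%;
note this is a property of the mid-latitude band, not of the globe — at
the equator the meridional radius of curvature (6,335 km) differs from the
mean sphere by 0.56%.

## Shore-based raft geolocation

The inclinometer geometry is a right triangle: observer eye height above
the instantaneous sea surface is `C + H − T` (cliff height + instrument
height − tide height; a higher tide raises the sea toward the observer),
and the horizontal range is that height divided by `tan(declination)`.
The four packaged station cliff heights are 64.1 m (Garland Stone), 66.7 m
(Skomer Head), 63.7 m (South Haven) and 49.0 m (North Haven); the
instrument height defaults to 0.895 m. Earth curvature and refraction are
ignored: from 50–67 m cliffs at 2 km range the effect is below 0.3 m,
far inside the angular reading error. Magnetic bearings are taken as true
by default; a configurable declination offset is provided.

Rafts ranged at or beyond 2,000 m are flagged `retained = False`. The
comparison carries a 1 µm guard band so that a range reconstructed to
within numerical noise of the boundary counts as at the boundary.

Distance to shore is the minimum haversine distance to the island
boundary densified at 10 m spacing (vertex-only distances can overstate
the clearance by half an edge length). Tide and weather records are
matched to observations by nearest timestamp, ties toward the earlier
record; gaps beyond 3 h are flagged rather than dropped.

## Speed mixture and behavioural classification

Speeds are pooled across birds and modelled as a two-component normal
mixture fitted by EM (relative log-likelihood tolerance 1e-8, 1,000
iteration cap). Initialisation is quantile-based — component means at the
25th/75th percentiles, pooled sd, equal weights — plus four jittered
restarts from a seeded generator; the best log-likelihood wins, and the EM
monotonicity of the log-likelihood is asserted each iteration. Components
closer than one pooled sd are flagged `poorly_separated`. The
classification threshold is the equal-posterior speed, found by bracketed
root finding (Brent) on the log-density difference in (μ₁, μ₂); for equal
weights and variances this reduces to the midpoint.

Labelling is strict: speed < threshold → rafting, otherwise flying;
segments above 30 m/s are marked excluded (never silently dropped).
Behaviour is attributed to the segment's **end** fix. Day/night uses the
NOAA solar-position equations with the standard −0.833° rise/set
convention; the study radius is 5 km around the North Haven colony
(51°44′14.0″N, 5°16′55.5″W), tested with strict inequality.

## Circular statistics

Von Mises concentration solves `A(κ) = I₁(κ)/I₀(κ) = R̄` by bracketed
root finding (tolerance 1e-10) using exponentially scaled Bessel
functions; degenerate samples (R̄ at the saturation point) cap κ at 1e6
with a warning. The Jammalamadaka–Sarma correlation uses sines of
deviations from the circular means; the test statistic
`z = √(n λ₂₀ λ₀₂ / λ₂₂) · r` is referred to the standard normal,
two-sided. Because per-stratum sample sizes can be modest, a seeded
permutation p-value (shuffling one margin) is available alongside the
asymptotic one. Wind directions are used as reported by weather stations
(direction the wind comes from); the "rafting direction" is the bearing
from the colony/island centre for shore observations and the segment
travel bearing for GPS data — both conventions are explicit arguments.

## Raft-size model

`log(size) ~ wind speed` with errors correlated within Julian day. The
correlation structure is MA(4): the printed coefficient table of the
source analysis labels the structure ARMA(0,4) even though its text says
four autoregressive parameters; this implementation follows the table and
offers AR(4) as an option. The natural log is used (an intercept near 4.7
corresponds to raft sizes around exp(4.7) ≈ 110 birds, consistent with
the data scale). Within-day ordering of the MA lags follows observation
timestamp.

Given θ, each day's correlation matrix is Toeplitz from the MA
autocovariances; β and σ² are profiled out by whitened least squares, and
θ is maximised by Nelder–Mead (5 seeded restarts, log-likelihood
tolerance 1e-8) in the Jones (1980) reparameterisation, which maps R⁴
onto the invertibility region. REML is the default criterion (ML
available); standard errors come from (XᵀV⁻¹X)⁻¹, t statistics on n − p
degrees of freedom. AIC = 2k − 2ℓ with k = 7 (two coefficients, four θ,
one scale); BIC uses log(n − p) under REML and log(n) under ML,
matching the conventions of the standard mixed-modelling software this
reproduces. With q = 0 the fit reduces exactly to OLS, which the tests
check against an independent OLS route. Standardized residuals are the
whitened residuals divided by σ̂ (unit variance under the model).

## Diel trends

Both smoothers use a periodic cubic B-spline basis on [0, 24) hours
(default 12 knots; the basis columns wrap, rows sum to one) with a
wrapped second-order difference penalty, so constants are unpenalized and
a large smoothing parameter collapses the fit to the intercept. Counts
use a Poisson log-link fit by penalized IRLS with the smoothing parameter
chosen by deviance-based GCV over a log-spaced grid; distance from shore
uses a Gaussian fit with a per-bird random intercept entering as a
ridge-penalized dummy block, the bird variance updated by an EM-type
iteration (ridge weight σ²/σ_b² at each step). Pointwise 95% bands come
from the Bayesian posterior covariance (A⁻¹ scale), whose average
coverage for penalized splines is close to nominal and errs mildly
conservative.

The source analysis describes Poisson models for both responses; Poisson
is ill-matched to continuous distances, so this package uses Gaussian for
distance and Poisson for counts. Users wanting strict fidelity can round
distances to integer metres and use the Poisson smoother.

## Synthetic world

The generators state one fixed world rather than tunable scenery:

- **Tracks**: a two-state Markov chain per bird (rafting↔flying switch
  probabilities 0.04/0.10 per 5-min step), speeds drawn from N(1.0, 0.5)
  (rafting) and N(9.0, 2.5) (flying) truncated at zero — chosen so the
  equal-posterior boundary lands near 2.5 m/s, as a fixture convention.
  Headings are von Mises with persistence, rafting headings drifting
  slowly; birds steer toward a target ring around the island whose radius
  is 900 m by day and 300 m by night, producing a daytime halo that
  closes at night.
- **Island**: a 1 km-radius circle (180 vertices) centred on the colony,
  so distance-to-shore has the closed form `distance − radius` for
  oracle tests. Four stations sit on its rim with the packaged cliff
  heights.
- **Observations**: the inclinometer geometry inverted exactly from true
  raft positions (optional Gaussian declination noise), tides a 2 m
  semidiurnal sinusoid.
- **Wind**: daily means N(8, 3.5) with hourly wobble, clipped to the
  observed 2.1–17.6 m/s range; directions von Mises about west.
- **Sizes**: log size = 4.674 + 0.065·wind + MA(4) noise with
  θ = (0.088, 0.162, 0.185, 0.162) and marginal sd 1.146, nested within
  day; sizes exponentiated and rounded up to ≥ 1 bird.

What the synthetic world does **not** emulate: foraging-trip structure
and colony-attendance cycles (so day/night rafting shares need not match
field proportions), tidal-current advection of rafts, observer
miscounts, GPS fix dropout, and real shoreline complexity. A green test
therefore establishes that the estimators recover the stated structure,
not that any field dataset would show it.

## Numerical edge cases

- Duplicate GPS timestamps collapse to the first fix with a logged
  warning; non-increasing timestamps are an error naming the bird.
- Zero-resultant angle samples make the circular mean (and the JS
  statistic's centring) undefined and raise rather than guess.
- Degenerate EM components (σ → 0) trigger a restart; if all restarts
  degenerate, fitting fails loudly.
- Non-invertible θ proposals are rejected inside the optimiser via the
  reparameterisation; user-supplied θ are checked against the unit
  circle explicitly.
- The GLS likelihood caches one Cholesky per distinct day-block size and
  batches the triangular solves, which is what keeps 500-replicate
  simulation studies inside a few minutes.

## Known limitations

- The Vincenty fallback (spherical value on non-convergence) loses the
  ellipsoidal correction exactly where it is largest (near-antipodal
  pairs); irrelevant at nearshore scales but documented.
- GCV occasionally undersmooths sparse count series; the smoothing
  parameter can be fixed explicitly in that case.
- The random-intercept variance uses an EM-type update inside penalized
  least squares, not a full REML mixed-model fit; simulations recover a
  200 m between-bird sd within 25% at 50 birds, which is adequate for
  the descriptive use here.
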