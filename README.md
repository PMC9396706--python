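# nichetrack

Migration phenology and seasonal climatic-niche overlap from satellite
telemetry of migratory birds.

`nichetrack` is for movement ecologists asking whether a migrant *tracks* a
similar climatic niche year-round or *switches* niches between its breeding
and non-breeding grounds — the kind of question raised by waterbirds such as
cormorants that winter on a subtropical coast and breed 1000–2300 km away in
the northern temperate zone.  It chains the four analysis stages such a study
needs, each usable on its own:

1. **Location-error filtering** (`nichetrack.crw`).  Argos-class satellite
   fixes carry hundreds of metres to kilometres of error.  A continuous-time
   correlated random walk (integrated Ornstein–Uhlenbeck velocity) is fitted
   by maximum likelihood with a Kalman filter — each planar axis is a
   2-state (position, velocity) linear-Gaussian system with the exact
   transition over every irregular time step and class-specific measurement
   variances — and error-reduced positions come from the RTS smoother.
2. **Migration phenology from net squared displacement** (`nichetrack.nsd`).
   NSD(t), the squared distance from the trajectory's first fix, is flat
   within a seasonal range and sigmoid through migration.  Two models are
   fitted by nonlinear least squares:

   single (spring only):  NSD(t) = δ / (1 + exp((θ − t)/φ))

   double (annual):       NSD(t) = δ / (1 + exp((θ_s − t)/φ_s))
                                  − δ / (1 + exp((θ_a − t)/φ_a))

   with δ the plateau (km²), θ the midpoints (day of year) and φ the
   logistic time scales (days).  √δ is a surrogate of migration distance,
   2φ of migration duration, and departure/arrival dates come from analytic
   threshold crossings of the fitted curve.
3. **Movement metrics** (`nichetrack.movement`): hourly speed from steps
   with 30–60 min gaps, along-track trip distance, per-animal seasonal
   summaries with 95% CIs, observed-vs-model OLS regressions.
4. **Climatic-niche overlap** (`nichetrack.niche`): climate (tmin, tmax,
   precipitation, wind) extracted at thinned occurrence locations, PCA
   ordination of the pooled climate table, kernel-smoothed occupancy on a
   100 × 100 grid of the first two PCs, and the overlap indices
   Schoener's D = 1 − ½ Σ|p₁ − p₂| and Hellinger-based
   I = 1 − ½ Σ(√p₁ − √p₂)², both in [0, 1].

A seeded synthetic-data module (`nichetrack.synthdata`) generates migratory
trajectories with duty-cycled sampling and Argos-class noise, NSD curves,
and paired seasonal climate rasters in which temperature and precipitation
are strongly separated while wind speed is nearly identical — so the whole
chain can be exercised and validated end to end without any external data.

## Worked example

Fit the spring migration model to a noisy NSD series and derive the
migration metrics:

```python
import numpy as np
from nichetrack import (SingleSigmoidNSD, single_sigmoid,
                        derive_migration_metrics, segment_timing)

t = np.arange(1.0, 250.0, 0.5)                      # day of year
rng = np.random.default_rng(0)
nsd = single_sigmoid(t, 2.4e6, 118.0, 4.2) + rng.normal(0, 5e4, t.size)

fit = SingleSigmoidNSD().fit(t, nsd)
print(f"delta = {fit.delta_:.0f} km^2   theta = {fit.theta_:.2f}   "
      f"phi = {fit.phi_:.2f}   converged = {fit.converged_}")
m = derive_migration_metrics(fit)
print(f"migration distance sqrt(delta) = {m['sqrt_delta_km']:.1f} km")
print(f"duration surrogate 2*phi = {m['two_phi_days']:.2f} days")
tm = segment_timing(fit, frac=0.025)
print(f"spring departure day {tm.spring_departure:.1f}, "
      f"arrival day {tm.spring_arrival:.1f}")
```

prints

```
delta = 2397984 km^2   theta = 118.07   phi = 4.20   converged = True
migration distance sqrt(delta) = 1548.5 km
duration surrogate 2*phi = 8.39 days
spring departure day 102.7, arrival day 133.4
```

The fitted plateau of ~2.4 × 10⁶ km² corresponds to a ~1550 km migration;
the bird crossed half of it on day 118, spent ~8.4 days between the ¼ and ¾
displacement quantiles, and by the 2.5% threshold rule departed on day 102.7
and arrived on day 133.4.

The full pipeline (simulate → filter → NSD fits → timing → speeds → niche
overlap) is also available from the shell:

```sh
nichetrack run-all --seed 1 --out results/
```

which writes `tracks.csv`, `tracks_filtered.csv`, `nsd_fits.json`,
`timing.csv`, `speeds.csv`, `overlap.json` and a `manifest.json` recording
per-stage status.  With the default synthetic climates the overlap report
shows `schoener_D: 0.0` and `hellinger_I: 0.0` (separated seasonal niches)
while the one-dimensional wind-speed overlap stays near 0.89.

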