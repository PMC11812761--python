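# Methods

## Model structure

The package compares two states of the world for every raster cell *x*
with population density ρ(x) > 0 and one-way travel time t(x) minutes to
the nearest emergency-capable facility:

* **No ambulance** — the patient arranges informal transport:
  `t0 = t + τ`, with τ the Rayleigh waiting delay described below.
* **Ambulance** — a vehicle leaves a hub located at the facility, drives
  to the patient and back: `t1_amb = 2·s·t + θ`, with speed multiplier
  s ∈ (0, 1] and call-out delay θ (default 0; θ > 0 is a hook beyond the
  base model, which assumes immediate dispatch).

Survival of the emergency is `S(t) = exp(−λt)`; the expected annual lives
saved are

    Δ = Σ_x cases(x) · [p1·S(t1(x)) − p0·S(t0(x))],

with cases(x) = ρ(x) · cell area · (birth rate/1000) · incidence fraction,
and p0, p1 the care-seeking proportions without/with the service
(supply-induced demand; both default 1).

Simplifying assumptions baked into the defaults: the hub is centralised at
the facility; informal transport starts at the patient's location; no
clinical care is delivered in the vehicle (the ambulance affects survival
only through time); θ = 0.

## Waiting delay

τ(x) ~ Rayleigh with mean `β/√ρ(x)`.  β (minutes) is the mean waiting
delay where the density is 1 person/km²; the √ρ scaling is the
nearest-available-vehicle distance in a Poisson field of vehicles whose
intensity is proportional to population density.  The Rayleigh scale is
σ = (β/√ρ)·√(2/π).  At the reference density of 137 persons/km² the means
for β = 60…300 are 5.1, 10.3, 15.4, 20.5, 25.6 minutes, which is the
calibration the defaults are anchored to.

The probability that the ambulance improves the transfer,
`q(x) = Pr[τ > (2s−1)·t]`, is the Rayleigh survival function at the
threshold; q ≡ 1 when s ≤ 0.5 (the round trip cannot lose) or t = 0, and
q is defined as 0 on unreachable cells (t = ∞), where neither mode can
deliver the patient.

## Transfer-choice rules

* `fastest` — t1 = min(t0, 2st): an upper bound on benefit (perfect
  information); per-replication Δ is provably ≥ 0.
* `ambulance` — t1 = 2st: everyone waits for the ambulance; Δ can be
  negative when informal transport is quick to find.
* `random` — a fraction w (default 0.5) takes the ambulance.  Implemented
  as the w-mixture of survival probabilities rather than per-individual
  Bernoulli assignment: cells carry *expected* fractional case counts, so
  the mixture is exact in expectation and lower-variance.

## Parameters, units, defaults

| key | meaning | unit | default |
|---|---|---|---|
| `delay.beta` | mean waiting delay at ρ=1 | min | [60, 120, 180, 240, 300] |
| `speed.s` | ambulance time multiplier | — | [0.6, 0.7, 0.8, 0.9] |
| `survival.lambda_mean` | survival rate | /min | 0.056 |
| `survival.lambda_sd` | sd of λ draw | /min | 0.01 |
| `incidence.gamma_shape` | Gamma shape | — | 2 |
| `incidence.gamma_scale` | Gamma scale (draws = % of live births) | % | 0.5 |
| `incidence.birth_rate_per_1000` | crude birth rate | /1000/yr | 27.5 |
| `careseeking.p0`, `p1` | care-seeking without/with service | — | 1, 1 |
| `scenario.choice_rule` | fastest / ambulance / random | — | fastest |
| `monte_carlo.n_reps` | replications | — | 10000 |
| `travel.edge_cost` | edge friction rule | — | mean |
| `travel.connectivity` | grid neighbourhood | — | 8 |
| `tau_mode` | sample / expectation | — | sample |

λ = 0.056/min is anchored to an elicited severe-PPH survival of ~0.16 at
the longest plausible transfer times (exp(−0.056·32.7) ≈ 0.160); because
the anchoring arithmetic admits more than one reading of the time scale,
λ is treated as a direct input rather than derived.  The distribution of
λ is Normal(mean, sd) truncated to positive values by rejection —
clipping would create an atom at 0 — with sd defaulting to 0.01, which
spans roughly the elicited survival band without meaningful truncation
(the mean sits 5.6 sd from zero); a warning fires if > 10 % of the mass
is negative.  Incidence draws are divided by 100: the Gamma(2, 0.5) is
specified in percent (mode 0.5 %) while the case arithmetic needs a
fraction.

## Travel-time computation

Moving between adjacent cells costs `d(i,j) metres × f(i,j) min/m`, with
d the centre-to-centre distance (cell size orthogonally, ×√2 diagonally,
×√5 for the optional knight's moves of 16-connectivity) and f the
arithmetic mean of the two cells' frictions.  Cost-distance
implementations differ on the combining rule, so `min` and `max`
variants are exposed rather than hard-coded.  The surface is the
multi-source Dijkstra distance (scipy.sparse.csgraph) from all facility
cells at time 0; nodata friction is impassable; unreachable cells get
+inf, contribute zero to both scenarios, and are counted in the run log.
A pure-Python exhaustive-relaxation oracle (≤ 5×5 grids) provides an
independent check in the tests.

All area/distance arithmetic uses an equal-area approximation from the
transform's cell size in km, with a `cell_area_km2` config override for
geographic-CRS rasters; at ~1 km resolution this is adequate and exact
geodesy is out of scope.  Facilities are snapped to the nearest cell
centre; grids are north-up with cell-centre semantics.

## Monte Carlo design

Per replication: one incidence fraction and one λ drawn globally, one τ
per populated cell (cell-level draws match the spatial resolution of the
other inputs).  Replications run on independent child streams
(`numpy` SeedSequence spawning, PCG64), so results are bit-reproducible
across runs and platforms given the seed.  τ is drawn as a unit-Rayleigh
deviate scaled by σ(β, ρ): over a β × s results grid every combination
reuses the same seed (common random numbers), so the deviates are shared
and only the scale changes, making the grid's qualitative monotonicities
(benefit non-decreasing in β, non-increasing in s under `fastest`) hold
replication by replication rather than merely in expectation.

`tau_mode: expectation` replaces the τ draw by a 256-node quantile
average of the Rayleigh — a variance-reduction option that leaves the
mean unchanged.  Credible intervals are equal-tailed percentiles
(2.5/97.5) of the replication draws; the percentile estimator is the
natural reading where the interval construction is otherwise
unspecified.  A deterministic quadrature oracle (adaptive integration of
the survival difference over the Rayleigh density at fixed λ and mean
incidence, single cell) cross-checks the Monte Carlo path in the tests.

## Synthetic data

The generator emulates the qualitative structure of WorldPop density and
Weiss-style friction surfaces: Gaussian "towns" (peak ~2000 persons/km²,
sd 3 km, truncated at 4 sd) on a 5 persons/km² background; straight road
corridors at 0.0012 min/m (~50 km/h) between town centres across
0.03 min/m (~2 km/h, walking-pace) terrain; facilities in the largest
towns, which reproduces the empirical pattern that density is high near
hospitals.  Town amplitudes are drawn U(0.5, 1)×peak so "largest town" is
well defined.  What it does *not* emulate: realistic road-network
topology, seasonal/diurnal travel-time variation, spatially varying
incidence, and the measurement error of friction-surface travel times —
so passing tests demonstrate the estimator's internal correctness and
qualitative behaviour, not calibration to any real region.  Reproducing a
real region's absolute lives-saved numbers requires that region's actual
density and friction rasters as user inputs.

## Numerical choices and degenerate inputs

* Zero/nodata density cells carry no population: excluded from integrals
  (not given infinite delay).
* Grid alignment is enforced to 1e−9 on transforms and cell sizes.
* Per-replication conservation (Δ = Σ per-cell map) holds to 1e−9
  relative and is asserted in tests.
* GeoTIFF round trips are bit-exact for the stored dtype; +inf is not
  representable in the nodata tag, so unreachable cells are written as
  nodata and restored to +inf on load by the simulate pipeline.
* β → 0 degenerates τ to 0 exactly in both the sampler and the oracle.

## Test problem sizes

The suite exercises the estimator on 30×30–50×50 synthetic regions with
100–1000 replications, the oracle-equivalence checks on single cells with
10⁵ replications, and the Dijkstra/brute-force equivalence on 100 random
≤ 5×5 grids — sizes chosen to make every property sharply testable while
keeping the whole suite under a minute of compute.

## Known limitations

Beyond the synthetic-data caveats above: no paramedic effect on λ, no
ambulance queueing (θ is a scalar hook only), scalar p0/p1 (no
supply-induced-demand distributions), static facility hubs, a single
condition per run (sum independent runs for multiple conditions), and no
reprojection — inputs must share a grid.
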