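# Methods

## Burn-trace reduction

A trial is six thermocouple series (1 center, 5 outer on a 6.25 cm circle
inside a 25 cm diameter × 3 cm deep mesh ring), nominally sampled at 1 Hz,
plus mass records. All crossing times are linearly interpolated between
bracketing samples; no smoothing or denoising is applied beyond that.

* **Ignition** is the first time any sensor reaches 50 °C. The center
  sensor participates in the start because the ignition source (an
  ethanol-soaked cotton disk) sits at the center; the intensity metrics
  (maximum temperature, temperature sum) use only the five outer sensors.
* **Extinction** is the last interpolated downcrossing of 70 °C across all
  sensors. The extinction threshold deliberately exceeds the ignition
  threshold (a flame holds the sensors well above both; the asymmetry
  guards against declaring extinction during slow smoulder). A trace that
  peaks in [50, 70) therefore yields burning time 0, which is logged.
* **Fire front speed** takes each outer sensor's arrival as its first
  50 °C crossing — the same flame-presence criterion as ignition, there
  being no separate published arrival criterion — and averages
  radius/delay over arriving sensors. Arrivals before source ignition are
  an input error.
* **Temperature sum** subtracts, per outer sensor, the mean of that
  sensor's samples before fuelbed ignition (its baseline), then integrates
  the across-sensor mean excess over the burn window by the trapezoid
  rule, which at exactly 1 Hz equals the per-second sum. Negative
  excesses are not clipped: the operation stays linear, so the result is
  exactly invariant to constant per-sensor offsets. Trials without
  pre-ignition samples fall back to the first sample as baseline, with a
  warning.
* **Mass loss** reconstructs pre-burn oven-dry mass from air-dry mass and
  moisture content per component; results are clamped to [0, 100]% with a
  warning if the residue exceeds the reconstruction.
* **Flammable** means the fire reached the ring edge and mass loss
  exceeded 40%. When edge arrival was not recorded, it is proxied by all
  five outer sensors having ignited — the only in-data signal of full
  lateral spread.

## Fuelbed traits

Packing ratio is total particle volume over bed volume, with particle
volume = air-dry mass × (1 − moisture) / tissue density; tissue density is
oven-dry mass over saturated-displacement volume (no shrinkage correction
from saturated to air-dry volume is attempted). Mixture particle volumes
are additive — observed nonadditive flammability is interpreted
downstream, never baked into the trait calculus. Particle size is the
product length × width × height in cm³, averaged over representative
small/medium/large particles as the mean of products; log10 size is used
only in the statistical layer. The identity
packing density = packing ratio × tissue density / (1 − moisture) holds to
machine precision and is property-tested.

## Mixture effect sizes

ES(%) = 100·(observed − expected)/expected. Monoculture reference values
are replicate means per species; effect sizes are computed per mixture
replicate against those means and then averaged per pair, giving one value
per pair and parameter. The volume-weighted expectation is the plain mean
(50:50-by-volume design); the mass-weighted one uses the measured
half-ring masses. A monoculture that never ignited contributes front
speed 0 to the expectation; where an expectation is exactly 0 the ES is
recorded as missing, not infinite. The clade partition defaults to the
non-*Pinus* Pinaceae codes (AbVe, LaEu, PiAb) and is configurable.

## Statistical layer

* **Pearson**: product-moment r, two-sided p from t with n−2 df; zero
  variance is an error, not NaN.
* **Logistic threshold**: the descending curve
  p(x) = 1/(1+exp(b(x−x₅₀))) is fit to species-mean proportions burned by
  quasi-binomial deviance minimisation (Nelder–Mead over a slope ×
  midpoint start grid; slope capped at 200 per point). Per-trial success
  counts do not exist, so proportions are treated as quasi-binomial;
  species means (not replicates) are the default unit. Separation —
  responses all on one side, or an effectively perfect binary split — is
  flagged, not raised, since the boundary fit is still informative. The
  reported transition interval is (x at p=0.9, x at p=0.1) = x₅₀ ∓ ln(9)/b.
  The likelihood-ratio test against the intercept-only model gives the
  slope p-value. Note the fitted slope is attenuated when the data violate
  the binomial variance structure (e.g. additive noise at the plateaus, or
  species means of few all-or-nothing replicates): the midpoint stays
  accurate but the fitted interval is then wider than the generating one.
* **Gaussian response**: a·exp(−(x−μ)²/2σ²) + baseline by least squares,
  multi-started over data quantiles of μ and spreads of σ; constant
  responses are rejected (σ unidentifiable).
* **Two-way ANOVA**: |ES| on weighting × clade membership, main effects
  only with type-II sums of squares (matching a two-F-row report; an
  interaction term is available by flag). Zero residual variance flags
  infinite F rather than failing.
* **PCA**: log10 transform of named columns, z-standardisation,
  eigendecomposition of the correlation matrix; per axis the
  largest-|loading| variable is made positive. Variance shares sum to
  100% and are permutation-invariant; both are tested.
* **Per-type OLS**: packing ratio on log10 particle size within litter
  types, significance starred at p < .01; groups under 3 points are
  skipped with a warning.

No multiple-testing correction and no phylogenetically corrected
regression (PGLS/PIC) are applied: the analysis design uses raw Pearson
correlations throughout.

## Synthetic experiments

The generator emulates the laboratory design: by default 34 species and 34
random pairs burned once per block in 5 blocks (340 trials), room
temperature 18 ± 2 °C, 1 Hz sampling. Trait ranges are the realistic
laboratory ranges: tissue density U(0.08, 0.59) g/cm³, air-dry moisture
U(0.03, 0.11); three "dense" short-needle species pack above the
flammability threshold (target packing ratio U(0.20, 0.32)) while the rest
span U(0.02, 0.18), so most of the pool is flammable. Two moss species
carry no particle size.

Mechanism: ignitability is logistic in packing ratio,
p = expit(−75·(β − 0.16)), i.e. a 16% threshold whose 0.9/0.1 interval
spans ≈13–19% packing ratio — inside the sharp 12–20% transition such
experiments report. Ignited beds burn almost entirely (mass loss
U(92, 100)%); failed beds lose U(0, 8)% and only the central cotton disk
registers. Front speed decreases and burn duration increases with packing
density; peak temperature declines with packing ratio from an optimum at
low packing. Thermocouple pulses are a 10 s linear rise, 4 s plateau and
exponential decay plus 0.5 °C Gaussian sensor noise — any pulse shape
satisfying the crossing-time contract would do, and all shape parameters
live in the config. Ground truth (front speed, analytic flame window,
peak, mass loss, packing) is emitted per trial; the pulse "temperature
sum" truth is the untruncated pulse integral and is therefore only an
approximation to the windowed metric (it is not used in recovery
tolerances).

Mixtures pack additively; a per-pair dominance coefficient δ shifts the
ignition propensity by 6δ logit units before the draw, so nonadditivity
emerges through the same threshold mechanism the analysis probes
(positive δ: the flammable partner spreads the dense needles out; negative
δ: the needles fill the partner's air spaces). With δ ≡ 0 and an
all-flammable pool, mass-loss effect sizes are exactly additive-null by
construction; rate and intensity parameters inherit the mild curvature of
their packing-response maps, so their null effect sizes are centered only
approximately. Each trial draws from its own counter-indexed substream of
the master seed: regenerating with a different δ re-uses the same
uniforms, which keeps dominance sweeps monotone (common random numbers).

The phylogeny is a pure-birth tree conditioned on the species count (tip
branches extended by one exponential waiting time so no pair sits at zero
distance), scaled to a 350 My root age and ultrametric by construction.
Packing is by default decoupled from the tree; a conservatism knob blends
species packing toward the rank order of a Brownian trait evolved on the
tree, and a "linear response" switch softens the ignition logistic
five-fold (a gradual, near-linear decline) — together these let tests
demonstrate that relatedness predicts nonadditivity only when the trait is
conserved *and* the response is smooth, and that the sharp threshold
destroys that signal.

What the generator does **not** emulate: combustion chemistry, wind,
moisture dynamics during the burn, sensor dropout, partial lateral spread
(burns are all-or-nothing at the trial level, so fitted logistic slopes on
generator data are attenuated relative to the generating curve — see
above), or ≥3-species mixtures. Passing recovery tests therefore shows the
reduction pipeline is correct and calibrated on threshold-governed data,
not that real burns follow these pulse shapes.

## Problem sizes and numerical choices

Tests and the acceptance script use: 10 random piecewise-linear trials for
the exact oracle comparisons (agreement ≤ 1e−9 relative); 105 mono burns
(~100 flammable) with full traces for metric recovery (tolerances: speed
5%, peak 2%, window 3 s, mass loss exact); a 40-species proportions
scenario (slope 1.5 per point, midpoint 16%, mean-preserving beta noise,
sd 0.05 at the transition) for threshold recovery; 200 pairs for the
additive-null check and 5000 replicates of n = 34 for the 5%-type-I
calibration; and the default 340-trial design for the degrees-of-freedom
and distance-correlation outputs. Optimiser settings (Nelder–Mead xatol
1e−8, multi-start grids) are fixed in code; all randomness flows from a
single seed argument.

## Known limitations

Extinction detection assumes the trace ends below 70 °C; a recording cut
mid-burn truncates the window at the last sample. The quasi-binomial
logistic is fit to proportions without replicate weights. The reached-edge
proxy (all outer sensors ignited) can misclassify a burn that spreads
asymmetrically past the sensors. Tip-label matching between trait tables
and trees is exact string match.
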