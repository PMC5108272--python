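# litterflame

Laboratory litterbed flammability analysis: from raw thermocouple burn
traces and litter trait measurements to species flammability parameters,
two-species mixture nonadditivity, packing-ratio thresholds, and
phylogenetic-distance prediction.

## The problem

Surface fires run on shed plant litter. How well a litterbed burns depends
strongly on how it packs: large particles build open, well-aerated beds
that carry fire; small solitary needles (typical of *Picea*, *Abies*,
*Larix* — the non-*Pinus* Pinaceae) build dense beds that suffocate it.
Because packing responds to particle size through a sharp oxygen-limitation
threshold, a 50:50 two-species litter mixture need not burn like the
average of its components: a handful of small needles can extinguish a
flammable partner's bed, or large particles can open up a dense one. This
package implements the full analysis pipeline for ring-burn experiments
that quantify these effects, plus a mechanistic synthetic-burn generator so
every stage is testable against known ground truth (raw data from such
experiments are rarely deposited).

## What it computes

**Flammability parameters per ring burn** (`litterflame.burn_core`), from
six thermocouple traces (1 center + 5 outer at radius 6.25 cm in a
25 cm x 3 cm ring) and mass records:

* total burning time (s): fuelbed ignition (first sensor ≥ 50 °C,
  interpolated) to the last interpolated 70 °C downcrossing;
* fire front speed (cm/min): sensor radius over the flame's arrival delay
  from the central ignition source, averaged over arriving outer sensors;
* maximum temperature (°C): mean of the five outer sensors' maxima;
* temperature sum (°C·s): integrated outer-sensor excess over each
  sensor's pre-ignition baseline across the burn;
* mass loss (%): oven-dry-equivalent consumption, with
  pre-burn oven-dry mass = air-dry mass × (1 − moisture content);
* classification: flammable ⇔ fire reached the ring edge **and** mass
  loss > 40%.

**Fuelbed traits** (`litterflame.fuelbed`): tissue density ρ (g/cm³),
packing density = mass / bed volume, and packing ratio
β = mass·(1−mc)/ρ / bed volume (particle volumes additive in mixtures).

**Mixture nonadditivity** (`litterflame.mixtures`): for each species pair
and parameter, ES(%) = 100·(observed − expected)/expected, with the
expectation either volume-weighted (plain mean of the monoculture values;
the design is 50:50 by volume) or mass-weighted; pairs partitioned by
focal-clade membership (default: the non-*Pinus* Pinaceae).

**Phylogenetic distance** (`litterflame.phylo`): patristic distance in
million years on a rooted, dated Newick tree (twice the divergence time on
an ultrametric tree).

**Inference** (`litterflame.stats`, `litterflame.analysis`): Pearson
correlation with t test on n−2 df; descending quasi-binomial logistic
threshold p(β) = 1/(1+exp(b(β−β₅₀))) with its 0.9/0.1 transition interval;
Gaussian response of maximum temperature to packing; two-way type-II ANOVA
of |ES| on weighting × clade; correlation-matrix PCA; per-litter-type OLS.

**Synthetic experiments** (`litterflame.synth`): a species pool with
realistic trait ranges, a pure-birth dated phylogeny, and mono +
50:50-mixture burn trials whose thermocouple pulses, ignition logistic
(threshold 16% packing ratio), dominance coefficients and mass-loss
plateaus are all ground truth for recovery tests.

## Worked example

```bash
python examples/01_burn_metrics.py
```

prints (seeded, reproducible):

```
species S06 (long_needle), packing ratio 9.4%
total burning time :   154.9 s   (truth 154.9)
fire front speed   :    6.49 cm/min (truth 6.56)
max temperature    :   605.3 °C  (truth 604.5)
temperature sum    :   24976 °C·s
mass loss          :    96.8 %   (truth 96.8)
flammable          : True
```

i.e. a well-aerated needle bed (packing ratio 9.4%, below the ~16%
threshold) carries fire at ~6.5 cm/min, burns for ~2.5 minutes at ~600 °C
and consumes ~97% of its fuel — and the pipeline recovers the generator's
ground truth within its stated tolerances. The other examples cover
mixture effect sizes (`02`), phylogenetic distances (`03`), threshold
fitting (`04`) and the full file-to-file pipeline (`05`).

The same steps are available as a thin CLI:

```bash
litterflame simulate --seed 11 --out data/
litterflame metrics --traces data/traces.csv --trials data/trials.csv --out metrics.csv
litterflame mix --metrics metrics.csv --design data/pairs.csv --out effects.csv
litterflame phylo --tree data/tree.nwk --pairs data/pairs.csv --out dist.csv
litterflame analyze --metrics metrics.csv --traits data/traits.csv \
    --pairs data/pairs.csv --dist dist.csv --out report/
```

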