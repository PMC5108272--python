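"""Nonadditive mixture effect sizes from a simulated two-species experiment.

Simulates the full block design with a negative dominance imposed on pairs
involving the dense short-needle species (their needles fill the air spaces
of the partner's litterbed), then prints the per-pair mass-weighted effect
sizes for mass loss.
"""

from litterflame.mixtures import effect_size_table
from litterflame.synth import SimulationConfig, gen_experiment

cfg = SimulationConfig(rng_seed=3, dense_pair_dominance=0.8,
                       packing_ratio_range=(0.02, 0.13))
exp = gen_experiment(cfg, with_traces=False)
dense = frozenset(exp.traits.loc[exp.traits.litter_type == "short_needle",
                                 "species_code"])
effects = effect_size_table(exp.metrics, exp.pairs, clade_members=dense)

ml = effects[effects.parameter == "mass_loss"].sort_values("es_mw_pct")
print(ml[["pair_id", "observed", "expected_mw", "es_mw_pct", "group"]]
      .to_string(index=False, float_format="%.1f"))
print("\nES = 100*(observed - expected)/expected; 'with' pairs involve a dense "
      "short-needle species. Their |ES| is far larger: the mixture either "
      "collapses below or is lifted above the packing threshold, so it burns "
      "like one partner rather than like the average.")
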