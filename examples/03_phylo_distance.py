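"""Pairwise phylogenetic distances on a dated tree, and their (non-)relation
to mixture nonadditivity.

Parses a small Newick tree, prints patristic distances for a few pairs,
then runs the distance-vs-effect-size correlation on a simulated default
experiment (no trait conservatism, no dominance: the null the study design
tests against).
"""

from litterflame import parse_tree, pairwise_distance
from litterflame.mixtures import effect_size_table
from litterflame.stats import pearson_test
from litterflame.synth import SimulationConfig, gen_experiment

tree = parse_tree("((A:150,B:150):50,(C:120,D:120):80);")
for a, b in [("A", "B"), ("A", "C"), ("C", "D")]:
    print(f"d({a},{b}) = {pairwise_distance(tree, a, b):.0f} My")
print("on an ultrametric tree the distance is twice the divergence time\n")

exp = gen_experiment(SimulationConfig(rng_seed=8), with_traces=False)
eff = effect_size_table(exp.metrics, exp.pairs)
sub = eff[eff.parameter == "mass_loss"].dropna(subset=["es_mw_pct"])
dist = {frozenset((r.species_a, r.species_b)): r.distance_my
        for r in exp.true_distances.itertuples()}
pairs = {p.pair_id: frozenset((p.species_a, p.species_b)) for p in exp.pairs}
d = sub.pair_id.map(lambda pid: dist[pairs[pid]])
res = pearson_test(d, sub.es_mw_pct)
print(f"distance vs mass-loss ES over {len(sub)} pairs: "
      f"r = {res.r:.2f}, df = {res.df}, p = {res.p:.2f}")
print("with packing decoupled from the tree, relatedness does not predict "
      "nonadditivity — the sharp packing threshold, not distance, drives it.")
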