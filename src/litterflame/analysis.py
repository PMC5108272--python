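"""End-to-end report: the study's inferential tables and curve fits.

Combines the per-trial metrics, trait table, mixture design and
phylogenetic distances into:

* correlations of phylogenetic distance with volume- and mass-weighted
  mixture effect sizes per flammability parameter;
* correlations of fuelbed packing ratio and moisture content with the
  monoculture flammability parameters (species means);
* the two-way ANOVA of |effect size| on weighting method x focal-clade
  membership, per parameter;
* the logistic packing-ratio threshold for proportion burned and the
  Gaussian packing-ratio response of maximum temperature;
* PCA of fuelbed traits and of flammability parameters among flammable
  species, and per-litter-type regressions of packing ratio on log10
  particle size.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from . import stats as lfstats
from .fuelbed import mixture_packing_ratio, packing_density
from .geometry import BurnGeometry
from .mixtures import DEFAULT_CLADE_MEMBERS, PARAMETERS, effect_size_table


def species_summary(metrics: pd.DataFrame, traits: pd.DataFrame,
                    geometry: BurnGeometry = BurnGeometry()) -> pd.DataFrame:
    """Monoculture species means joined with derived fuelbed descriptors.

    Returns one row per species: the five flammability parameters (means
    over replicate blocks; missing front speeds count as 0), proportion of
    sample burned as a fraction, packing ratio (%), packing density
    (g/cm³), moisture (%), log10 particle size and litter type, plus a
    species-level flammable flag (majority of replicate classifications).
    """
    mono = metrics[metrics["species_2"].isna() | (metrics["species_2"] == "")].copy()
    mono["front_speed"] = mono["front_speed"].fillna(0.0)
    agg = mono.groupby("species_1").agg(
        burning_time=("burning_time", "mean"), front_speed=("front_speed", "mean"),
        max_temp=("max_temp", "mean"), temp_sum=("temp_sum", "mean"),
        mass_loss=("mass_loss", "mean"), flammable=("flammable", "mean"),
    )
    agg["prop_burned"] = agg["mass_loss"] / 100.0
    agg["flammable"] = agg["flammable"] > 0.5

    t = traits.set_index("species_code")
    full_mass = 2.0 * t["half_ring_mass_g"]
    agg["packing_ratio_pct"] = [
        100.0 * mixture_packing_ratio([full_mass[s]], [t.loc[s, "moisture_frac"]],
                                      [t.loc[s, "tissue_density_g_cm3"]], geometry)
        for s in agg.index
    ]
    agg["packing_density"] = [packing_density(full_mass[s], geometry) for s in agg.index]
    agg["moisture_pct"] = 100.0 * t["moisture_frac"]
    agg["tissue_density"] = t["tissue_density_g_cm3"]
    size = t["length_cm"] * t["width_cm"] * t["height_cm"]
    agg["lg_particle_size"] = np.log10(size)
    agg["litter_type"] = t["litter_type"]
    return agg


def run_analysis(metrics: pd.DataFrame, traits: pd.DataFrame,
                 design: Iterable, distances: pd.DataFrame,
                 clade_members: frozenset = DEFAULT_CLADE_MEMBERS,
                 geometry: BurnGeometry = BurnGeometry()) -> dict:
    """All inferential outputs as one nested dict (JSON-serialisable)."""
    design = list(design)
    effects = effect_size_table(metrics, design, clade_members)
    species = species_summary(metrics, traits, geometry)

    # --- phylogenetic distance vs effect size, per parameter & weighting
    dist_key = {frozenset((r["species_a"], r["species_b"])): r["distance_my"]
                for _, r in distances.iterrows()}
    pair_dist = {d.pair_id: dist_key[frozenset((d.species_a, d.species_b))] for d in design}
    effects = effects.assign(distance_my=effects["pair_id"].map(pair_dist))
    phylo_corr = {}
    for param in PARAMETERS:
        sub = effects[effects["parameter"] == param]
        phylo_corr[param] = {}
        for wt, col in (("volume", "es_vw_pct"), ("mass", "es_mw_pct")):
            ok = sub.dropna(subset=[col, "distance_my"])
            if len(ok) >= 3 and ok[col].nunique() > 1:
                res = lfstats.pearson_test(ok["distance_my"], ok[col])
                phylo_corr[param][wt] = asdict(res)
            else:
                phylo_corr[param][wt] = None

    # --- fuelbed traits vs monoculture flammability (species means)
    trait_corr = {}
    for xcol, label in (("packing_ratio_pct", "packing_ratio"),
                        ("moisture_pct", "moisture_content")):
        trait_corr[label] = {}
        for param in PARAMETERS:
            res = lfstats.pearson_test(species[xcol], species[param])
            trait_corr[label][param] = asdict(res)

    # --- two-way ANOVA of |ES|: weighting x clade membership, per parameter
    anova = {}
    for param in PARAMETERS:
        sub = effects[effects["parameter"] == param].dropna(subset=["es_vw_pct", "es_mw_pct"])
        stacked = pd.concat([
            pd.DataFrame({"aes": sub["es_vw_pct"].abs(), "weighting": "volume",
                          "group": sub["group"]}),
            pd.DataFrame({"aes": sub["es_mw_pct"].abs(), "weighting": "mass",
                          "group": sub["group"]}),
        ])
        try:
            tab = lfstats.two_way_anova(stacked["aes"], stacked["weighting"], stacked["group"])
            anova[param] = {f.name: {"F": f.F, "p": f.p} for f in tab.factors}
        except ValueError as exc:
            anova[param] = {"error": str(exc)}

    # --- packing-ratio threshold fits (species means)
    logistic = lfstats.fit_logistic_threshold(species["packing_ratio_pct"],
                                              species["prop_burned"])
    gaussian = lfstats.fit_gaussian_response(species["packing_ratio_pct"],
                                             species["max_temp"])

    # --- PCAs and per-type regressions among flammable species
    flam = species[species["flammable"]]
    pca_traits = pca_flam = None
    trait_cols = ["lg_particle_size", "tissue_density", "packing_density",
                  "packing_ratio_pct"]
    ok = flam.dropna(subset=trait_cols)
    if len(ok) > len(trait_cols) + 1:
        res = lfstats.pca_correlation(ok[trait_cols])
        pca_traits = {"variance_explained_pct": res.variance_explained.tolist(),
                      "loadings": res.loadings.to_dict()}
    flam_cols = ["burning_time", "front_speed", "max_temp", "temp_sum", "packing_density"]
    if len(flam) > len(flam_cols) + 1:
        res = lfstats.pca_correlation(flam[flam_cols])
        pca_flam = {"variance_explained_pct": res.variance_explained.tolist(),
                    "loadings": res.loadings.to_dict()}

    typed = species.dropna(subset=["lg_particle_size"])
    group_fits = lfstats.linear_fit_by_group(typed["lg_particle_size"],
                                             typed["packing_ratio_pct"],
                                             typed["litter_type"])

    return {
        "phylo_distance_correlations": phylo_corr,
        "trait_correlations": trait_corr,
        "anova_weighting_x_clade": anova,
        "logistic_threshold": {
            "slope": logistic.slope, "midpoint_pct": logistic.midpoint,
            "transition_interval_pct": list(logistic.transition_interval),
            "p_slope": logistic.p_slope, "separated": logistic.separated,
        },
        "gaussian_max_temp": {
            "amplitude": gaussian.amplitude, "mean_pct": gaussian.mean,
            "sd_pct": gaussian.sd, "baseline": gaussian.baseline, "rss": gaussian.rss,
        },
        "pca_fuelbed_traits": pca_traits,
        "pca_flammability": pca_flam,
        "size_vs_packing_by_type": {g: asdict(f) for g, f in group_fits.items()},
        "effect_sizes": effects.to_dict(orient="records"),
    }


def write_report(report: dict, outdir) -> None:
    """Write the report dict as JSON plus tidy CSVs for the main tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(json.dumps(report, indent=1, default=float))
    pd.DataFrame(report["effect_sizes"]).to_csv(outdir / "effect_sizes.csv", index=False)

    rows = []
    for param, by_wt in report["phylo_distance_correlations"].items():
        for wt, res in by_wt.items():
            if res:
                rows.append({"parameter": param, "weighting": wt, **res})
    pd.DataFrame(rows).to_csv(outdir / "phylo_correlations.csv", index=False)

    rows = []
    for param, factors in report["anova_weighting_x_clade"].items():
        if "error" in factors:
            continue
        for fname, fr in factors.items():
            rows.append({"parameter": param, "factor": fname, **fr})
    pd.DataFrame(rows).to_csv(outdir / "anova.csv", index=False)
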