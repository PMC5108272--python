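"""Synthetic laboratory burn experiments with known ground truth.

The raw burn data behind the original study design are not publicly
deposited, so this module generates complete experiments with the same
structure — a species pool with litter traits, a dated ultrametric
phylogeny, and mono-specific plus 50:50 two-species mixture ring burns
with six-sensor thermocouple traces — from a mechanistic toy model whose
parameters are the ground truth every pipeline stage can be checked
against.

The core mechanism mirrors the field understanding of litterbed fire:

* ignitability is a sharp logistic function of the fuelbed packing ratio
  around a threshold (default 16%, steepness such that the 0.9/0.1
  ignition-probability interval spans packing ratios of roughly 13-19%,
  inside the reported 12-20% transition);
* among ignited beds, fire front speed decreases and burning time
  increases with packing density;
* flammable burns consume the fuel entirely or almost entirely (92-100%
  oven-dry mass loss), failed burns consume very little (<8%);
* a two-species bed packs additively, but a per-pair dominance
  coefficient delta shifts the ignition propensity on the logit scale
  (positive: the flammable partner dominates; negative: the dense
  nonflammable partner suffocates the bed), so nonadditivity emerges
  through the same threshold mechanism it is meant to emulate.

Thermocouple pulses are a linear rise to a short plateau followed by
exponential decay, plus Gaussian sensor noise; any pulse shape satisfying
the threshold-crossing contract would do, and the shape parameters live in
the config. Every trial draws from its own counter-based substream of the
master seed, so a trial's data are reproducible independently of how many
other trials were generated (and common random numbers are preserved when
only the dominance coefficient changes).
"""

from __future__ import annotations

import json
import math
import random as _pyrandom
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .burn_core import BurnTrial, ThermocoupleTrace
from .fuelbed import mixture_packing_ratio
from .geometry import BurnGeometry, ring_volume
from .mixtures import MixtureDesign

_LOGISTIC = lambda z: 1.0 / (1.0 + math.exp(-z))


@dataclass
class SimulationConfig:
    """Study-design and mechanism parameters for a synthetic experiment.

    Defaults reproduce the laboratory design: 34 species and 34 random
    pairs burned in 5 replicate blocks (340 trials), room temperature
    18 +/- 2 °C, 1 Hz thermocouple sampling, three dense short-needle
    species whose litterbeds pack above the flammability threshold.
    """

    n_species: int = 34
    n_pairs: int = 34
    n_dense_species: int = 3  # short-needle species packed above threshold
    n_moss_species: int = 2
    replicate_blocks: int = 5

    # trace generation
    sampling_hz: float = 1.0
    baseline_temp: float = 18.0  # °C room temperature
    baseline_sd: float = 2.0  # °C between-trial room variation
    sensor_noise_sd: float = 0.5  # °C per-sample noise
    source_ignition_s: float = 10.0  # cotton disk lit, trace clock
    center_delay_s: float = 5.0  # disk -> fuelbed ignition at the center
    rise_time_s: float = 10.0
    peak_plateau_s: float = 4.0

    # mechanism
    packing_threshold: float = 0.16  # packing-ratio fraction
    threshold_steepness: float = 75.0  # logit units per unit packing ratio
    front_speed_range: tuple = (2.0, 10.0)  # cm/min
    flammable_mass_loss_range: tuple = (0.92, 1.0)
    nonflammable_mass_loss_range: tuple = (0.0, 0.08)
    dominance_scale: float = 6.0  # logit shift at |delta| = 1
    default_dominance: float = 0.0
    dense_pair_dominance: float = 0.0  # |delta| for pairs involving a dense species
    mixture_dominance: dict = field(default_factory=dict)  # pair_id -> delta
    # soften the sharp threshold into a gradual decline of ignitability
    # (about linear across the packing range); nonadditivity then grows
    # smoothly with the packing difference between the mixed species
    linear_response: bool = False

    # trait distributions
    tissue_density_range: tuple = (0.08, 0.59)  # g/cm3
    moisture_range: tuple = (0.03, 0.11)  # fraction
    packing_ratio_range: tuple = (0.02, 0.18)
    dense_packing_ratio_range: tuple = (0.20, 0.32)

    # phylogeny
    root_age_my: float = 350.0
    trait_conservatism: float = 0.0  # 0 = packing decoupled from the tree

    geometry: BurnGeometry = field(default_factory=BurnGeometry)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.packing_threshold < 1):
            raise ValueError("packing threshold must be in (0, 1)")
        if self.threshold_steepness <= 0 or self.sampling_hz <= 0:
            raise ValueError("rates must be positive")
        if self.n_dense_species + self.n_moss_species > self.n_species:
            raise ValueError("dense + moss species exceed the pool size")
        if not (0 <= self.trait_conservatism <= 1):
            raise ValueError("trait_conservatism must be in [0, 1]")


@dataclass
class TrialTruth:
    """Generator-side ground truth for one trial."""

    trial_id: str
    flammable: bool
    front_speed: Optional[float]  # cm/min (mean over outer sensors)
    flame_window: float  # s, first 50 °C upcross to last 70 °C downcross
    peak_temperature: float  # °C, mean of outer-sensor peaks
    temperature_sum: float  # °C·s, analytic pulse integral
    mass_loss_pct: float
    packing_ratio: float  # fraction
    packing_density: float  # g/cm3
    dominance: float  # delta (0 for monocultures)


@dataclass
class SimulatedExperiment:
    config: SimulationConfig
    traits: pd.DataFrame
    pairs: list  # of MixtureDesign
    newick: str
    true_distances: pd.DataFrame  # species_a, species_b, distance_my (design pairs)
    trials: list  # of BurnTrial ([] on the metrics-only path)
    metrics: pd.DataFrame  # ground-truth metrics, one row per trial
    truths: dict  # trial_id -> TrialTruth

    @property
    def pairs_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"pair_id": p.pair_id, "species_a": p.species_a, "species_b": p.species_b,
              "mass_a_g": p.mass_a, "mass_b_g": p.mass_b} for p in self.pairs]
        )


def _species_codes(n: int) -> list:
    return [f"S{i + 1:02d}" for i in range(n)]


# ---------------------------------------------------------------------------
# species pool

def _particle_dims(size_cm3: float, litter_type: str, rng) -> tuple:
    """Decompose a particle volume into plausible L x W x H."""
    if litter_type in ("short_needle", "long_needle"):
        aspect = rng.uniform(20.0, 60.0)  # needles: long and thin
    elif litter_type == "branch":
        aspect = rng.uniform(10.0, 30.0)
    else:  # broad leaf: flat
        aspect = rng.uniform(1.0, 3.0)
    length = (size_cm3 * aspect ** 2) ** (1.0 / 3.0)
    width = math.sqrt(size_cm3 / length)
    if litter_type == "broad_leaf":  # flatten: thickness << width
        width = math.sqrt(size_cm3 / length * 10.0)
    height = size_cm3 / (length * width)
    return length, width, height


def gen_species_pool(config: SimulationConfig,
                     tip_conservatism_values: Optional[dict] = None) -> pd.DataFrame:
    """Species trait table: one row per species, deterministic under seed.

    The first ``n_dense_species`` are short-needle species whose target
    packing ratio falls above the flammability threshold (emulating the
    dense, poorly ventilated litterbeds of the non-Pinus Pinaceae); the
    last ``n_moss_species`` are mosses without a defined particle size.
    When ``tip_conservatism_values`` (a Brownian trait per species from the
    phylogeny) is given and ``trait_conservatism > 0``, packing ratios are
    blended toward the rank order of the evolved trait.
    """
    rng = np.random.default_rng([config.rng_seed, 1])
    codes = _species_codes(config.n_species)
    n_dense, n_moss = config.n_dense_species, config.n_moss_species

    rows = []
    pr_lo, pr_hi = config.packing_ratio_range
    dense_lo, dense_hi = config.dense_packing_ratio_range
    vol = ring_volume(config.geometry)
    for i, code in enumerate(codes):
        dense = i < n_dense
        moss = i >= config.n_species - n_moss
        pr = rng.uniform(dense_lo, dense_hi) if dense else rng.uniform(pr_lo, pr_hi)
        if moss:
            pr = rng.uniform(pr_lo, min(pr_hi, config.packing_threshold * 0.7))
        rho = rng.uniform(*config.tissue_density_range)
        mc = rng.uniform(*config.moisture_range)

        # smaller particles pack denser; lg size declines with packing ratio
        lg_size = 1.3 - 7.0 * pr + rng.normal(0.0, 0.35)
        if dense:
            lg_size = rng.normal(-1.2, 0.25)  # small solitary needles
        if dense:
            ltype = "short_needle"
        elif moss:
            ltype = "moss"
        else:
            ltype = rng.choice(["long_needle", "broad_leaf", "branch"])
        if ltype == "moss":
            length = width = height = None
        else:
            length, width, height = _particle_dims(10.0 ** lg_size, ltype, rng)

        full_mass = pr * vol * rho / (1.0 - mc)  # mass that realises the target pr
        rows.append({
            "species_code": code, "length_cm": length, "width_cm": width,
            "height_cm": height, "tissue_density_g_cm3": rho, "moisture_frac": mc,
            "litter_type": ltype, "half_ring_mass_g": full_mass / 2.0,
        })
    df = pd.DataFrame(rows)

    c = config.trait_conservatism
    if c > 0 and tip_conservatism_values:
        # map the Brownian trait through its ranks onto the packing range,
        # then blend: pr = c * evolved + (1 - c) * independent
        z = np.array([tip_conservatism_values[code] for code in codes])
        ranks = stats_rankdata(z)
        evolved_pr = pr_lo + (dense_hi - pr_lo) * (ranks - 0.5) / len(z)
        base_pr = df["half_ring_mass_g"] * 2 * (1 - df["moisture_frac"]) / (
            df["tissue_density_g_cm3"] * vol)
        new_pr = c * evolved_pr + (1 - c) * base_pr.to_numpy()
        df["half_ring_mass_g"] = (
            new_pr * vol * df["tissue_density_g_cm3"] / (1 - df["moisture_frac"]) / 2.0
        )
    return df


def stats_rankdata(z: np.ndarray) -> np.ndarray:
    order = np.argsort(np.argsort(z))
    return order + 1.0


# ---------------------------------------------------------------------------
# phylogeny

def _brownian_tips(tree: dendropy.Tree, rng, rate: float) -> dict:
    """Brownian-motion trait evolved along the tree; one value per tip label."""
    values = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node._bm = 0.0
        else:
            edge = node.edge.length or 0.0
            node._bm = node.parent_node._bm + rng.normal(0.0, math.sqrt(max(edge, 1e-12) * rate))
        if node.is_leaf():
            values[node.taxon.label] = node._bm
    return values


def gen_phylogeny(config: SimulationConfig) -> tuple:
    """Pure-birth ultrametric tree over the species codes.

    Returns ``(newick_text, true_distance, bm_tips)`` where
    ``true_distance`` maps frozenset({a, b}) to the patristic distance in
    My and ``bm_tips`` is a Brownian trait per tip (used for optional trait
    conservatism).
    """
    rng = np.random.default_rng([config.rng_seed, 2])
    pyrng = _pyrandom.Random(int(rng.integers(2 ** 31)))
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0,
        num_extant_tips=config.n_species, rng=pyrng,
    )
    # the simulation stops at the n-th birth, leaving the last sibling pair
    # at distance zero; extend every tip branch by one exponential waiting
    # time (the time to the next, unrealised, speciation) to condition on n
    tree.seed_node.edge.length = None
    extra = rng.exponential(1.0 / config.n_species)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    # scale so the root-to-tip depth equals the configured root age
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    f = config.root_age_my / depth
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= f
    codes = _species_codes(config.n_species)
    leaves = list(tree.leaf_node_iter())
    order = rng.permutation(len(leaves))
    for leaf, k in zip(leaves, order):
        leaf.taxon.label = codes[k]

    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    true_distance = {}
    for i, a in enumerate(codes):
        for b in codes[i + 1:]:
            true_distance[frozenset((a, b))] = float(pdm.patristic_distance(taxa[a], taxa[b]))
    bm_tips = _brownian_tips(tree, np.random.default_rng([config.rng_seed, 3]),
                             rate=1.0 / config.root_age_my)
    newick = tree.as_string(schema="newick", suppress_rooting=True).strip()
    return newick, true_distance, bm_tips


# ---------------------------------------------------------------------------
# single burn trial

def _ignition_probability(pr: float, delta: float, config: SimulationConfig) -> float:
    steepness = config.threshold_steepness
    if config.linear_response:
        steepness = steepness / 5.0  # gradual, near-linear decline
    z = -steepness * (pr - config.packing_threshold) + config.dominance_scale * delta
    return _LOGISTIC(z)


def _pulse(times: np.ndarray, baseline: float, t_arr: float, excess: float,
           rise: float, plateau: float, tau: float) -> np.ndarray:
    """Linear rise -> plateau -> exponential decay, on top of the baseline."""
    temp = np.full_like(times, baseline)
    t_peak, t_dec = t_arr + rise, t_arr + rise + plateau
    rising = (times >= t_arr) & (times < t_peak)
    temp[rising] = baseline + excess * (times[rising] - t_arr) / rise
    flat = (times >= t_peak) & (times < t_dec)
    temp[flat] = baseline + excess
    dec = times >= t_dec
    temp[dec] = baseline + excess * np.exp(-(times[dec] - t_dec) / tau)
    return temp


def _pulse_end(t_arr: float, excess: float, rise: float, plateau: float,
               tau: float, baseline: float, thresh: float = 70.0) -> float:
    """Analytic last downcrossing of ``thresh`` for the pulse above."""
    if baseline + excess < thresh:
        return -np.inf
    return t_arr + rise + plateau + tau * math.log(excess / (thresh - baseline))


def _pulse_start(t_arr: float, excess: float, rise: float, baseline: float,
                 thresh: float = 50.0) -> float:
    if baseline + excess < thresh:
        return np.inf
    return t_arr + rise * (thresh - baseline) / excess


def gen_burn_trial(trial_id: str, block: str, components: list,
                   config: SimulationConfig, trial_index: int,
                   delta: float = 0.0, with_traces: bool = True) -> tuple:
    """One synthetic ring burn.

    ``components`` is a list of trait-table rows (as dicts/Series): one for
    a monoculture (burned as a full ring, twice the half-ring mass) or two
    for a 50:50 mixture (each at its half-ring mass). Returns
    ``(BurnTrial, TrialTruth)``; on the metrics-only path the trial carries
    no traces (``with_traces=False``), which is sufficient for statistical
    studies that only need ground-truth metrics.
    """
    rng = np.random.default_rng([config.rng_seed, 4, trial_index])
    geom = config.geometry
    mono = len(components) == 1
    masses = [2.0 * c["half_ring_mass_g"] if mono else c["half_ring_mass_g"]
              for c in components]
    mcs = [c["moisture_frac"] for c in components]
    rhos = [c["tissue_density_g_cm3"] for c in components]
    codes = [c["species_code"] for c in components]

    pr = mixture_packing_ratio(masses, mcs, rhos, geom)
    pdens = sum(masses) / ring_volume(geom)
    p_ignite = _ignition_probability(pr, delta, config)
    flammable = bool(rng.random() < p_ignite)

    baseline = rng.normal(config.baseline_temp, config.baseline_sd)
    t0 = config.source_ignition_s
    rise, plateau = config.rise_time_s, config.peak_plateau_s
    n_outer = geom.n_outer_sensors

    if flammable:
        s_lo, s_hi = config.front_speed_range
        speed = s_lo + (s_hi - s_lo) * math.exp(-pdens / 0.05)  # cm/min
        delay = geom.sensor_radius / (speed / 60.0)  # s to the sensor circle
        arrivals = t0 + delay * (1.0 + rng.normal(0.0, 0.01, n_outer))
        peak_excess = (250.0 + 350.0 * math.exp(-((pr - 0.08) ** 2) / (2 * 0.06 ** 2)))
        peak_excess *= 1.0 + rng.normal(0.0, 0.02)
        excesses = peak_excess * (1.0 + rng.normal(0.0, 0.005, n_outer))
        tau = float(np.clip(30.0 + 250.0 * pdens, 20.0, 90.0))
        taus = tau * (1.0 + rng.normal(0.0, 0.02, n_outer))
        center_arr = t0 + config.center_delay_s
        center_excess = peak_excess * (1.0 + rng.normal(0.0, 0.005))
        center_tau = tau
        ml = rng.uniform(*config.flammable_mass_loss_range)
        reached = True
        true_speed = float(np.mean(geom.sensor_radius / (arrivals - t0) * 60.0))
    else:
        # only the ethanol-soaked cotton disk burns at the center
        arrivals = np.full(n_outer, np.nan)
        excesses = rng.uniform(5.0, 15.0, n_outer)  # warm air bump, below 50 °C
        taus = np.full(n_outer, 20.0)
        center_arr = t0 + config.center_delay_s
        center_excess = rng.uniform(100.0, 150.0)
        center_tau = 15.0
        ml = rng.uniform(*config.nonflammable_mass_loss_range)
        reached = False
        true_speed = None

    # analytic ground truth on the noise-free pulses
    starts, ends = [], []
    sensors = [(center_arr, center_excess, center_tau)]
    if flammable:
        sensors += [(a, e, tu) for a, e, tu in zip(arrivals, excesses, taus)]
    for t_arr, exc, tu in sensors:
        starts.append(_pulse_start(t_arr, exc, rise, baseline))
        ends.append(_pulse_end(t_arr, exc, rise, plateau, tu, baseline))
    start_true, end_true = min(starts), max(ends)
    window = max(end_true - start_true, 0.0) if np.isfinite(end_true) else 0.0

    if flammable:
        peak_true = float(baseline + np.mean(excesses))
        # integral of (T - baseline) per outer sensor: rise/2 + plateau + tau decay
        tsum_true = float(np.mean(excesses * (rise / 2.0 + plateau + taus)))
    else:
        peak_true = float(baseline + np.mean(excesses))
        tsum_true = 0.0 if window == 0.0 else float(np.mean(excesses) * 1.0)

    pre_od = sum(m * (1 - mc) for m, mc in zip(masses, mcs))
    residue = pre_od * (1.0 - ml)

    traces = []
    if with_traces:
        duration = (end_true if np.isfinite(end_true) else center_arr + 60.0) + 40.0
        times = np.arange(0.0, duration, 1.0 / config.sampling_hz)
        noise = lambda: rng.normal(0.0, config.sensor_noise_sd, len(times))
        traces.append(ThermocoupleTrace(
            sensor_id="C", position="center",
            times=times,
            temperatures=_pulse(times, baseline, center_arr, center_excess,
                                rise, plateau, center_tau) + noise(),
        ))
        for j in range(n_outer):
            if flammable:
                temp = _pulse(times, baseline, arrivals[j], excesses[j],
                              rise, plateau, taus[j])
            else:
                temp = _pulse(times, baseline, center_arr + 30.0, excesses[j],
                              rise, plateau, taus[j])
            traces.append(ThermocoupleTrace(
                sensor_id=f"O{j + 1}", position="outer",
                times=times, temperatures=temp + noise(),
            ))

    trial = BurnTrial(
        trial_id=trial_id, block=block,
        components=list(zip(codes, masses)),
        moisture_contents=mcs,
        post_burn_oven_dry_mass=residue,
        ignition_time_of_source=t0,
        traces=traces,
        reached_edge_observed=reached,
    )
    truth = TrialTruth(
        trial_id=trial_id, flammable=flammable, front_speed=true_speed,
        flame_window=window, peak_temperature=peak_true,
        temperature_sum=tsum_true, mass_loss_pct=100.0 * ml,
        packing_ratio=pr, packing_density=pdens, dominance=delta,
    )
    return trial, truth


# ---------------------------------------------------------------------------
# full experiment

def _draw_pairs(config: SimulationConfig, traits: pd.DataFrame) -> list:
    rng = np.random.default_rng([config.rng_seed, 5])
    codes = list(traits["species_code"])
    half_mass = dict(zip(traits["species_code"], traits["half_ring_mass_g"]))
    seen, pairs = set(), []
    k = 1
    while len(pairs) < config.n_pairs:
        a, b = rng.choice(codes, size=2, replace=False)
        key = frozenset((a, b))
        if key in seen:
            continue
        seen.add(key)
        pairs.append(MixtureDesign(pair_id=f"P{k:02d}", species_a=str(a), species_b=str(b),
                                   mass_a=half_mass[a], mass_b=half_mass[b]))
        k += 1
    return pairs


def _pair_delta(pair: MixtureDesign, dense_codes: set, config: SimulationConfig,
                rng) -> float:
    if pair.pair_id in config.mixture_dominance:
        return float(config.mixture_dominance[pair.pair_id])
    if config.dense_pair_dominance and (
            pair.species_a in dense_codes or pair.species_b in dense_codes):
        sign = 1.0 if rng.random() < 0.5 else -1.0
        return sign * config.dense_pair_dominance
    return config.default_dominance


def gen_experiment(config: SimulationConfig, with_traces: bool = True,
                   outdir: Optional[str] = None) -> SimulatedExperiment:
    """Generate the full block design: every fuelbed type once per block.

    With the default config this is (34 monocultures + 34 mixtures) x 5
    blocks = 340 trials. When ``outdir`` is given, the standard file set is
    written there: ``traces.csv`` (omitted on the metrics-only path),
    ``trials.csv``, ``traits.csv``, ``pairs.csv``, ``tree.nwk`` and
    ``ground_truth.json``.
    """
    newick, true_dist, bm_tips = gen_phylogeny(config)
    traits = gen_species_pool(config, tip_conservatism_values=bm_tips)
    pairs = _draw_pairs(config, traits)
    dense_codes = set(traits.loc[traits["litter_type"] == "short_needle", "species_code"])
    delta_rng = np.random.default_rng([config.rng_seed, 6])
    deltas = {p.pair_id: _pair_delta(p, dense_codes, config, delta_rng) for p in pairs}

    by_code = {row["species_code"]: row for _, row in traits.iterrows()}
    trials, truths, rows = [], {}, []
    trial_index = 0
    for block in range(1, config.replicate_blocks + 1):
        block_id = f"B{block}"
        for code in traits["species_code"]:
            trial_id = f"{code}-{block_id}"
            trial, truth = gen_burn_trial(trial_id, block_id, [by_code[code]],
                                          config, trial_index,
                                          delta=0.0, with_traces=with_traces)
            trial_index += 1
            trials.append(trial)
            truths[trial_id] = truth
            rows.append(_metric_row(trial_id, block_id, code, "", truth))
        for p in pairs:
            trial_id = f"{p.pair_id}-{block_id}"
            trial, truth = gen_burn_trial(
                trial_id, block_id, [by_code[p.species_a], by_code[p.species_b]],
                config, trial_index, delta=deltas[p.pair_id], with_traces=with_traces)
            trial_index += 1
            trials.append(trial)
            truths[trial_id] = truth
            rows.append(_metric_row(trial_id, block_id, p.species_a, p.species_b, truth))

    dist_rows = [{"species_a": p.species_a, "species_b": p.species_b,
                  "distance_my": true_dist[frozenset((p.species_a, p.species_b))]}
                 for p in pairs]
    exp = SimulatedExperiment(
        config=config, traits=traits, pairs=pairs, newick=newick,
        true_distances=pd.DataFrame(dist_rows),
        trials=trials,
        metrics=pd.DataFrame(rows),
        truths=truths,
    )
    if outdir is not None:
        _write_experiment(exp, Path(outdir), with_traces=with_traces)
    return exp


def _metric_row(trial_id: str, block: str, sp1: str, sp2: str, truth: TrialTruth) -> dict:
    """Ground-truth metrics row (the fast path around trace synthesis)."""
    return {
        "trial_id": trial_id, "block": block, "species_1": sp1, "species_2": sp2,
        "burning_time": truth.flame_window,
        "front_speed": truth.front_speed if truth.front_speed is not None else np.nan,
        "max_temp": truth.peak_temperature,
        "temp_sum": truth.temperature_sum,
        "mass_loss": truth.mass_loss_pct,
        "flammable": truth.flammable,
    }


def _write_experiment(exp: SimulatedExperiment, outdir: Path, with_traces: bool) -> None:
    from . import io as lfio  # local import to avoid a cycle

    outdir.mkdir(parents=True, exist_ok=True)
    if with_traces:
        lfio.write_traces(exp.trials, outdir / "traces.csv")
    lfio.write_trials(exp.trials, outdir / "trials.csv")
    lfio.write_traits(exp.traits, outdir / "traits.csv")
    exp.pairs_frame.to_csv(outdir / "pairs.csv", index=False)
    (outdir / "tree.nwk").write_text(exp.newick + "\n")
    truth_payload = {
        "config": {k: v for k, v in asdict(exp.config).items() if k != "geometry"},
        "trials": {tid: asdict(t) for tid, t in exp.truths.items()},
        "design_distances_my": exp.true_distances.to_dict(orient="records"),
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth_payload, indent=1))
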