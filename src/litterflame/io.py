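"""CSV readers/writers for the pipeline's tabular interchange formats.

Formats (all plain CSV with headers):

* traces:  ``trial_id,sensor_id,position,time_s,temp_C`` (long format)
* trials:  ``trial_id,block,species_1,mass_1_g,species_2,mass_2_g,mc_1,mc_2,
  residue_od_g,source_ignition_s,reached_edge``
* traits:  ``species_code,length_cm,width_cm,height_cm,tissue_density_g_cm3,
  moisture_frac,litter_type,half_ring_mass_g``
* pairs:   ``pair_id,species_a,species_b,mass_a_g,mass_b_g``
* metrics: one row per trial with the five parameters and the classification
* effects: ``pair_id,parameter,observed,expected_vw,expected_mw,es_vw_pct,
  es_mw_pct,group``
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, List, Union

import numpy as np
import pandas as pd

from .burn_core import BurnTrial, FlammabilityMetrics, ThermocoupleTrace
from .fuelbed import SpeciesTraits
from .mixtures import MixtureDesign

PathLike = Union[str, Path]


# --- traces ---------------------------------------------------------------

def write_traces(trials: Iterable[BurnTrial], path: PathLike) -> None:
    frames = []
    for trial in trials:
        for tr in trial.traces:
            frames.append(pd.DataFrame({
                "trial_id": trial.trial_id, "sensor_id": tr.sensor_id,
                "position": tr.position, "time_s": tr.times,
                "temp_C": np.round(tr.temperatures, 2),
            }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trials(traces_path: PathLike, trials_path: PathLike) -> List[BurnTrial]:
    """Assemble BurnTrial objects from the traces + trial-metadata CSVs."""
    traces = pd.read_csv(traces_path)
    meta = pd.read_csv(trials_path)
    grouped = {tid: g for tid, g in traces.groupby("trial_id")}
    trials = []
    for _, row in meta.iterrows():
        tid = row["trial_id"]
        if tid not in grouped:
            raise ValueError(f"no traces for trial {tid!r}")
        tr_list = []
        for sid, g in grouped[tid].groupby("sensor_id"):
            g = g.sort_values("time_s")
            positions = g["position"].unique()
            if len(positions) != 1:
                raise ValueError(f"trial {tid}, sensor {sid}: inconsistent position")
            tr_list.append(ThermocoupleTrace(
                sensor_id=str(sid), position=str(positions[0]),
                times=g["time_s"].to_numpy(float),
                temperatures=g["temp_C"].to_numpy(float),
            ))
        components = [(str(row["species_1"]), float(row["mass_1_g"]))]
        mcs = [float(row["mc_1"])]
        if isinstance(row.get("species_2"), str) and row["species_2"]:
            components.append((str(row["species_2"]), float(row["mass_2_g"])))
            mcs.append(float(row["mc_2"]))
        edge = row.get("reached_edge")
        if edge is None or (isinstance(edge, float) and math.isnan(edge)):
            edge_val = None
        elif isinstance(edge, (bool, np.bool_)):
            edge_val = bool(edge)
        else:
            edge_val = str(edge).strip().lower() in ("true", "1", "yes")
        trials.append(BurnTrial(
            trial_id=str(tid), block=str(row["block"]),
            components=components, moisture_contents=mcs,
            post_burn_oven_dry_mass=float(row["residue_od_g"]),
            ignition_time_of_source=float(row["source_ignition_s"]),
            traces=tr_list, reached_edge_observed=edge_val,
        ))
    return trials


def write_trials(trials: Iterable[BurnTrial], path: PathLike) -> None:
    rows = []
    for t in trials:
        (sp1, m1) = t.components[0]
        (sp2, m2) = t.components[1] if len(t.components) == 2 else ("", np.nan)
        mc2 = t.moisture_contents[1] if len(t.components) == 2 else np.nan
        rows.append({
            "trial_id": t.trial_id, "block": t.block,
            "species_1": sp1, "mass_1_g": m1, "species_2": sp2, "mass_2_g": m2,
            "mc_1": t.moisture_contents[0], "mc_2": mc2,
            "residue_od_g": t.post_burn_oven_dry_mass,
            "source_ignition_s": t.ignition_time_of_source,
            "reached_edge": t.reached_edge_observed,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


# --- metrics --------------------------------------------------------------

def metrics_frame(trials: Iterable[BurnTrial],
                  metrics: Iterable[FlammabilityMetrics]) -> pd.DataFrame:
    rows = []
    for t, m in zip(trials, metrics):
        sp2 = t.components[1][0] if len(t.components) == 2 else ""
        rows.append({
            "trial_id": t.trial_id, "block": t.block,
            "species_1": t.components[0][0], "species_2": sp2,
            "burning_time": m.total_burning_time,
            "front_speed": m.fire_front_speed if m.fire_front_speed is not None else np.nan,
            "max_temp": m.max_temperature, "temp_sum": m.temperature_sum,
            "mass_loss": m.mass_loss, "flammable": m.flammable,
        })
    return pd.DataFrame(rows)


def read_metrics(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["species_2"] = df["species_2"].fillna("")
    return df


# --- traits ---------------------------------------------------------------

def write_traits(traits: pd.DataFrame, path: PathLike) -> None:
    cols = ["species_code", "length_cm", "width_cm", "height_cm",
            "tissue_density_g_cm3", "moisture_frac", "litter_type", "half_ring_mass_g"]
    traits[cols].to_csv(path, index=False)


def read_traits(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


def traits_objects(traits: pd.DataFrame) -> List[SpeciesTraits]:
    out = []
    for _, r in traits.iterrows():
        dims = [r["length_cm"], r["width_cm"], r["height_cm"]]
        dims = [None if (d is None or (isinstance(d, float) and math.isnan(d))) else float(d)
                for d in dims]
        out.append(SpeciesTraits(
            species_code=str(r["species_code"]),
            particle_length=dims[0], particle_width=dims[1], particle_height=dims[2],
            tissue_density=float(r["tissue_density_g_cm3"]),
            moisture_content=float(r["moisture_frac"]),
            litter_type=str(r["litter_type"]),
            half_ring_air_dry_mass=float(r["half_ring_mass_g"]),
        ))
    return out


# --- pairs ----------------------------------------------------------------

def read_pairs(path: PathLike) -> List[MixtureDesign]:
    df = pd.read_csv(path)
    return [MixtureDesign(pair_id=str(r["pair_id"]), species_a=str(r["species_a"]),
                          species_b=str(r["species_b"]), mass_a=float(r["mass_a_g"]),
                          mass_b=float(r["mass_b_g"]))
            for _, r in df.iterrows()]
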