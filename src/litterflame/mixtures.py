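"""Nonadditive mixture effect sizes.

A two-species litterbed need not burn like the average of its components.
The departure is quantified per flammability parameter as

    effect size (%) = 100 * (observed - expected) / expected

where *observed* is the measured mixture value and *expected* is the
additive prediction from the two monocultures, weighted either by volume
(the 50:50-by-volume design makes this the plain mean) or by the measured
component masses.

Pairs are partitioned by whether they involve a member of a focal clade —
by default the non-Pinus Pinaceae (Abies veitchii, Larix eurolepis, Picea
abies), whose dense short-needle litterbeds are nonflammable and drive the
strongest nonadditivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

PARAMETERS = ("burning_time", "front_speed", "max_temp", "temp_sum", "mass_loss")

#: Species codes of the non-Pinus Pinaceae in the study design
#: (Abies veitchii, Larix eurolepis, Picea abies).
DEFAULT_CLADE_MEMBERS = frozenset({"AbVe", "LaEu", "PiAb"})


@dataclass
class MixtureDesign:
    """One 50:50-by-volume species pair with its measured half-ring masses."""

    pair_id: str
    species_a: str
    species_b: str
    mass_a: float
    mass_b: float

    def __post_init__(self) -> None:
        if self.species_a == self.species_b:
            raise ValueError("mixture components must be distinct species")
        if self.mass_a <= 0 or self.mass_b <= 0:
            raise ValueError("component masses must be positive")


@dataclass
class EffectSizeRecord:
    pair_id: str
    parameter: str
    observed: float
    expected_volume_weighted: Optional[float]
    expected_mass_weighted: Optional[float]
    effect_size_vw: Optional[float]  # %
    effect_size_mw: Optional[float]  # %
    involves_non_pinus_pinaceae: bool


def expected_value(
    value_a: float,
    value_b: float,
    weighting: str,
    mass_a: float = 1.0,
    mass_b: float = 1.0,
) -> float:
    """Additive expectation for a 50:50-by-volume mixture.

    ``weighting="volume"`` gives the plain mean of the component monoculture
    values (each species fills half the ring); ``"mass"`` weights by the
    measured half-ring masses.
    """
    if weighting == "volume":
        return (value_a + value_b) / 2.0
    if weighting == "mass":
        if mass_a + mass_b <= 0:
            raise ValueError("total mass must be positive")
        return (mass_a * value_a + mass_b * value_b) / (mass_a + mass_b)
    raise ValueError(f"weighting must be 'volume' or 'mass', got {weighting!r}")


def effect_size(observed: float, expected: float) -> float:
    """Signed nonadditivity: 100 * (observed - expected) / expected."""
    if expected == 0:
        raise ValueError("effect size undefined for expected value 0")
    return 100.0 * (observed - expected) / expected


def partition_pairs(
    pairs: Iterable[tuple],
    clade_members: frozenset = DEFAULT_CLADE_MEMBERS,
    known_species: Optional[set] = None,
) -> list:
    """Label each (species_a, species_b) pair "with"/"without" the focal clade.

    A pair is "with" if at least one member species belongs to the clade.
    When ``known_species`` is given, unknown codes raise.
    """
    labels = []
    for a, b in pairs:
        if known_species is not None:
            for s in (a, b):
                if s not in known_species:
                    raise ValueError(f"unknown species code {s!r}")
        labels.append("with" if (a in clade_members or b in clade_members) else "without")
    return labels


def _safe_effect_size(observed: float, expected: Optional[float]) -> Optional[float]:
    if expected is None or expected == 0 or not math.isfinite(expected):
        return None
    return effect_size(observed, expected)


def monoculture_means(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per-species replicate means of the five parameters, monocultures only.

    ``metrics`` is the tidy trial-metrics table (one row per trial, columns
    ``species_1``, ``species_2`` — the latter empty for monocultures — and
    the five parameter columns). A species whose monoculture never ignited
    contributes front speed 0 to mixture expectations, so missing front
    speeds are treated as 0 here.
    """
    mono = metrics[metrics["species_2"].isna() | (metrics["species_2"] == "")].copy()
    if mono.empty:
        raise ValueError("no monoculture trials in metrics table")
    mono["front_speed"] = mono["front_speed"].fillna(0.0)
    return mono.groupby("species_1")[list(PARAMETERS)].mean()


def effect_size_table(
    metrics: pd.DataFrame,
    design: Iterable[MixtureDesign],
    clade_members: frozenset = DEFAULT_CLADE_MEMBERS,
) -> pd.DataFrame:
    """Per-pair, per-parameter mixture effect sizes (tidy long format).

    Monoculture reference values are replicate means per species. Effect
    sizes are computed per mixture replicate against those means, then
    averaged per pair, yielding one record per pair and parameter. Effect
    sizes with a zero additive expectation are left missing.

    Returns columns: ``pair_id, parameter, observed, expected_vw,
    expected_mw, es_vw_pct, es_mw_pct, group``.
    """
    mono = monoculture_means(metrics)
    mix = metrics[~(metrics["species_2"].isna() | (metrics["species_2"] == ""))]
    rows = []
    for d in design:
        for sp in (d.species_a, d.species_b):
            if sp not in mono.index:
                raise ValueError(f"pair {d.pair_id}: no monoculture reference for species {sp!r}")
        reps = mix[
            ((mix["species_1"] == d.species_a) & (mix["species_2"] == d.species_b))
            | ((mix["species_1"] == d.species_b) & (mix["species_2"] == d.species_a))
        ]
        group = "with" if (d.species_a in clade_members or d.species_b in clade_members) else "without"
        for param in PARAMETERS:
            va = mono.loc[d.species_a, param]
            vb = mono.loc[d.species_b, param]
            evw = expected_value(va, vb, "volume")
            emw = expected_value(va, vb, "mass", d.mass_a, d.mass_b)
            obs = reps[param]
            if param == "front_speed":
                obs = obs.fillna(0.0)
            obs = obs.dropna()
            if obs.empty:
                continue
            es_vw = [_safe_effect_size(o, evw) for o in obs]
            es_mw = [_safe_effect_size(o, emw) for o in obs]
            es_vw = [e for e in es_vw if e is not None]
            es_mw = [e for e in es_mw if e is not None]
            rows.append({
                "pair_id": d.pair_id,
                "parameter": param,
                "observed": float(obs.mean()),
                "expected_vw": evw,
                "expected_mw": emw,
                "es_vw_pct": float(np.mean(es_vw)) if es_vw else np.nan,
                "es_mw_pct": float(np.mean(es_mw)) if es_mw else np.nan,
                "group": group,
            })
    return pd.DataFrame(rows)
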