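"""Flammability metrics from raw thermocouple burn traces.

One ring burn produces six temperature time series (one center sensor, five
outer sensors on a 6.25 cm circle) plus pre/post mass records. This module
reduces those to five flammability parameters:

* total burning time (s) — sustainability,
* fire front speed (cm/min) — sustainability / rate of lateral spread,
* maximum temperature (°C) — combustibility,
* temperature sum (°C·s) — combustibility, a proxy for total heat release,
* mass loss (%) — consumability,

and a binary flammable/nonflammable classification: flammable litterbeds
support fire spread to the ring edge and lose more than 40% of their
oven-dry mass.

Conventions: the fuelbed counts as ignited once any sensor first reaches
50 °C (linearly interpolated between samples); the flame counts as
extinguished after the last interpolated downcrossing of 70 °C. The baseline
for the temperature sum is each outer sensor's mean temperature before
fuelbed ignition, so the sum is invariant to constant sensor offsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .geometry import BurnGeometry

logger = logging.getLogger(__name__)

IGNITION_TEMP_C = 50.0
EXTINCTION_TEMP_C = 70.0
FLAMMABLE_MASS_LOSS_PCT = 40.0


@dataclass
class ThermocoupleTrace:
    """One sensor's temperature record within a burn trial.

    ``times`` are seconds (strictly increasing, nominally 1 s steps);
    ``temperatures`` are °C. ``position`` is ``"center"`` or ``"outer"``.
    """

    sensor_id: str
    position: str
    times: np.ndarray
    temperatures: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if self.position not in ("center", "outer"):
            raise ValueError(f"position must be center|outer, got {self.position!r}")
        if self.times.shape != self.temperatures.shape or self.times.ndim != 1:
            raise ValueError("times and temperatures must be equal-length 1-D arrays")
        if len(self.times) < 2:
            raise ValueError("trace needs at least two samples")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError(f"sensor {self.sensor_id}: times must be strictly increasing")
        if not np.all(np.isfinite(self.temperatures)):
            raise ValueError(f"sensor {self.sensor_id}: temperatures must be finite")


@dataclass
class BurnTrial:
    """One ring burn: mono-specific or a 50:50 two-species mixture.

    ``components`` holds ``(species_code, air_dry_mass_g)`` for 1 or 2
    species; ``moisture_contents`` are the matching water-mass / air-dry-mass
    fractions. ``ignition_time_of_source`` is the moment (s, trace clock) the
    ethanol-soaked cotton disk at the ring center is lit.
    """

    trial_id: str
    block: str
    components: list
    moisture_contents: list
    post_burn_oven_dry_mass: float
    ignition_time_of_source: float
    traces: list = field(default_factory=list)
    reached_edge_observed: Optional[bool] = None

    def __post_init__(self) -> None:
        if len(self.components) not in (1, 2):
            raise ValueError("trial must have 1 or 2 components")
        if len(self.moisture_contents) != len(self.components):
            raise ValueError("one moisture content per component")
        for _, m in self.components:
            if m < 0:
                raise ValueError("masses must be >= 0")
        for mc in self.moisture_contents:
            if not (0 <= mc < 1):
                raise ValueError("moisture content must be in [0, 1)")
        if self.post_burn_oven_dry_mass < 0:
            raise ValueError("residue mass must be >= 0")
        if self.traces:
            n_center = sum(1 for t in self.traces if t.position == "center")
            if len(self.traces) != 6 or n_center != 1:
                raise ValueError("trial requires exactly 6 traces with exactly 1 center")

    @property
    def outer_traces(self) -> list:
        return [t for t in self.traces if t.position == "outer"]

    @property
    def center_trace(self) -> ThermocoupleTrace:
        return next(t for t in self.traces if t.position == "center")


@dataclass
class FlammabilityMetrics:
    """The five flammability parameters plus the binary classification."""

    total_burning_time: float  # s
    fire_front_speed: Optional[float]  # cm/min; None if no outer sensor ignites
    max_temperature: float  # °C
    temperature_sum: float  # °C·s
    mass_loss: float  # % of pre-burn oven-dry mass
    flammable: bool


def detect_ignition(trace: ThermocoupleTrace, threshold: float = IGNITION_TEMP_C) -> Optional[float]:
    """First time the trace reaches ``threshold`` °C, or None.

    The crossing time is linearly interpolated between the bracketing
    samples; if the first sample is already at or above the threshold its
    own timestamp is returned.
    """
    t, temp = trace.times, trace.temperatures
    above = temp >= threshold
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(t[0])
    # interpolate on the rising segment temp[i-1] < threshold <= temp[i]
    frac = (threshold - temp[i - 1]) / (temp[i] - temp[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def _last_downcrossing(trace: ThermocoupleTrace, threshold: float) -> Optional[float]:
    """Last time the trace is at/above ``threshold``, interpolated downward.

    If the trace ends while still above the threshold, the final sample time
    is returned.
    """
    t, temp = trace.times, trace.temperatures
    above = temp >= threshold
    if not above.any():
        return None
    i = int(len(temp) - 1 - np.argmax(above[::-1]))  # last index at/above
    if i == len(temp) - 1:
        return float(t[-1])
    frac = (temp[i] - threshold) / (temp[i] - temp[i + 1])
    return float(t[i] + frac * (t[i + 1] - t[i]))


def burn_window(
    trial: BurnTrial,
    ignition_thresh: float = IGNITION_TEMP_C,
    extinction_thresh: float = EXTINCTION_TEMP_C,
) -> Optional[tuple]:
    """(start, end) of the burn on the trace clock, or None if no burn.

    Start is the earliest ignition over all six sensors (the source is
    central, so the center sensor participates); end is the latest
    interpolated downcrossing of the extinction threshold over all sensors.
    """
    if not trial.traces:
        raise ValueError("trial has no traces")
    starts = [detect_ignition(tr, ignition_thresh) for tr in trial.traces]
    starts = [s for s in starts if s is not None]
    if not starts:
        return None
    ends = [_last_downcrossing(tr, extinction_thresh) for tr in trial.traces]
    ends = [e for e in ends if e is not None]
    if not ends:
        return None
    start, end = min(starts), max(ends)
    if end < start:
        logger.warning(
            "trial %s: extinction (%.1f s) precedes ignition (%.1f s); "
            "peaks likely stayed between the thresholds — burning time set to 0",
            trial.trial_id, end, start,
        )
        return None
    return start, end


def total_burning_time(
    trial: BurnTrial,
    ignition_thresh: float = IGNITION_TEMP_C,
    extinction_thresh: float = EXTINCTION_TEMP_C,
) -> float:
    """Seconds between fuelbed ignition and complete flame extinction.

    Returns 0 if no sensor ignites or none reaches the extinction threshold.
    """
    window = burn_window(trial, ignition_thresh, extinction_thresh)
    if window is None:
        return 0.0
    return window[1] - window[0]


def fire_front_speed(
    trial: BurnTrial,
    geometry: BurnGeometry = BurnGeometry(),
    arrival_thresh: float = IGNITION_TEMP_C,
) -> Optional[float]:
    """Mean lateral flame-spread speed in cm/min, or None.

    For each outer sensor that reaches the arrival threshold, the speed is
    sensor radius over the delay from source (cotton disk) ignition; the
    result is the mean over arriving outer sensors.
    """
    speeds = []
    for tr in trial.outer_traces:
        arrival = detect_ignition(tr, arrival_thresh)
        if arrival is None:
            continue
        dt = arrival - trial.ignition_time_of_source
        if dt <= 0:
            raise ValueError(
                f"trial {trial.trial_id}, sensor {tr.sensor_id}: "
                f"flame arrival at {arrival:.1f} s precedes source ignition"
            )
        speeds.append(geometry.sensor_radius / dt * 60.0)  # cm/s -> cm/min
    if not speeds:
        return None
    return float(np.mean(speeds))


def max_temperature(trial: BurnTrial) -> float:
    """Mean of the per-sensor maximum temperatures over the 5 outer sensors."""
    outer = trial.outer_traces
    if len(outer) != 5:
        raise ValueError(f"trial {trial.trial_id}: expected 5 outer traces, got {len(outer)}")
    return float(np.mean([tr.temperatures.max() for tr in outer]))


def temperature_sum(
    trial: BurnTrial,
    ignition_thresh: float = IGNITION_TEMP_C,
    extinction_thresh: float = EXTINCTION_TEMP_C,
) -> float:
    """Integrated outer-sensor temperature above baseline over the burn, °C·s.

    Each outer sensor's baseline is its mean temperature before fuelbed
    ignition; the per-time mean excess over the 5 outer sensors is
    integrated (trapezoid) over the burn window, which at exactly 1 Hz
    equals the per-second sum. Returns 0 when the burning time is 0.
    """
    window = burn_window(trial, ignition_thresh, extinction_thresh)
    if window is None:
        return 0.0
    start, end = window
    outer = trial.outer_traces
    if len(outer) != 5:
        raise ValueError(f"trial {trial.trial_id}: expected 5 outer traces, got {len(outer)}")

    # common grid: union of sample times inside the window plus the endpoints
    grid = np.unique(np.concatenate(
        [tr.times[(tr.times > start) & (tr.times < end)] for tr in outer]
        + [np.array([start, end])]
    ))
    mean_excess = np.zeros_like(grid)
    for tr in outer:
        pre = tr.temperatures[tr.times < start]
        if len(pre) == 0:
            logger.warning(
                "trial %s, sensor %s: no pre-ignition samples; using first sample as baseline",
                trial.trial_id, tr.sensor_id,
            )
            baseline = tr.temperatures[0]
        else:
            baseline = pre.mean()
        mean_excess += (np.interp(grid, tr.times, tr.temperatures) - baseline) / len(outer)
    return float(np.trapezoid(mean_excess, grid))


def mass_loss(trial: BurnTrial) -> float:
    """Percent of the pre-burn oven-dry mass consumed by the burn.

    The pre-burn oven-dry mass is reconstructed from the air-dry component
    masses and their moisture contents. Clamped to [0, 100] with a warning
    if the residue exceeds the reconstructed pre-burn mass.
    """
    pre_od = sum(m * (1 - mc) for (_, m), mc in zip(trial.components, trial.moisture_contents))
    if pre_od <= 0:
        raise ValueError(f"trial {trial.trial_id}: non-positive pre-burn oven-dry mass")
    pct = 100.0 * (pre_od - trial.post_burn_oven_dry_mass) / pre_od
    if pct < 0:
        logger.warning(
            "trial %s: residue %.2f g exceeds reconstructed pre-burn mass %.2f g; clamping",
            trial.trial_id, trial.post_burn_oven_dry_mass, pre_od,
        )
    return float(min(max(pct, 0.0), 100.0))


def reached_edge(trial: BurnTrial, arrival_thresh: float = IGNITION_TEMP_C) -> bool:
    """Did the fire spread to the ring edge?

    Uses the direct observation when recorded; otherwise proxied by all five
    outer sensors having ignited (the only in-data signal of lateral spread).
    """
    if trial.reached_edge_observed is not None:
        return bool(trial.reached_edge_observed)
    return all(detect_ignition(tr, arrival_thresh) is not None for tr in trial.outer_traces)


def classify_flammable(mass_loss_pct: float, reached_edge_flag: bool,
                       mass_loss_cutoff: float = FLAMMABLE_MASS_LOSS_PCT) -> bool:
    """Flammable = fire spread to the ring edge AND >40% of the sample burned."""
    return bool(reached_edge_flag and mass_loss_pct > mass_loss_cutoff)


def compute_metrics(
    trial: BurnTrial,
    geometry: BurnGeometry = BurnGeometry(),
    ignition_thresh: float = IGNITION_TEMP_C,
    extinction_thresh: float = EXTINCTION_TEMP_C,
) -> FlammabilityMetrics:
    """All five flammability parameters plus the classification for one trial."""
    if len(trial.traces) != 6:
        raise ValueError(f"trial {trial.trial_id}: requires all 6 traces")
    ml = mass_loss(trial)
    return FlammabilityMetrics(
        total_burning_time=total_burning_time(trial, ignition_thresh, extinction_thresh),
        fire_front_speed=fire_front_speed(trial, geometry, ignition_thresh),
        max_temperature=max_temperature(trial),
        temperature_sum=temperature_sum(trial, ignition_thresh, extinction_thresh),
        mass_loss=ml,
        flammable=classify_flammable(ml, reached_edge(trial, ignition_thresh)),
    )
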