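"""Synthetic smart-home data generator.

An agent-based resident routine produces a labeled ground-truth event log;
per-channel emission models turn occupancy into ambient sensor streams at
0.2 Hz; a lossy packetizer turns streams into data packets with
configurable packet loss and bit corruption.

The generator emulates a single-occupant home instrumented with one wall
box per room plus fridge-door and flush-handle boxes.  The resident
follows a daily routine: a nightly sleeping block (optionally interrupted
by nocturnal toilet visits, which split the sleeping interval), morning
grooming, anchored cooking/eating pairs, afternoon seated activity,
evening TV, and scattered toilet visits.  ``structure_level`` in [0, 1]
controls day-to-day regularity: 1 yields an identical schedule every day,
lower values add Gaussian timing jitter and stochastic event counts.

Between scheduled events the resident putters about in the kitchen and
dining room (short dwells with moderate movement); an empty ground-truth
log therefore renders as an empty house — baselines and noise only.
"""
from __future__ import annotations

import datetime as dt
import json
import math
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from . import codec
from .domain import (
    ADLEvent,
    ADLLabel,
    AdlSenseError,
    CHANNELS,
    DataPacket,
    GroundTruthLog,
    HomeLayout,
    Placement,
    SAMPLES_PER_DAY,
    SAMPLING_PERIOD_S,
    SECONDS_PER_DAY,
    SensorChannel,
    default_layout,
    validate_layout,
)

HOUR = 3600.0


class SchedulingError(AdlSenseError):
    """The profile demands more activity time than a day can hold."""


# ---------------------------------------------------------------------------
# Resident profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ActivitySpec:
    """Daily pattern for one (non-sleeping) activity.

    ``anchors`` is a sequence of (preferred start second-of-day,
    occurrence probability) pairs; each anchor independently contributes
    at most one event per day.  Durations are log-normal (median seconds,
    dispersion sigma) truncated to hard bounds; starts are clamped to
    ``start_window``.  ``movement`` is the probability per 5 s sample that
    the resident moves enough to be seen by a PIR sensor during the
    activity.
    """

    label: ADLLabel
    compartment: str
    anchors: tuple[tuple[float, float], ...]
    duration_median_s: float
    duration_sigma: float
    duration_bounds_s: tuple[float, float]
    start_window: tuple[float, float]
    movement: float


@dataclass(frozen=True)
class ResidentProfile:
    """Behavioral parameters of the simulated resident.

    Sleeping is modeled separately from the anchored daytime activities:
    a nightly block whose start/duration are jittered, split by a Poisson
    number of nocturnal toilet visits.  Getting ready for bed is attached
    to the front of every sleeping block; eating is attached to the end
    of every cooking event with probability ``eating_after_cooking_prob``.
    """

    activities: tuple[ActivitySpec, ...]
    structure_level: float = 0.7
    jitter_base_s: float = 2700.0  # 1-sigma timing jitter at structure 0

    sleep_start_s: float = 23.0 * HOUR
    sleep_start_window: tuple[float, float] = (22.5 * HOUR, 23.75 * HOUR)
    sleep_duration_median_s: float = 7.5 * HOUR
    sleep_duration_sigma: float = 0.06
    sleep_duration_bounds_s: tuple[float, float] = (6.5 * HOUR, 8.5 * HOUR)
    sleep_compartment: str = "bedroom"
    sleep_movement: float = 0.01

    nocturnal_toileting_rate: float = 0.6  # visits per night (Poisson)
    nocturnal_margin_s: float = 5400.0  # keep visits away from sleep edges

    getting_ready_duration_median_s: float = 600.0
    getting_ready_duration_sigma: float = 0.25
    getting_ready_duration_bounds_s: tuple[float, float] = (240.0, 840.0)

    eating_after_cooking_prob: float = 1.0
    eating_lag_bounds_s: tuple[float, float] = (120.0, 600.0)
    eating_spec: ActivitySpec | None = None

    idle_compartments: tuple[str, ...] = ("dining_room", "kitchen")
    idle_dwell_bounds_s: tuple[float, float] = (120.0, 360.0)
    idle_movement: float = 0.5

    def activity(self, label: ADLLabel) -> ActivitySpec | None:
        for spec in self.activities:
            if spec.label is label:
                return spec
        return None

    @property
    def deterministic(self) -> bool:
        return self.structure_level >= 1.0

    @property
    def jitter_sd_s(self) -> float:
        return self.jitter_base_s * (1.0 - min(self.structure_level, 1.0))

    def expected_daily_rate(self, label: ADLLabel) -> float:
        """Mean events/day implied by the profile (used by count checks)."""
        if label is ADLLabel.SLEEPING:
            return 1.0 + self.nocturnal_toileting_rate  # splits add events
        if label is ADLLabel.GETTING_READY_FOR_BED:
            return 1.0
        if label is ADLLabel.EATING:
            cooking = self.activity(ADLLabel.COOKING)
            base = sum(p for _, p in cooking.anchors) if cooking else 0.0
            return base * self.eating_after_cooking_prob
        rate = 0.0
        spec = self.activity(label)
        if spec is not None:
            rate += sum(p for _, p in spec.anchors)
        if label is ADLLabel.TOILETING:
            rate += self.nocturnal_toileting_rate
        return rate

    def total_demand_s(self) -> float:
        total = self.sleep_duration_median_s + self.getting_ready_duration_median_s
        for spec in self.activities:
            total += sum(p for _, p in spec.anchors) * spec.duration_median_s
        cooking = self.activity(ADLLabel.COOKING)
        if cooking and self.eating_spec:
            total += (
                sum(p for _, p in cooking.anchors)
                * self.eating_after_cooking_prob
                * self.eating_spec.duration_median_s
            )
        total += self.nocturnal_toileting_rate * 420.0
        return total


def _eating_spec() -> ActivitySpec:
    return ActivitySpec(
        label=ADLLabel.EATING,
        compartment="dining_room",
        anchors=(),
        duration_median_s=1320.0,
        duration_sigma=0.25,
        duration_bounds_s=(720.0, 2400.0),
        start_window=(7.0 * HOUR, 22.0 * HOUR),
        movement=0.25,
    )


def default_profile() -> ResidentProfile:
    """A regular, healthy single resident (the study-style condition)."""
    acts = (
        ActivitySpec(
            ADLLabel.GROOMING,
            "bathroom",
            anchors=((-1.0, 0.9),),  # -1 => relative to wake (see scheduler)
            duration_median_s=1500.0,
            duration_sigma=0.22,
            duration_bounds_s=(1100.0, 2900.0),
            start_window=(5.5 * HOUR, 11.0 * HOUR),
            movement=0.6,
        ),
        ActivitySpec(
            ADLLabel.TOILETING,
            "bathroom",
            anchors=((9.66 * HOUR, 0.9), (13.1 * HOUR, 0.7), (16.75 * HOUR, 0.9)),
            duration_median_s=420.0,
            duration_sigma=0.3,
            duration_bounds_s=(180.0, 720.0),
            start_window=(8.5 * HOUR, 22.0 * HOUR),
            movement=0.6,
        ),
        ActivitySpec(
            ADLLabel.COOKING,
            "kitchen",
            anchors=((11.5 * HOUR, 0.9), (17.75 * HOUR, 0.3)),
            duration_median_s=1500.0,
            duration_sigma=0.3,
            duration_bounds_s=(780.0, 3300.0),
            start_window=(10.5 * HOUR, 19.0 * HOUR),
            movement=0.7,
        ),
        ActivitySpec(
            ADLLabel.WATCHING_TV,
            "living_room",
            anchors=((20.5 * HOUR, 0.9),),
            duration_median_s=4800.0,
            duration_sigma=0.3,
            duration_bounds_s=(1800.0, 7200.0),
            start_window=(19.25 * HOUR, 21.75 * HOUR),
            movement=0.10,
        ),
        ActivitySpec(
            ADLLabel.SEATED_ACTIVITY,
            "living_room",
            anchors=((10.75 * HOUR, 0.5), (14.66 * HOUR, 0.8)),
            duration_median_s=2700.0,
            duration_sigma=0.3,
            duration_bounds_s=(1560.0, 5400.0),
            start_window=(8.5 * HOUR, 17.5 * HOUR),
            movement=0.12,
        ),
    )
    return ResidentProfile(activities=acts, eating_spec=_eating_spec())


def alzheimer_profile() -> ResidentProfile:
    """Low-structure preset: fragmented sleep, elevated nocturnal
    toileting, high day-to-day variability.  Intended for the qualitative
    routine-regularity contrast with :func:`default_profile`; no numeric
    claim attaches to its parameter values."""
    base = default_profile()
    return replace(
        base,
        structure_level=0.3,
        sleep_duration_median_s=6.5 * HOUR,
        sleep_duration_sigma=0.12,
        sleep_duration_bounds_s=(5.0 * HOUR, 8.5 * HOUR),
        sleep_start_window=(21.5 * HOUR, 23.9 * HOUR),
        nocturnal_toileting_rate=2.0,
    )


# ---------------------------------------------------------------------------
# Emission model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EmissionModel:
    """Per-channel physics of the simulated home.

    Pulses rise linearly over the emitting event and decay exponentially
    afterwards (time constant ``pulse_decay_s``).  Luminance combines an
    outdoor diurnal curve attenuated per room with a lamp that the
    resident switches on whenever a room is occupied while dark (the TV
    replaces the lamp with its own signature level; a sleeping resident
    leaves the light off).  PIR sensors trigger stochastically while the
    resident moves and hold their output briefly.
    """

    noise_sd: dict[str, float] = field(
        default_factory=lambda: {
            "temperature": 0.05,
            "humidity": 0.15,
            "luminance": 2.0,
            "acceleration": 0.02,
        }
    )
    pir_trigger_prob: float = 0.95
    pir_false_rate: float = 1e-4
    pir_hold_s: float = 10.0

    temperature_base_c: float = 21.0
    humidity_base_gm3: float = 8.0

    shower_humidity_amp_gm3: float = 6.0
    cooking_temperature_amp_c: float = 2.0
    cooking_humidity_amp_gm3: float = 1.5
    pulse_decay_s: float = 1200.0

    outdoor_peak_lx: float = 300.0
    sunrise_s: float = 6.5 * HOUR
    sunset_s: float = 19.0 * HOUR
    lamp_lx: float = 200.0
    tv_lx: float = 40.0
    lamp_on_threshold_lx: float = 30.0
    attenuation: dict[str, float] = field(
        default_factory=lambda: {
            "living_room": 0.8,
            "dining_room": 0.7,
            "kitchen": 0.6,
            "bedroom": 0.5,
            "bathroom": 0.02,
        }
    )
    default_attenuation: float = 0.6

    transient_amp_ms2: float = 3.0
    flush_end_offset_s: float = 10.0
    grooming_flush_prob: float = 0.7

    @classmethod
    def noise_free(cls) -> "EmissionModel":
        """Zero Gaussian noise, deterministic PIR (always triggers on
        movement, no false triggers).  Used by closed-loop oracles."""
        return cls(
            noise_sd={k: 0.0 for k in ("temperature", "humidity", "luminance", "acceleration")},
            pir_trigger_prob=1.0,
            pir_false_rate=0.0,
        )

    def daylight_lx(self, second_of_day: np.ndarray) -> np.ndarray:
        """Outdoor illuminance: half-sine between sunrise and sunset."""
        s = np.asarray(second_of_day, dtype=float)
        frac = (s - self.sunrise_s) / (self.sunset_s - self.sunrise_s)
        out = np.where(
            (frac > 0) & (frac < 1),
            self.outdoor_peak_lx * np.sin(np.pi * np.clip(frac, 0, 1)),
            0.0,
        )
        return out

    def room_attenuation(self, compartment: str) -> float:
        return self.attenuation.get(compartment, self.default_attenuation)


@dataclass(frozen=True)
class SimConfig:
    layout: HomeLayout
    profile: ResidentProfile
    emission: EmissionModel
    n_days: int = 1
    start_date: dt.date = dt.date(2023, 3, 6)
    packet_loss_rate: float = 0.0047
    bit_corruption_rate: float = 0.0005
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("packet_loss_rate", "bit_corruption_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise AdlSenseError(f"{name} {rate} outside [0, 1]")
        if self.n_days < 1:
            raise AdlSenseError(f"n_days {self.n_days} must be >= 1")


def default_config(
    n_days: int = 1, seed: int = 0, noise_free: bool = False, **kwargs
) -> SimConfig:
    emission = EmissionModel.noise_free() if noise_free else EmissionModel()
    return SimConfig(
        layout=default_layout(),
        profile=default_profile(),
        emission=emission,
        n_days=n_days,
        seed=seed,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# Routine generation
# ---------------------------------------------------------------------------


def _truncated_lognormal(
    rng: np.random.Generator,
    median: float,
    sigma: float,
    bounds: tuple[float, float],
    deterministic: bool,
) -> float:
    if deterministic or sigma <= 0:
        return float(min(max(median, bounds[0]), bounds[1]))
    for _ in range(64):
        x = median * math.exp(sigma * rng.standard_normal())
        if bounds[0] <= x <= bounds[1]:
            return float(x)
    return float(min(max(median, bounds[0]), bounds[1]))


def _jittered(
    rng: np.random.Generator,
    center: float,
    sd: float,
    window: tuple[float, float],
    deterministic: bool,
) -> float:
    if deterministic or sd <= 0:
        return float(min(max(center, window[0]), window[1]))
    x = center + sd * rng.standard_normal()
    return float(min(max(x, window[0]), window[1]))


@dataclass
class _Interval:
    label: ADLLabel
    compartment: str
    start: float  # absolute seconds
    end: float


def _overlaps(a_start, a_end, intervals, buffer_s=120.0) -> _Interval | None:
    for iv in intervals:
        if a_start < iv.end + buffer_s and iv.start - buffer_s < a_end:
            return iv
    return None


def generate_routine(
    profile: ResidentProfile,
    layout: HomeLayout,
    n_days: int,
    rng: np.random.Generator,
    start_date: dt.date = dt.date(2023, 3, 6),
) -> GroundTruthLog:
    """Simulate ``n_days`` of resident behavior as a ground-truth log.

    Events never overlap; each night's sleeping block is preceded by a
    contiguous getting-ready-for-bed interval in the bathroom and may be
    split by nocturnal toilet visits.  The final night's sleeping event
    runs past the rendered range and is clipped by the renderer, not here,
    so that perfectly regular profiles yield exactly day-shifted copies.
    Raises :class:`SchedulingError` when the profile demands more than 24 h
    of activity per day.
    """
    errors = validate_layout(layout)
    if errors:
        raise AdlSenseError("invalid layout: " + "; ".join(errors))
    for spec in profile.activities:
        if spec.compartment not in layout.compartments:
            raise AdlSenseError(
                f"profile assigns {spec.label.value} to unknown compartment "
                f"'{spec.compartment}'"
            )
    demand = profile.total_demand_s()
    if demand > SECONDS_PER_DAY:
        raise SchedulingError(
            f"profile demands {demand / 3600:.1f} h of activity per day"
        )

    det = profile.deterministic
    jitter = profile.jitter_sd_s
    day0 = start_date.toordinal() * SECONDS_PER_DAY
    events: list[_Interval] = []

    # --- nightly sleeping blocks (night d starts on the evening of day d)
    sleep_blocks: list[tuple[float, float]] = []
    for d in range(n_days):
        base = day0 + d * SECONDS_PER_DAY
        start = base + _jittered(
            rng, profile.sleep_start_s, jitter / 2, profile.sleep_start_window, det
        )
        dur = _truncated_lognormal(
            rng,
            profile.sleep_duration_median_s,
            profile.sleep_duration_sigma,
            profile.sleep_duration_bounds_s,
            det,
        )
        sleep_blocks.append((start, start + dur))

    # wake on day 0 comes from a virtual previous night with the same law
    v_start = _jittered(
        rng, profile.sleep_start_s, jitter / 2, profile.sleep_start_window, det
    ) - SECONDS_PER_DAY
    v_dur = _truncated_lognormal(
        rng,
        profile.sleep_duration_median_s,
        profile.sleep_duration_sigma,
        profile.sleep_duration_bounds_s,
        det,
    )
    wakes = [day0 + v_start + v_dur] + [end for _, end in sleep_blocks[:-1]]
    # the tail of the virtual previous night falls inside the observed
    # range: emit it, clipped at range start, so the house is never empty
    # while the resident is asleep on the morning of day 0
    if wakes[0] - day0 > 600.0:
        events.append(
            _Interval(ADLLabel.SLEEPING, profile.sleep_compartment, day0, wakes[0])
        )

    toileting_spec = profile.activity(ADLLabel.TOILETING)

    for d, (s_start, s_end) in enumerate(sleep_blocks):
        # getting ready for bed: contiguous, immediately before sleeping
        gr_dur = _truncated_lognormal(
            rng,
            profile.getting_ready_duration_median_s,
            profile.getting_ready_duration_sigma,
            profile.getting_ready_duration_bounds_s,
            det,
        )
        events.append(
            _Interval(ADLLabel.GETTING_READY_FOR_BED, "bathroom", s_start - gr_dur, s_start)
        )
        # nocturnal toilet visits split the sleeping block
        if det:
            k = int(round(profile.nocturnal_toileting_rate))
        else:
            k = int(rng.poisson(profile.nocturnal_toileting_rate))
        lo = s_start + profile.nocturnal_margin_s
        hi = s_end - profile.nocturnal_margin_s
        visits: list[tuple[float, float]] = []
        if k > 0 and hi - lo > 3600.0:
            for j in range(k):
                dur = (
                    420.0
                    if det or toileting_spec is None
                    else _truncated_lognormal(
                        rng,
                        toileting_spec.duration_median_s,
                        toileting_spec.duration_sigma,
                        toileting_spec.duration_bounds_s,
                        det,
                    )
                )
                if det:
                    t = lo + (j + 1) * (hi - lo) / (k + 1)
                else:
                    t = float(rng.uniform(lo, hi - dur))
                if all(abs(t - v[0]) > 2700.0 for v in visits):
                    visits.append((t, t + dur))
        visits.sort()
        cursor = s_start
        for v_lo, v_hi in visits:
            if v_lo - cursor >= 3600.0:  # keep sleep fragments classifiable
                events.append(_Interval(ADLLabel.SLEEPING, profile.sleep_compartment, cursor, v_lo))
                events.append(_Interval(ADLLabel.TOILETING, "bathroom", v_lo, v_hi))
                cursor = v_hi
        events.append(_Interval(ADLLabel.SLEEPING, profile.sleep_compartment, cursor, s_end))

    # --- anchored daytime activities
    night_blocks = [
        _Interval(ADLLabel.SLEEPING, profile.sleep_compartment, s - 900.0, e)
        for s, e in sleep_blocks
    ]

    def try_place(
        label: ADLLabel,
        compartment: str,
        start: float,
        dur: float,
        day_lo: float,
        day_hi: float,
    ) -> _Interval | None:
        placed = events + night_blocks
        t = max(start, day_lo)
        for _ in range(12):
            if t + dur > day_hi:
                return None
            hit = _overlaps(t, t + dur, placed)
            if hit is None:
                iv = _Interval(label, compartment, t, t + dur)
                events.append(iv)
                return iv
            t = hit.end + 180.0
        return None

    cooking_spec = profile.activity(ADLLabel.COOKING)
    for d in range(n_days):
        base = day0 + d * SECONDS_PER_DAY
        wake = wakes[d]
        bedtime = sleep_blocks[d][0]
        day_lo = wake + 300.0
        day_hi = bedtime - 1500.0  # leave room for getting ready

        order = (
            ADLLabel.GROOMING,
            ADLLabel.COOKING,
            ADLLabel.WATCHING_TV,
            ADLLabel.SEATED_ACTIVITY,
            ADLLabel.TOILETING,
        )
        for label in order:
            spec = profile.activity(label)
            if spec is None:
                continue
            for anchor_s, prob in spec.anchors:
                if det:
                    include = prob >= 0.5
                else:
                    include = bool(rng.random() < prob)
                if not include:
                    continue
                if anchor_s < 0:  # relative to wake (morning grooming)
                    center = wake + 1200.0
                else:
                    center = base + anchor_s
                start = _jittered(
                    rng,
                    center,
                    jitter,
                    (base + spec.start_window[0], base + spec.start_window[1]),
                    det,
                )
                dur = _truncated_lognormal(
                    rng, spec.duration_median_s, spec.duration_sigma, spec.duration_bounds_s, det
                )
                if label is ADLLabel.WATCHING_TV:
                    dur = min(dur, max(bedtime - 1800.0 - start, 0.0))
                    if dur < spec.duration_bounds_s[0]:
                        continue
                placed = try_place(label, spec.compartment, start, dur, day_lo, day_hi)
                # eating follows cooking within a short lag
                if (
                    placed is not None
                    and label is ADLLabel.COOKING
                    and profile.eating_spec is not None
                ):
                    if det:
                        take = profile.eating_after_cooking_prob >= 0.5
                        lag = sum(profile.eating_lag_bounds_s) / 2.0
                    else:
                        take = bool(rng.random() < profile.eating_after_cooking_prob)
                        lag = float(rng.uniform(*profile.eating_lag_bounds_s))
                    if take:
                        espec = profile.eating_spec
                        edur = _truncated_lognormal(
                            rng,
                            espec.duration_median_s,
                            espec.duration_sigma,
                            espec.duration_bounds_s,
                            det,
                        )
                        try_place(
                            espec.label,
                            espec.compartment,
                            placed.end + lag,
                            edur,
                            day_lo,
                            day_hi,
                        )

    events.sort(key=lambda iv: iv.start)
    out = [
        ADLEvent(
            label=iv.label,
            start=_to_dt(iv.start),
            end=_to_dt(iv.end),
            compartment=iv.compartment,
            source="ground_truth",
            provenance="device",
        )
        for iv in events
    ]
    log = GroundTruthLog(out)
    bad = log.validate()
    if bad:  # pragma: no cover - scheduler guarantees this
        raise AdlSenseError("scheduler produced invalid log: " + "; ".join(bad))
    return log


def _to_dt(abs_s: float) -> dt.datetime:
    ordinal, sod = divmod(abs_s, SECONDS_PER_DAY)
    day = dt.date.fromordinal(int(ordinal))
    return dt.datetime(day.year, day.month, day.day) + dt.timedelta(seconds=float(sod))


# ---------------------------------------------------------------------------
# Ambient rendering
# ---------------------------------------------------------------------------


@dataclass
class StreamSet:
    """Per-box ambient sample streams on the 5 s grid.

    ``box_streams[node_id]`` is an (n_samples, 5) float array in canonical
    channel order; sample ``i`` belongs to absolute second
    ``start_abs_s + 5 * i``.
    """

    start_date: dt.date
    n_samples: int
    box_streams: dict[int, np.ndarray]
    layout: HomeLayout

    @property
    def start_abs_s(self) -> int:
        return self.start_date.toordinal() * SECONDS_PER_DAY

    @property
    def times_abs_s(self) -> np.ndarray:
        return self.start_abs_s + SAMPLING_PERIOD_S * np.arange(self.n_samples)


_MOVEMENT = {label: 0.6 for label in ADLLabel}
_MOVEMENT.update(
    {
        ADLLabel.SLEEPING: 0.01,
        ADLLabel.WATCHING_TV: 0.06,
        ADLLabel.SEATED_ACTIVITY: 0.12,
        ADLLabel.EATING: 0.14,
        ADLLabel.COOKING: 0.7,
    }
)

_IDLE = -2
_ABSENT = -1


def render_ambient(
    truth: GroundTruthLog, config: SimConfig, rng: np.random.Generator | None = None
) -> StreamSet:
    """Render ground-truth events into per-box ambient streams.

    Occupancy drives PIR motion in the occupied room only; grooming raises
    bathroom humidity with a linear-rise / exponential-decay pulse; cooking
    does the same for kitchen temperature and humidity and shakes the
    fridge-door accelerometer; toileting ends with a flush-handle
    transient; TV watching imposes the TV luminance signature during dark
    hours.  Events extending past the rendered range are clipped.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    layout, em, profile = config.layout, config.emission, config.profile
    n = config.n_days * SAMPLES_PER_DAY
    t0 = config.start_date.toordinal() * SECONDS_PER_DAY
    sod = (SAMPLING_PERIOD_S * np.arange(n) + t0) % SECONDS_PER_DAY

    comp_index = {c: i for i, c in enumerate(layout.compartments)}
    occupancy = np.full(n, _ABSENT, dtype=np.int32)
    movement = np.zeros(n, dtype=float)
    lamp_wanted = np.zeros(n, dtype=bool)
    tv_active = np.zeros(n, dtype=bool)

    def clip_idx(abs_start: float, abs_end: float) -> tuple[int, int]:
        i0 = int(max(0, math.ceil((abs_start - t0) / SAMPLING_PERIOD_S)))
        i1 = int(min(n, math.ceil((abs_end - t0) / SAMPLING_PERIOD_S)))
        return i0, i1

    events = truth.sorted()

    # idle filler between consecutive events: putter in kitchen/dining
    idle_segments: list[tuple[float, float]] = []
    for prev, nxt in zip(events, events[1:]):
        gap_lo = _abs(prev.end)
        gap_hi = _abs(nxt.start)
        if gap_hi - gap_lo > 60.0:
            idle_segments.append((gap_lo, gap_hi))
    idle_rooms = [c for c in profile.idle_compartments if c in comp_index]
    for lo, hi in idle_segments:
        cursor = lo
        prev_room = None
        while cursor < hi - 30.0:
            dwell = float(rng.uniform(*profile.idle_dwell_bounds_s))
            room_choices = [r for r in idle_rooms if r != prev_room] or idle_rooms
            room = room_choices[int(rng.integers(len(room_choices)))] if room_choices else None
            end = min(cursor + dwell, hi)
            if room is not None:
                i0, i1 = clip_idx(cursor, end)
                occupancy[i0:i1] = comp_index[room]
                movement[i0:i1] = profile.idle_movement
                lamp_wanted[i0:i1] = True
            prev_room = room
            cursor = end

    # channel effect accumulators per compartment
    hum_extra = {c: np.zeros(n) for c in layout.compartments}
    temp_extra = {c: np.zeros(n) for c in layout.compartments}
    accel_fridge = np.zeros(n)
    accel_flush = np.zeros(n)

    def add_pulse(arr: np.ndarray, i0: int, i1: int, amp: float) -> None:
        if i1 <= i0:
            return
        rise = np.linspace(0.0, amp, i1 - i0, endpoint=True)
        arr[i0:i1] += rise
        tail = np.arange(n - i1) * SAMPLING_PERIOD_S
        arr[i1:] += amp * np.exp(-tail / em.pulse_decay_s)

    def add_transients(arr: np.ndarray, i0: int, i1: int, count: int) -> None:
        if i1 - i0 < 4 or count < 1:
            return
        slots = sorted(
            rng.choice(np.arange(i0 + 1, i1 - 1), size=min(count, i1 - i0 - 2), replace=False).tolist()
        )
        last = -10
        for s in slots:
            if s - last >= 4:  # >= 20 s apart
                arr[s] += em.transient_amp_ms2
                last = s

    # paint events longest-first so short events override enclosing ones
    for event in sorted(events, key=lambda e: -e.duration_s):
        abs_start = _abs(event.start)
        abs_end = _abs(event.end)
        i0, i1 = clip_idx(abs_start, abs_end)
        if i1 <= i0:
            continue
        occupancy[i0:i1] = comp_index[event.compartment]
        movement[i0:i1] = _MOVEMENT[event.label]
        lamp_wanted[i0:i1] = event.label is not ADLLabel.SLEEPING
        tv_active[i0:i1] = event.label is ADLLabel.WATCHING_TV

        if event.label is ADLLabel.GROOMING:
            add_pulse(hum_extra[event.compartment], i0, i1, em.shower_humidity_amp_gm3)
            if rng.random() < em.grooming_flush_prob:
                j = min(i1 - 2, n - 1)
                accel_flush[j] += em.transient_amp_ms2
        elif event.label is ADLLabel.COOKING:
            add_pulse(temp_extra[event.compartment], i0, i1, em.cooking_temperature_amp_c)
            add_pulse(hum_extra[event.compartment], i0, i1, em.cooking_humidity_amp_gm3)
            add_transients(accel_fridge, i0, i1, 1 + int(rng.poisson(0.7)))
        elif event.label is ADLLabel.TOILETING:
            j = max(i0, min(i1 - 1 - int(em.flush_end_offset_s // SAMPLING_PERIOD_S), n - 1))
            accel_flush[j] += em.transient_amp_ms2

    daylight = em.daylight_lx(sod)
    hold = max(1, int(round(em.pir_hold_s / SAMPLING_PERIOD_S)))

    streams: dict[int, np.ndarray] = {}
    room_cache: dict[str, np.ndarray] = {}
    for comp in layout.compartments:
        ci = comp_index[comp]
        occ = occupancy == ci
        room_day = daylight * em.room_attenuation(comp)

        moves = occ & (rng.random(n) < movement)
        trig = moves & (rng.random(n) < em.pir_trigger_prob)
        if em.pir_false_rate > 0:
            trig |= rng.random(n) < em.pir_false_rate
        motion = trig.copy()
        for k in range(1, hold + 1):
            motion[k:] |= trig[:-k]

        lum = room_day.copy()
        dark = room_day < em.lamp_on_threshold_lx
        lamp_on = occ & lamp_wanted & dark
        tv_here = occ & tv_active & dark
        lum = np.where(tv_here, em.tv_lx, np.where(lamp_on & ~tv_here, em.lamp_lx, lum))

        temp = em.temperature_base_c + temp_extra[comp]
        hum = em.humidity_base_gm3 + hum_extra[comp]

        def noisy(arr, key, clip_zero=False):
            sd = em.noise_sd.get(key, 0.0)
            if sd > 0:
                arr = arr + sd * rng.standard_normal(n)
            if clip_zero:
                arr = np.clip(arr, 0.0, None)
            return arr

        room_cache[comp] = np.column_stack(
            [
                noisy(temp, "temperature"),
                noisy(hum, "humidity"),
                noisy(lum, "luminance", clip_zero=True),
                motion.astype(float),
                noisy(np.zeros(n), "acceleration", clip_zero=True),
            ]
        )

    for box in layout.boxes:
        base = room_cache[box.compartment]
        if box.placement is Placement.WALL:
            streams[box.node_id] = base
        else:
            s = base.copy()
            s[:, 3] = 0.0  # appliance boxes face the appliance, not the room
            accel = accel_fridge if box.placement is Placement.FRIDGE_DOOR else accel_flush
            sd = em.noise_sd.get("acceleration", 0.0)
            noise = sd * rng.standard_normal(n) if sd > 0 else 0.0
            s[:, 4] = np.clip(accel + noise, 0.0, None)
            streams[box.node_id] = s

    return StreamSet(
        start_date=config.start_date, n_samples=n, box_streams=streams, layout=layout
    )


def _abs(moment: dt.datetime) -> float:
    return (
        moment.date().toordinal() * SECONDS_PER_DAY
        + moment.hour * 3600
        + moment.minute * 60
        + moment.second
        + moment.microsecond / 1e6
    )


# ---------------------------------------------------------------------------
# Packetization
# ---------------------------------------------------------------------------


@dataclass
class ChannelReport:
    """Transmission accounting for one packetized stream set."""

    sent: int
    lost: int
    corrupted: int

    @property
    def captured(self) -> int:
        return self.sent - self.lost


def packetize(
    streams: StreamSet,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[DataPacket], ChannelReport]:
    """Turn sample streams into data packets over a lossy link.

    Every sample becomes one packet; each packet is independently dropped
    with ``packet_loss_rate`` and bit-corrupted with
    ``bit_corruption_rate``.  Corrupted packets take a round trip through
    the codec with one flipped payload bit, so their ``parity_ok`` flag is
    the even-parity verdict, not an assumption.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = streams.n_samples
    t0_ord = streams.start_date.toordinal()
    packets: list[DataPacket] = []
    sent = lost = corrupted = 0
    for node_id in sorted(streams.box_streams):
        data = streams.box_streams[node_id]
        keep = rng.random(n) >= config.packet_loss_rate
        corrupt = rng.random(n) < config.bit_corruption_rate
        sent += n
        lost += int(n - keep.sum())
        kept_idx = np.flatnonzero(keep)
        sod = (SAMPLING_PERIOD_S * kept_idx) % SECONDS_PER_DAY
        day = (SAMPLING_PERIOD_S * kept_idx) // SECONDS_PER_DAY
        voltage = np.round(3.0 - 2e-8 * SAMPLING_PERIOD_S * kept_idx, 4)
        for j, i in enumerate(kept_idx):
            row = data[i]
            packet = DataPacket(
                node_id=node_id,
                date=dt.date.fromordinal(t0_ord + int(day[j])),
                timestamp=int(sod[j]),
                supply_voltage=float(voltage[j]),
                status_word=0,
                values=(
                    float(row[0]),
                    float(row[1]),
                    max(float(row[2]), 0.0),
                    float(row[3]),
                    max(float(row[4]), 0.0),
                ),
            )
            if corrupt[i]:
                record = codec.corrupt_record(codec.encode_packet(packet), rng)
                try:
                    packet = codec.decode_packet(record)
                except codec.DecodeError:
                    # hit a structural field; keep the packet, flagged,
                    # like any other parity failure
                    packet.parity_ok = False
                    packet.raw = record
                if not packet.parity_ok:
                    corrupted += 1
            packets.append(packet)
    return packets, ChannelReport(sent=sent, lost=lost, corrupted=corrupted)


# ---------------------------------------------------------------------------
# Study-scale simulation
# ---------------------------------------------------------------------------


def derive_home_seeds(master_seed: int, n_homes: int) -> list[int]:
    """Deterministic per-home seeds below 2**31."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n_homes)]


def simulate_home(
    config: SimConfig,
) -> tuple[GroundTruthLog, StreamSet, list[DataPacket], ChannelReport]:
    """Run routine -> ambient -> packets for one home under one seed."""
    ss = np.random.SeedSequence(config.seed)
    r_routine, r_render, r_packet = [np.random.default_rng(s) for s in ss.spawn(3)]
    truth = generate_routine(
        config.profile, config.layout, config.n_days, r_routine, config.start_date
    )
    streams = render_ambient(truth, config, r_render)
    packets, report = packetize(streams, config, r_packet)
    return truth, streams, packets, report


def simulate_study(
    n_homes: int,
    n_days: int,
    base_config: SimConfig,
    seed: int,
    out_dir: str | os.PathLike | None = None,
    dialect: str = "csv",
):
    """Simulate a multi-home study; optionally write one packet file and
    one truth log per home plus a manifest.

    Per-home seeds are derived deterministically from the master seed, so
    re-running with the same arguments reproduces byte-identical outputs.
    When ``out_dir`` is None, yields ``(home_index, truth, streams,
    packets, report)`` lazily to bound memory.
    """
    if n_homes < 1:
        raise AdlSenseError("n_homes must be >= 1")
    seeds = derive_home_seeds(seed, n_homes)

    def runs():
        for h in range(n_homes):
            cfg = replace(base_config, n_days=n_days, seed=seeds[h])
            truth, streams, packets, report = simulate_home(cfg)
            yield h, truth, streams, packets, report

    if out_dir is None:
        return runs()

    os.makedirs(out_dir, exist_ok=True)
    manifest = {
        "n_homes": n_homes,
        "n_days": n_days,
        "master_seed": seed,
        "home_seeds": seeds,
        "packet_loss_rate": base_config.packet_loss_rate,
        "bit_corruption_rate": base_config.bit_corruption_rate,
        "start_date": base_config.start_date.isoformat(),
        "dialect": dialect,
        "homes": [],
    }
    from .domain import write_events_csv

    for h, truth, streams, packets, report in runs():
        pfile = os.path.join(out_dir, f"home{h:02d}.packets.{dialect}")
        tfile = os.path.join(out_dir, f"home{h:02d}.truth.csv")
        codec.write_packets(packets, pfile, dialect)
        write_events_csv(truth.sorted(), tfile)
        manifest["homes"].append(
            {
                "home": h,
                "seed": seeds[h],
                "packets": os.path.basename(pfile),
                "truth": os.path.basename(tfile),
                "sent": report.sent,
                "lost": report.lost,
                "corrupted": report.corrupted,
            }
        )
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
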