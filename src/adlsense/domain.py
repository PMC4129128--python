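"""Shared vocabulary for ambient ADL monitoring.

This module defines the eight activity-of-daily-living labels, the five
ambient sensor channels, sensor boxes and home layouts, the 0.2 Hz data
packet, and labeled activity events.  Everything downstream (simulator,
sorting pipeline, rule engine, evaluation) speaks these types.

Time model
----------
A packet carries a calendar date plus an integer seconds-of-day on a 5 s
grid (the 0.2 Hz sampling period).  Events carry naive datetimes.  There
are no time zones and no DST; the intra-day timeline is what the sorting
pipeline and the activity maps are defined on.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

SAMPLING_PERIOD_S = 5  # 1 / 0.2 Hz
SECONDS_PER_DAY = 86_400
SAMPLES_PER_DAY = SECONDS_PER_DAY // SAMPLING_PERIOD_S  # 17 280


class AdlSenseError(Exception):
    """Base class for all package errors."""


class PacketValidationError(AdlSenseError):
    """A packet field violates its invariant; the message names the field."""


class ADLLabel(str, Enum):
    """The eight recognized activities of daily living.

    Each label carries a short include/exclude definition used for
    documentation and reporting; the set is closed by design.
    """

    SLEEPING = "sleeping"
    GROOMING = "grooming"
    TOILETING = "toileting"
    GETTING_READY_FOR_BED = "getting_ready_for_bed"
    COOKING = "cooking"
    EATING = "eating"
    WATCHING_TV = "watching_tv"
    SEATED_ACTIVITY = "seated_activity"

    @property
    def definition(self) -> str:
        return _ADL_DEFINITIONS[self]


_ADL_DEFINITIONS: dict[ADLLabel, str] = {
    ADLLabel.SLEEPING: (
        "Night rest or a nap, in bed or on the couch. "
        "Does not include lying down awake to rest."
    ),
    ADLLabel.GROOMING: (
        "Full personal hygiene as one activity: showering, shaving, "
        "brushing teeth, styling (toilet use during it included). "
        "Does not include a simple toilet visit with hand washing."
    ),
    ADLLabel.TOILETING: (
        "A simple toilet visit with hand washing. "
        "Does not include any further personal hygiene."
    ),
    ADLLabel.GETTING_READY_FOR_BED: (
        "Personal hygiene immediately before bedtime. "
        "Does not include other pre-bedtime rituals."
    ),
    ADLLabel.COOKING: (
        "Preparing food in the kitchen. Does not include trivial "
        "preparation such as making tea or coffee or cutting delivered food."
    ),
    ADLLabel.EATING: (
        "Having a meal, including delivered food. Does not include "
        "snacking or having only a drink."
    ),
    ADLLabel.WATCHING_TV: (
        "Watching TV with the TV as the main focus. Does not include "
        "other activities while the TV merely runs."
    ),
    ADLLabel.SEATED_ACTIVITY: (
        "Sitting at a table or in an easy chair while reading, solving "
        "puzzles, doing crafts, or listening to the radio. Not a nap."
    ),
}

ADL_LABELS: tuple[ADLLabel, ...] = tuple(ADLLabel)


class SensorChannel(str, Enum):
    """The five ambient channels captured by every sensor box."""

    TEMPERATURE = "temperature"
    HUMIDITY = "humidity"
    LUMINANCE = "luminance"
    MOTION = "motion"
    ACCELERATION = "acceleration"

    @property
    def unit(self) -> str:
        return _CHANNEL_UNITS[self]


_CHANNEL_UNITS: dict[SensorChannel, str] = {
    SensorChannel.TEMPERATURE: "°C",
    SensorChannel.HUMIDITY: "g/m³",  # absolute humidity
    SensorChannel.LUMINANCE: "lx",
    SensorChannel.MOTION: "binary",
    SensorChannel.ACCELERATION: "m/s²",  # magnitude, not a 3-axis vector
}

CHANNELS: tuple[SensorChannel, ...] = tuple(SensorChannel)
N_CHANNELS = len(CHANNELS)


class Placement(str, Enum):
    WALL = "wall"
    FRIDGE_DOOR = "fridge_door"
    FLUSH_HANDLE = "flush_handle"


@dataclass(frozen=True)
class SensorBox:
    """One wireless sensor box: a node id, the room it serves, and where
    it is mounted (wall at ~2 m height, or on an appliance)."""

    node_id: int
    compartment: str
    placement: Placement = Placement.WALL


@dataclass
class HomeLayout:
    """Rooms of a single-occupant home and the sensor boxes installed in
    them.  Every room carries a wall box; the kitchen additionally has a
    fridge-door box and the bathroom a flush-handle box."""

    compartments: list[str]
    boxes: list[SensorBox]

    def wall_boxes(self, compartment: str) -> list[SensorBox]:
        return [
            b
            for b in self.boxes
            if b.compartment == compartment and b.placement is Placement.WALL
        ]

    def appliance_boxes(self, compartment: str) -> list[SensorBox]:
        return [
            b
            for b in self.boxes
            if b.compartment == compartment and b.placement is not Placement.WALL
        ]

    def box(self, node_id: int) -> SensorBox:
        for b in self.boxes:
            if b.node_id == node_id:
                return b
        raise KeyError(f"no box with node_id {node_id}")

    def compartment_of(self, node_id: int) -> str:
        return self.box(node_id).compartment

    @property
    def node_ids(self) -> list[int]:
        return [b.node_id for b in self.boxes]


def default_layout() -> HomeLayout:
    """Five-room apartment with one wall box per room plus the two
    appliance boxes (fridge door, flush handle)."""
    rooms = ["living_room", "dining_room", "kitchen", "bathroom", "bedroom"]
    boxes = [SensorBox(i + 1, room) for i, room in enumerate(rooms)]
    boxes.append(SensorBox(6, "kitchen", Placement.FRIDGE_DOOR))
    boxes.append(SensorBox(7, "bathroom", Placement.FLUSH_HANDLE))
    return HomeLayout(compartments=rooms, boxes=boxes)


def validate_layout(layout: HomeLayout) -> list[str]:
    """Check all layout invariants; violations are returned as data, not
    raised.  An empty list means the layout is valid."""
    violations: list[str] = []
    seen: set[int] = set()
    for box in layout.boxes:
        if box.node_id in seen:
            violations.append(f"duplicate node_id {box.node_id}")
        seen.add(box.node_id)
        if box.compartment not in layout.compartments:
            violations.append(
                f"box {box.node_id} placed in unknown compartment "
                f"'{box.compartment}'"
            )
        if box.placement is Placement.FRIDGE_DOOR and box.compartment != "kitchen":
            violations.append(
                f"fridge_door box {box.node_id} outside the kitchen"
            )
        if box.placement is Placement.FLUSH_HANDLE and box.compartment != "bathroom":
            violations.append(
                f"flush_handle box {box.node_id} outside the bathroom"
            )
    for required in ("kitchen", "bathroom"):
        if required not in layout.compartments:
            violations.append(f"required compartment '{required}' missing")
    for room in layout.compartments:
        if not layout.wall_boxes(room):
            violations.append(f"compartment '{room}' has no wall box")
    return violations


@dataclass(slots=True)
class DataPacket:
    """One 0.2 Hz transmission from one sensor box.

    The handshake part is (timestamp, date, node number, supply voltage,
    status word); the payload is one reading per ambient channel in the
    canonical channel order.  ``parity_ok`` reflects the even-parity check
    of the serialized record (True for packets that never went through a
    corrupted link).
    """

    node_id: int
    date: dt.date
    timestamp: int  # seconds of day, multiple of 5
    supply_voltage: float
    status_word: int  # opaque bit-field
    values: tuple[float, ...]  # one per SensorChannel, canonical order
    parity_ok: bool = True
    # corrupted packets keep the record as received so that serializing
    # them again preserves the corruption (and its parity verdict)
    raw: str | None = None

    def value(self, channel: SensorChannel) -> float:
        return self.values[CHANNELS.index(channel)]

    @property
    def abs_seconds(self) -> int:
        """Seconds since day 0 of the proleptic Gregorian ordinal; a total
        order over (date, time-of-day)."""
        return self.date.toordinal() * SECONDS_PER_DAY + self.timestamp


def validate_packet(packet: DataPacket) -> None:
    """Raise :class:`PacketValidationError` naming the offending field."""
    if not 0 <= packet.timestamp < SECONDS_PER_DAY:
        raise PacketValidationError(
            f"timestamp {packet.timestamp} outside [0, {SECONDS_PER_DAY})"
        )
    if packet.timestamp % SAMPLING_PERIOD_S != 0:
        raise PacketValidationError(
            f"timestamp {packet.timestamp} not on the {SAMPLING_PERIOD_S} s grid"
        )
    if len(packet.values) != N_CHANNELS:
        raise PacketValidationError(
            f"values has {len(packet.values)} entries, expected {N_CHANNELS}"
        )
    motion = packet.values[CHANNELS.index(SensorChannel.MOTION)]
    if motion not in (0.0, 1.0):
        raise PacketValidationError(f"motion value {motion} not binary")
    lum = packet.values[CHANNELS.index(SensorChannel.LUMINANCE)]
    if lum < 0:
        raise PacketValidationError(f"luminance {lum} negative")
    acc = packet.values[CHANNELS.index(SensorChannel.ACCELERATION)]
    if acc < 0:
        raise PacketValidationError(f"acceleration magnitude {acc} negative")
    if packet.node_id < 0:
        raise PacketValidationError(f"node_id {packet.node_id} negative")


GROUND_TRUTH = "ground_truth"
CLASSIFIED = "classified"


@dataclass
class ADLEvent:
    """A labeled activity interval, used both as ground truth and as
    classifier output."""

    label: ADLLabel
    start: dt.datetime
    end: dt.datetime
    compartment: str
    source: str = GROUND_TRUTH
    provenance: str = "device"  # device | paper_logbook (ground truth only)

    def __post_init__(self) -> None:
        self.label = ADLLabel(self.label)
        if self.start >= self.end:
            raise PacketValidationError(
                f"event start {self.start} not before end {self.end}"
            )

    @property
    def duration_s(self) -> float:
        return (self.end - self.start).total_seconds()

    def overlap_s(self, other: "ADLEvent") -> float:
        lo = max(self.start, other.start)
        hi = min(self.end, other.end)
        return max(0.0, (hi - lo).total_seconds())


@dataclass
class GroundTruthLog:
    """The subject's activity protocol: switch-device events merged with
    paper log-book corrections.  No two events of the same label overlap."""

    events: list[ADLEvent] = field(default_factory=list)

    def validate(self) -> list[str]:
        violations = []
        by_label: dict[ADLLabel, list[ADLEvent]] = {}
        for e in self.events:
            by_label.setdefault(e.label, []).append(e)
        for label, evs in by_label.items():
            evs = sorted(evs, key=lambda e: e.start)
            for a, b in zip(evs, evs[1:]):
                if a.end > b.start:
                    violations.append(
                        f"overlapping {label.value} events at {b.start}"
                    )
        return violations

    def sorted(self) -> list[ADLEvent]:
        return sorted(self.events, key=lambda e: (e.start, e.end))


# --- event CSV schema -------------------------------------------------------

EVENT_CSV_COLUMNS = ["label", "start", "end", "compartment", "source", "provenance"]


def events_to_frame(events: Iterable[ADLEvent]):
    import pandas as pd

    rows = [
        {
            "label": e.label.value,
            "start": e.start.isoformat(),
            "end": e.end.isoformat(),
            "compartment": e.compartment,
            "source": e.source,
            "provenance": e.provenance,
        }
        for e in events
    ]
    return pd.DataFrame(rows, columns=EVENT_CSV_COLUMNS)


def events_from_frame(frame) -> list[ADLEvent]:
    events = []
    for row in frame.itertuples(index=False):
        events.append(
            ADLEvent(
                label=ADLLabel(row.label),
                start=dt.datetime.fromisoformat(row.start),
                end=dt.datetime.fromisoformat(row.end),
                compartment=row.compartment,
                source=getattr(row, "source", GROUND_TRUTH),
                provenance=getattr(row, "provenance", "device"),
            )
        )
    return events


def write_events_csv(events: Sequence[ADLEvent], path) -> None:
    events_to_frame(events).to_csv(path, index=False)


def read_events_csv(path) -> list[ADLEvent]:
    import pandas as pd

    return events_from_frame(pd.read_csv(path, dtype=str))


# --- layout JSON ------------------------------------------------------------


def layout_to_dict(layout: HomeLayout) -> dict:
    return {
        "compartments": list(layout.compartments),
        "boxes": [
            {
                "node_id": b.node_id,
                "compartment": b.compartment,
                "placement": b.placement.value,
            }
            for b in layout.boxes
        ],
    }


def layout_from_dict(obj: dict) -> HomeLayout:
    try:
        boxes = [
            SensorBox(
                node_id=int(b["node_id"]),
                compartment=str(b["compartment"]),
                placement=Placement(b.get("placement", "wall")),
            )
            for b in obj["boxes"]
        ]
        return HomeLayout(
            compartments=[str(c) for c in obj["compartments"]], boxes=boxes
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise PacketValidationError(f"malformed layout description: {exc}") from exc


def abs_seconds(moment: dt.datetime) -> float:
    """datetime -> seconds on the same absolute axis as DataPacket.abs_seconds."""
    return (
        moment.date().toordinal() * SECONDS_PER_DAY
        + moment.hour * 3600
        + moment.minute * 60
        + moment.second
        + moment.microsecond / 1e6
    )


def from_abs_seconds(seconds: float) -> dt.datetime:
    ordinal, sod = divmod(int(round(seconds)), SECONDS_PER_DAY)
    day = dt.date.fromordinal(ordinal)
    return dt.datetime(day.year, day.month, day.day) + dt.timedelta(seconds=sod)
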