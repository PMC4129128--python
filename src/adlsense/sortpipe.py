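"""Preprocessing chain: compartment-wise Bucketsort, chronological
Radixsort, and transmission-integrity accounting.

Incoming packets are first partitioned into one bucket per compartment in
a single stable pass (each packet's node id maps bijectively to the room
where it was captured).  Each bucket is then ordered chronologically by a
least-significant-digit-first radix sort over a five-component intra-day
time key: second-of-minute, minute, hour, day-of-month, month.  When the
data span more than one calendar year an extra year pass runs, so the
contract — a stable ascending order by (date, seconds-of-day) in linear
time — holds for any input.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .domain import AdlSenseError, DataPacket, HomeLayout


class RoutingError(AdlSenseError):
    """A packet's node id does not exist in the home layout."""


class AccountingError(AdlSenseError):
    """Captured packets exceed the expected/sent count."""


@dataclass
class CompartmentBucket:
    compartment: str
    packets: list[DataPacket] = field(default_factory=list)


def bucket_sort(
    packets: Iterable[DataPacket], layout: HomeLayout
) -> list[CompartmentBucket]:
    """Stable one-pass partition of packets into per-compartment buckets.

    Buckets come back in layout order and include empty compartments;
    relative packet order within each bucket is preserved.  An unknown
    node id raises :class:`RoutingError` naming the packet.
    """
    node_to_comp = {b.node_id: b.compartment for b in layout.boxes}
    buckets = {c: CompartmentBucket(c) for c in layout.compartments}
    for i, p in enumerate(packets):
        comp = node_to_comp.get(p.node_id)
        if comp is None:
            raise RoutingError(
                f"packet #{i} ({p.date} t={p.timestamp}) from unknown node "
                f"{p.node_id}"
            )
        buckets[comp].packets.append(p)
    return [buckets[c] for c in layout.compartments]


def _counting_pass(
    packets: list[DataPacket], key: Callable[[DataPacket], int], size: int
) -> list[DataPacket]:
    bins: list[list[DataPacket]] = [[] for _ in range(size)]
    for p in packets:
        bins[key(p)].append(p)
    out: list[DataPacket] = []
    for b in bins:
        out.extend(b)
    return out


def radix_sort_chronological(
    bucket: CompartmentBucket | Sequence[DataPacket],
) -> list[DataPacket]:
    """Stable LSD radix sort by (date, seconds-of-day).

    Five counting passes over the intra-day time key (second-of-minute,
    minute, hour, day-of-month, month); a year pass is appended only when
    needed.  Output is a permutation of the input.
    """
    packets = list(bucket.packets if isinstance(bucket, CompartmentBucket) else bucket)
    if len(packets) <= 1:
        return packets
    packets = _counting_pass(packets, lambda p: p.timestamp % 60, 60)
    packets = _counting_pass(packets, lambda p: (p.timestamp // 60) % 60, 60)
    packets = _counting_pass(packets, lambda p: p.timestamp // 3600, 24)
    packets = _counting_pass(packets, lambda p: p.date.day, 32)
    packets = _counting_pass(packets, lambda p: p.date.month, 13)
    years = {p.date.year for p in packets}
    if len(years) > 1:
        y0 = min(years)
        packets = _counting_pass(packets, lambda p: p.date.year - y0, max(years) - y0 + 1)
    return packets


@dataclass
class IntegrityReport:
    """Captured-vs-lost accounting, as percentages to two decimals."""

    captured: int
    lost: int
    corrupted: int = 0

    @property
    def expected(self) -> int:
        return self.captured + self.lost

    @property
    def reliability_pct(self) -> float:
        if self.expected == 0:
            return 100.0
        return round(100.0 * self.captured / self.expected, 2)

    @property
    def lost_share_pct(self) -> float:
        if self.expected == 0:
            return 0.0
        return round(100.0 * self.lost / self.expected, 2)

    def to_dict(self) -> dict:
        return {
            "captured": self.captured,
            "lost": self.lost,
            "corrupted": self.corrupted,
            "reliability_pct": self.reliability_pct,
            "lost_share_pct": self.lost_share_pct,
        }


def integrity_report(
    expected: int, captured_packets: Sequence[DataPacket] | int
) -> IntegrityReport:
    """Build the transmission report from the expected (sent) count and
    the packets actually captured; corrupted packets are those whose
    even-parity check failed."""
    if isinstance(captured_packets, int):
        captured, corrupted = captured_packets, 0
    else:
        captured = len(captured_packets)
        corrupted = sum(1 for p in captured_packets if not p.parity_ok)
    if expected < captured:
        raise AccountingError(
            f"expected count {expected} below captured count {captured}"
        )
    return IntegrityReport(captured=captured, lost=expected - captured, corrupted=corrupted)


def sort_packets(
    packets: Sequence[DataPacket], layout: HomeLayout, expected: int | None = None
) -> tuple[dict[str, list[DataPacket]], IntegrityReport]:
    """Full Fig-style preprocessing chain for one home.

    Parity-failed packets are excluded before sorting and counted in the
    integrity report; the rest is bucketed per compartment and ordered
    chronologically.
    """
    report = integrity_report(
        expected if expected is not None else len(packets), packets
    )
    clean = [p for p in packets if p.parity_ok]
    sorted_streams = {
        b.compartment: radix_sort_chronological(b)
        for b in bucket_sort(clean, layout)
    }
    return sorted_streams, report
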