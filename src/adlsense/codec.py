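"""Text serialization of sensor packets with even-parity error handling.

Two dialects are supported:

``csv``
    One record per line, fixed column order
    (:data:`CSV_COLUMNS`), parity bit as the last column.
``jsonl``
    One JSON object per line with named fields plus a ``parity`` key.

The parity bit is computed over the UTF-8 bytes of the serialized payload
(everything except the parity field itself) so that the total number of
one-bits, including the stored bit, is even.  A single flipped payload bit
is always detected; two flips within the same record cancel out — the
classic even-parity blind spot.
"""
from __future__ import annotations

import datetime as dt
import json
from typing import Iterable, Sequence

from .domain import (
    AdlSenseError,
    CHANNELS,
    DataPacket,
    validate_packet,
)

CSV_COLUMNS = (
    "node_id",
    "date",
    "timestamp",
    "supply_voltage",
    "status_word",
    *(ch.value for ch in CHANNELS),
    "parity",
)

CSV_HEADER = ",".join(CSV_COLUMNS)

DIALECTS = ("csv", "jsonl")


class DecodeError(AdlSenseError):
    """A record is structurally unparseable (distinct from a parity failure,
    which is reported in-band via ``parity_ok``)."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        prefix = f"line {line_number}: " if line_number is not None else ""
        super().__init__(prefix + message)


def _bit_parity(data: bytes) -> int:
    return int.from_bytes(data, "big").bit_count() & 1 if data else 0


def _format_float(x: float) -> str:
    # repr round-trips exactly; integers render compactly
    if float(x).is_integer():
        return str(int(x))
    return repr(float(x))


def _payload_csv(packet: DataPacket) -> str:
    fields = [
        str(packet.node_id),
        packet.date.isoformat(),
        str(packet.timestamp),
        _format_float(packet.supply_voltage),
        str(packet.status_word),
        *(_format_float(v) for v in packet.values),
    ]
    return ",".join(fields)


def _payload_jsonl(packet: DataPacket) -> str:
    obj = {
        "node_id": packet.node_id,
        "date": packet.date.isoformat(),
        "timestamp": packet.timestamp,
        "supply_voltage": packet.supply_voltage,
        "status_word": packet.status_word,
        "values": list(packet.values),
    }
    return json.dumps(obj, sort_keys=True, separators=(",", ":"))


def encode_packet(packet: DataPacket, dialect: str = "csv") -> str:
    """Serialize one valid packet to a single record string.

    Raises :class:`~adlsense.domain.PacketValidationError` naming the field
    if the packet violates its invariants.
    """
    validate_packet(packet)
    if dialect == "csv":
        payload = _payload_csv(packet)
        return f"{payload},{_bit_parity(payload.encode())}"
    if dialect == "jsonl":
        payload = _payload_jsonl(packet)
        obj = json.loads(payload)
        obj["parity"] = _bit_parity(payload.encode())
        return json.dumps(obj, sort_keys=True, separators=(",", ":"))
    raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def decode_packet(
    record: str, dialect: str = "csv", line_number: int | None = None
) -> DataPacket:
    """Parse one record back into a packet.

    A record whose parity check fails is returned with ``parity_ok=False``
    — corrupted data is flagged, never silently dropped.  Only structurally
    unparseable records raise :class:`DecodeError`.
    """
    if dialect == "csv":
        return _decode_csv(record, line_number)
    if dialect == "jsonl":
        return _decode_jsonl(record, line_number)
    raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def _decode_csv(record: str, line_number: int | None) -> DataPacket:
    try:
        payload, parity_str = record.rstrip("\n").rsplit(",", 1)
        stored = int(parity_str)
        fields = payload.split(",")
        if len(fields) != len(CSV_COLUMNS) - 1:
            raise ValueError(
                f"expected {len(CSV_COLUMNS) - 1} payload fields, got {len(fields)}"
            )
        packet = DataPacket(
            node_id=int(fields[0]),
            date=dt.date.fromisoformat(fields[1]),
            timestamp=int(fields[2]),
            supply_voltage=float(fields[3]),
            status_word=int(fields[4]),
            values=tuple(float(f) for f in fields[5:10]),
            parity_ok=_bit_parity(payload.encode()) == stored,
        )
    except (ValueError, IndexError) as exc:
        raise DecodeError(f"unparseable csv record: {exc}", line_number) from exc
    if not packet.parity_ok:
        packet.raw = record.rstrip("\n")
    return packet


def _decode_jsonl(record: str, line_number: int | None) -> DataPacket:
    try:
        obj = json.loads(record)
        stored = int(obj.pop("parity"))
        payload = json.dumps(obj, sort_keys=True, separators=(",", ":"))
        packet = DataPacket(
            node_id=int(obj["node_id"]),
            date=dt.date.fromisoformat(obj["date"]),
            timestamp=int(obj["timestamp"]),
            supply_voltage=float(obj["supply_voltage"]),
            status_word=int(obj["status_word"]),
            values=tuple(float(v) for v in obj["values"]),
            parity_ok=_bit_parity(payload.encode()) == stored,
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise DecodeError(f"unparseable jsonl record: {exc}", line_number) from exc
    if not packet.parity_ok:
        packet.raw = record.rstrip("\n")
    return packet


def write_packets(packets: Iterable[DataPacket], path, dialect: str = "csv") -> int:
    """Write a ``*.packets.csv`` / ``*.packets.jsonl`` file; returns the
    number of records written."""
    n = 0
    with open(path, "w") as fh:
        if dialect == "csv":
            fh.write(CSV_HEADER + "\n")
        for p in packets:
            record = p.raw if p.raw is not None else encode_packet(p, dialect)
            fh.write(record + "\n")
            n += 1
    return n


def read_packets(path, dialect: str | None = None) -> list[DataPacket]:
    """Read a packet file; the dialect is inferred from the suffix when not
    given.  Parity failures are flagged on the returned packets."""
    path = str(path)
    if dialect is None:
        dialect = "jsonl" if path.endswith("jsonl") else "csv"
    packets: list[DataPacket] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if dialect == "csv" and i == 1 and line == CSV_HEADER:
                continue
            packets.append(decode_packet(line, dialect, line_number=i))
    return packets


def corrupt_record(record: str, rng, dialect: str = "csv") -> str:
    """Flip one low bit of a random digit character in the payload,
    emulating a single-bit transmission error that parity will catch.

    The flip maps digits onto digits (``0<->1``, ``2<->3``, ...) and spares
    the calendar-date field, so the corrupted record stays structurally
    parseable and the corruption is caught by parity, not by the parser.
    """
    if dialect == "csv":
        payload, parity = record.rsplit(",", 1)
        fields = payload.split(",")
        eligible = [
            (fi, ci)
            for fi, f in enumerate(fields)
            if fi != 1  # skip the date field
            for ci, c in enumerate(f)
            if c.isdigit()
        ]
        fi, ci = eligible[int(rng.integers(len(eligible)))]
        chars = list(fields[fi])
        chars[ci] = chr(ord(chars[ci]) ^ 0x01)
        fields[fi] = "".join(chars)
        return ",".join(fields) + f",{parity}"
    import re

    date_span = re.search(r'"date":"[^"]*"', record)
    chars = list(record)
    digit_positions = [
        i
        for i, c in enumerate(chars)
        if c.isdigit()
        and not (date_span and date_span.start() <= i < date_span.end())
    ]
    pos = digit_positions[int(rng.integers(len(digit_positions)))]
    chars[pos] = chr(ord(chars[pos]) ^ 0x01)
    return "".join(chars)
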