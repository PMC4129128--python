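"""Candidate windows, ambient value matrices, and feature extraction.

The classifier does not see raw packets: for every candidate activity
window it sees an ambient value matrix — a (box, channel) × time slice of
the chronologically sorted streams of the boxes relevant to the window's
compartment — and a feature vector summarizing it.

Candidate windows are presence episodes derived from PIR motion.  Raw
episodes merge across quiet gaps up to a tolerance; on top of that a
single-occupant closure merges consecutive episodes in the same room when
no substantial episode exists anywhere else during the gap (a lone
resident who stops moving in the bedroom and triggers no other sensor has
not left the bedroom).  Without the closure, low-motion activities such
as sleeping would fragment below the rule engine's duration floors.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .domain import (
    AdlSenseError,
    CHANNELS,
    DataPacket,
    HomeLayout,
    Placement,
    SAMPLING_PERIOD_S,
    SECONDS_PER_DAY,
    SensorChannel,
    from_abs_seconds,
)

MOTION_COL = CHANNELS.index(SensorChannel.MOTION)
ACCEL_COL = CHANNELS.index(SensorChannel.ACCELERATION)
LUM_COL = CHANNELS.index(SensorChannel.LUMINANCE)
TEMP_COL = CHANNELS.index(SensorChannel.TEMPERATURE)
HUM_COL = CHANNELS.index(SensorChannel.HUMIDITY)


class EmptyMatrixError(AdlSenseError):
    """No samples are available inside the requested window."""


@dataclass
class SortedStreams:
    """Per-box time/value arrays rebuilt from chronologically sorted
    packets (or directly from simulator streams in tests)."""

    times: dict[int, np.ndarray]  # node_id -> int64 absolute seconds, ascending
    values: dict[int, np.ndarray]  # node_id -> (n, 5) float
    layout: HomeLayout

    @classmethod
    def from_sorted(
        cls, per_compartment: dict[str, list[DataPacket]], layout: HomeLayout
    ) -> "SortedStreams":
        times: dict[int, list[int]] = {b.node_id: [] for b in layout.boxes}
        values: dict[int, list[tuple]] = {b.node_id: [] for b in layout.boxes}
        for packets in per_compartment.values():
            for p in packets:
                times[p.node_id].append(p.abs_seconds)
                values[p.node_id].append(p.values)
        return cls(
            times={k: np.asarray(v, dtype=np.int64) for k, v in times.items()},
            values={
                k: (np.asarray(v, dtype=float) if v else np.empty((0, 5)))
                for k, v in values.items()
            },
            layout=layout,
        )

    @classmethod
    def from_streamset(cls, streams) -> "SortedStreams":
        t = streams.times_abs_s.astype(np.int64)
        return cls(
            times={k: t for k in streams.box_streams},
            values=dict(streams.box_streams),
            layout=streams.layout,
        )


@dataclass
class CandidateWindow:
    """A maximal presence episode in one compartment."""

    compartment: str
    start: dt.datetime
    end: dt.datetime
    features: "FeatureVector | None" = None

    @property
    def duration_s(self) -> float:
        return (self.end - self.start).total_seconds()


def _episodes_from_motion(
    t: np.ndarray, motion: np.ndarray, gap_s: float
) -> list[tuple[int, int]]:
    """Cluster motion-active sample times into (start, end) second spans."""
    active = t[motion > 0.5]
    if active.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(active) > gap_s)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [active.size - 1]))
    return [
        (int(active[i]), int(active[j]) + SAMPLING_PERIOD_S)
        for i, j in zip(starts, ends)
    ]


def segment_candidates(
    streams: SortedStreams,
    layout: HomeLayout,
    gap_tolerance_s: float = 120.0,
    min_duration_s: float = 60.0,
    single_occupant_closure: bool = True,
    closure_blocker_samples: int = 8,
) -> list[CandidateWindow]:
    """Derive candidate activity windows from wall-box PIR motion.

    Per compartment: motion episodes merged over gaps up to
    ``gap_tolerance_s``; optionally closed over longer quiet gaps when no
    other compartment shows presence evidence during the gap (at least
    ``closure_blocker_samples`` motion-active samples — one or two PIR
    false triggers elsewhere, hold dilation included, are not evidence
    that the resident left); episodes
    shorter than ``min_duration_s`` are dropped.  Windows never overlap
    within a compartment.
    """
    per_comp: dict[str, list[tuple[int, int]]] = {}
    active_times: dict[str, np.ndarray] = {}
    for comp in layout.compartments:
        spans: list[tuple[int, int]] = []
        actives: list[np.ndarray] = []
        for box in layout.wall_boxes(comp):
            t = streams.times.get(box.node_id)
            v = streams.values.get(box.node_id)
            if t is None or t.size == 0:
                continue
            spans.extend(_episodes_from_motion(t, v[:, MOTION_COL], gap_tolerance_s))
            actives.append(t[v[:, MOTION_COL] > 0.5])
        active_times[comp] = (
            np.unique(np.concatenate(actives)) if actives else np.empty(0, np.int64)
        )
        spans.sort()
        merged: list[tuple[int, int]] = []
        for s, e in spans:
            if merged and s - merged[-1][1] <= gap_tolerance_s:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        per_comp[comp] = merged

    if single_occupant_closure:

        def elsewhere(comp: str, lo: int, hi: int) -> bool:
            for other, times in active_times.items():
                if other == comp or times.size == 0:
                    continue
                count = np.searchsorted(times, hi) - np.searchsorted(times, lo)
                if count >= closure_blocker_samples:
                    return True
            return False

        for comp, spans in per_comp.items():
            closed: list[tuple[int, int]] = []
            for s, e in spans:
                if closed and not elsewhere(comp, closed[-1][1], s):
                    closed[-1] = (closed[-1][0], e)
                else:
                    closed.append((s, e))
            per_comp[comp] = closed

    windows = [
        CandidateWindow(comp, from_abs_seconds(s), from_abs_seconds(e))
        for comp, spans in per_comp.items()
        for s, e in spans
        if e - s >= min_duration_s
    ]
    windows.sort(key=lambda w: (w.start, w.compartment))
    return windows


@dataclass
class AmbientValueMatrix:
    """Channels × samples slice for one candidate window.

    Rows are (node_id, placement, channel) triples covering the
    compartment's wall box(es) plus its appliance boxes; columns are the
    5 s grid over the padded window.  Samples missing from the sorted
    streams (packet loss) are masked, never interpolated.
    """

    window: CandidateWindow
    times: np.ndarray  # absolute seconds, int64
    row_meta: list[tuple[int, Placement, SensorChannel]]
    data: np.ma.MaskedArray
    pad_s: float

    @property
    def core_columns(self) -> np.ndarray:
        lo = _abs_s(self.window.start)
        hi = _abs_s(self.window.end)
        return (self.times >= lo) & (self.times < hi)


def _abs_s(moment: dt.datetime) -> float:
    return (
        moment.date().toordinal() * SECONDS_PER_DAY
        + moment.hour * 3600
        + moment.minute * 60
        + moment.second
    )


def build_matrix(
    window: CandidateWindow,
    streams: SortedStreams,
    layout: HomeLayout,
    pad_s: float = 60.0,
) -> AmbientValueMatrix:
    """Assemble the ambient value matrix for one candidate window.

    The window is padded by ``pad_s`` on both sides so endpoint deltas see
    the pre/post-activity baseline (lamp off, humidity before the shower).
    Raises :class:`EmptyMatrixError` when no samples at all are available
    — e.g. a window falling entirely inside a packet-loss gap.
    """
    boxes = layout.wall_boxes(window.compartment) + layout.appliance_boxes(
        window.compartment
    )
    lo = int(_abs_s(window.start) - pad_s)
    hi = int(_abs_s(window.end) + pad_s)
    lo -= lo % SAMPLING_PERIOD_S
    grid = np.arange(lo, hi, SAMPLING_PERIOD_S, dtype=np.int64)
    n_cols = grid.size

    rows: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    meta: list[tuple[int, Placement, SensorChannel]] = []
    any_valid = False
    for box in boxes:
        t = streams.times.get(box.node_id, np.empty(0, dtype=np.int64))
        v = streams.values.get(box.node_id, np.empty((0, 5)))
        idx = np.searchsorted(t, grid)
        idx_clip = np.clip(idx, 0, max(t.size - 1, 0))
        present = (t.size > 0) & (idx < t.size)
        if t.size:
            present &= t[idx_clip] == grid
        if present.any():
            any_valid = True
        for ch_i, ch in enumerate(CHANNELS):
            row = np.zeros(n_cols)
            if t.size:
                row[present] = v[idx_clip[present], ch_i]
            rows.append(row)
            masks.append(~present if t.size else np.ones(n_cols, dtype=bool))
            meta.append((box.node_id, box.placement, ch))
    if not any_valid or n_cols == 0:
        raise EmptyMatrixError(
            f"no samples available for {window.compartment} window "
            f"{window.start} – {window.end}"
        )
    data = np.ma.MaskedArray(np.vstack(rows), mask=np.vstack(masks))
    return AmbientValueMatrix(
        window=window, times=grid, row_meta=meta, data=data, pad_s=pad_s
    )


@dataclass(frozen=True)
class FeatureConfig:
    """Numerical knobs of feature extraction."""

    endpoint_s: float = 30.0  # robust (median) endpoint width for deltas
    transient_threshold_ms2: float = 1.5  # above per-window baseline
    transient_separation_s: float = 10.0
    luminance_change_lx: float = 20.0
    tv_band_lx: tuple[float, float] = (25.0, 60.0)
    daytime: tuple[float, float] = (8 * 3600.0, 19 * 3600.0)


@dataclass
class FeatureVector:
    """Deterministic summary of one ambient value matrix, the only thing
    rules ever look at."""

    compartment: str
    duration_s: float
    start_time_of_day_s: float
    is_daytime: bool
    motion_density: float
    temperature_delta: float
    humidity_delta: float
    luminance_mean: float
    luminance_range: float
    luminance_change: bool
    tv_signature: bool
    flush_transients: int
    fridge_transients: int

    def as_dict(self) -> dict[str, float]:
        return {
            "duration": self.duration_s,
            "time_of_day": self.start_time_of_day_s,
            "is_daytime": float(self.is_daytime),
            "motion_density": self.motion_density,
            "temperature_delta": self.temperature_delta,
            "temperature_delta_abs": abs(self.temperature_delta),
            "humidity_delta": self.humidity_delta,
            "humidity_delta_abs": abs(self.humidity_delta),
            "luminance_mean": self.luminance_mean,
            "luminance_range": self.luminance_range,
            "luminance_change": float(self.luminance_change),
            "tv_signature": float(self.tv_signature),
            "flush_transients": float(self.flush_transients),
            "fridge_transients": float(self.fridge_transients),
        }


FEATURE_NAMES = frozenset(
    {
        "duration",
        "time_of_day",
        "is_daytime",
        "motion_density",
        "temperature_delta",
        "temperature_delta_abs",
        "humidity_delta",
        "humidity_delta_abs",
        "luminance_mean",
        "luminance_range",
        "luminance_change",
        "tv_signature",
        "flush_transients",
        "fridge_transients",
    }
)


def _median_endpoint(row: np.ma.MaskedArray, width: int, tail: bool) -> float:
    seg = row[-width:] if tail else row[:width]
    if seg.count() == 0:  # widen until something is unmasked
        seg = row[-4 * width :] if tail else row[: 4 * width]
    if seg.count() == 0:
        return float("nan")
    return float(np.ma.median(seg))


def count_transients(
    accel: np.ndarray,
    threshold: float,
    separation_s: float,
    sampling_s: float = SAMPLING_PERIOD_S,
) -> int:
    """Number of acceleration excursions above baseline + threshold,
    separated by at least ``separation_s``."""
    a = np.asarray(np.ma.filled(accel, np.nan), dtype=float)
    finite = np.isfinite(a)
    if not finite.any():
        return 0
    baseline = float(np.median(a[finite]))
    above = finite & (a - baseline > threshold)
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return 0
    min_gap = max(1, int(round(separation_s / sampling_s)))
    count, last = 1, idx[0]
    for i in idx[1:]:
        if i - last >= min_gap:
            count += 1
        last = i
    return count


def extract_features(
    matrix: AmbientValueMatrix, config: FeatureConfig | None = None
) -> FeatureVector:
    """Compute the feature vector for one matrix.

    Endpoint deltas use 30 s medians over the padded edges; motion density
    and mean luminance use the unpadded core; transient counts scan each
    appliance box's acceleration row.
    """
    cfg = config or FeatureConfig()
    core = matrix.core_columns
    width = max(1, int(round(cfg.endpoint_s / SAMPLING_PERIOD_S)))

    def rows_for(placement: Placement | None, channel: SensorChannel):
        return [
            i
            for i, (_, p, ch) in enumerate(matrix.row_meta)
            if ch is channel and (placement is None or p is placement)
        ]

    def wall_row(channel: SensorChannel) -> np.ma.MaskedArray:
        idx = rows_for(Placement.WALL, channel)
        if not idx:
            idx = rows_for(None, channel)
        return matrix.data[idx].mean(axis=0)

    temp = wall_row(SensorChannel.TEMPERATURE)
    hum = wall_row(SensorChannel.HUMIDITY)
    lum = wall_row(SensorChannel.LUMINANCE)
    motion_rows = rows_for(Placement.WALL, SensorChannel.MOTION)
    motion = matrix.data[motion_rows].max(axis=0)

    core_motion = motion[core]
    density = (
        float(core_motion.mean()) if core_motion.count() else 0.0
    )
    t_delta = _median_endpoint(temp, width, True) - _median_endpoint(temp, width, False)
    h_delta = _median_endpoint(hum, width, True) - _median_endpoint(hum, width, False)
    lum_core = lum[core]
    lum_mean = float(lum_core.mean()) if lum_core.count() else 0.0
    lum_range = (
        float(lum.max() - lum.min()) if lum.count() else 0.0
    )

    flush = fridge = 0
    for i, (_, placement, ch) in enumerate(matrix.row_meta):
        if ch is not SensorChannel.ACCELERATION:
            continue
        if placement is Placement.FLUSH_HANDLE:
            flush += count_transients(
                matrix.data[i], cfg.transient_threshold_ms2, cfg.transient_separation_s
            )
        elif placement is Placement.FRIDGE_DOOR:
            fridge += count_transients(
                matrix.data[i], cfg.transient_threshold_ms2, cfg.transient_separation_s
            )

    start_tod = float(_abs_s(matrix.window.start) % SECONDS_PER_DAY)
    return FeatureVector(
        compartment=matrix.window.compartment,
        duration_s=matrix.window.duration_s,
        start_time_of_day_s=start_tod,
        is_daytime=cfg.daytime[0] <= start_tod < cfg.daytime[1],
        motion_density=density,
        temperature_delta=float(t_delta),
        humidity_delta=float(h_delta),
        luminance_mean=lum_mean,
        luminance_range=lum_range,
        luminance_change=lum_range >= cfg.luminance_change_lx,
        tv_signature=cfg.tv_band_lx[0] <= lum_mean <= cfg.tv_band_lx[1],
        flush_transients=int(flush),
        fridge_transients=int(fridge),
    )
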