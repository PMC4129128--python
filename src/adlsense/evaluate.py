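"""Event-level evaluation of the classifier against the subject protocol.

Covers the whole evaluation chain: merging the switch-device log with
paper log-book corrections, correlating classifier output with ground
truth under a configurable matching mode, per-ADL sensitivity and
specificity with macro averages, and day × time-of-day activity maps
with a routine-regularity score.

Matching semantics (event_overlap mode, the default): greedy one-to-one
matching in time order — a truth event is a true positive for its label
when some unmatched same-label classified event overlaps it by at least
the threshold fraction of the shorter of the two; unmatched classified
events are false positives.  The negative universe for specificity is
one-vs-rest over ground-truth events: true negatives for a label are the
truth events of other labels not claimed by one of its false positives.
An epoch mode (fixed-length epochs, per-epoch label comparison) is
available as the alternative reading of specificity.
"""
from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .domain import (
    ADLEvent,
    ADLLabel,
    ADL_LABELS,
    AdlSenseError,
    GroundTruthLog,
    SECONDS_PER_DAY,
)


class MergeError(AdlSenseError):
    """A log-book correction references a non-existent event."""


class MetricError(AdlSenseError):
    """A metric is requested for an empty universe or with labels missing."""


# ---------------------------------------------------------------------------
# Log merging
# ---------------------------------------------------------------------------

CORRECTION_OPS = ("add", "delete", "relabel", "retime")


@dataclass(frozen=True)
class Correction:
    """One paper log-book correction, applied in file order.

    ``label``/``start`` identify the targeted device event (for delete,
    relabel, retime); ``add`` instead supplies a full new event.
    """

    operation: str
    label: ADLLabel
    start: dt.datetime
    end: dt.datetime | None = None
    compartment: str | None = None
    new_label: ADLLabel | None = None
    new_start: dt.datetime | None = None
    new_end: dt.datetime | None = None


def merge_logs(
    device_log: GroundTruthLog, corrections: Sequence[Correction]
) -> GroundTruthLog:
    """Superimpose paper log-book corrections on the switch-device log.

    Corrections apply in order; the merged log must satisfy the
    ground-truth invariants (no same-label overlap), otherwise a
    :class:`MergeError` reports the violations.
    """
    events = list(device_log.events)

    def find(label: ADLLabel, start: dt.datetime) -> int:
        for i, e in enumerate(events):
            if e.label is label and e.start == start:
                return i
        raise MergeError(
            f"correction references non-existent event {label.value} @ {start}"
        )

    for c in corrections:
        if c.operation == "add":
            if c.end is None or c.compartment is None:
                raise MergeError(f"add correction @ {c.start} missing end/compartment")
            events.append(
                ADLEvent(
                    c.label, c.start, c.end, c.compartment,
                    source="ground_truth", provenance="paper_logbook",
                )
            )
        elif c.operation == "delete":
            events.pop(find(c.label, c.start))
        elif c.operation == "relabel":
            if c.new_label is None:
                raise MergeError(f"relabel correction @ {c.start} missing new_label")
            i = find(c.label, c.start)
            e = events[i]
            events[i] = ADLEvent(
                c.new_label, e.start, e.end, e.compartment,
                source="ground_truth", provenance="paper_logbook",
            )
        elif c.operation == "retime":
            i = find(c.label, c.start)
            e = events[i]
            events[i] = ADLEvent(
                e.label,
                c.new_start or e.start,
                c.new_end or e.end,
                e.compartment,
                source="ground_truth",
                provenance="paper_logbook",
            )
        else:
            raise MergeError(
                f"unknown correction operation '{c.operation}' "
                f"(expected one of {CORRECTION_OPS})"
            )
    merged = GroundTruthLog(sorted(events, key=lambda e: e.start))
    violations = merged.validate()
    if violations:
        raise MergeError("merged log invalid: " + "; ".join(violations))
    return merged


# ---------------------------------------------------------------------------
# Event matching and confusion counts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MatchConfig:
    mode: str = "event_overlap"  # event_overlap | epoch
    overlap_threshold: float = 0.5  # fraction of the shorter event
    epoch_s: float = 60.0

    def __post_init__(self) -> None:
        if not 0.0 < self.overlap_threshold <= 1.0:
            raise AdlSenseError(
                f"overlap_threshold {self.overlap_threshold} outside (0, 1]"
            )
        if self.epoch_s % 5 != 0:
            raise AdlSenseError(f"epoch length {self.epoch_s} not a multiple of 5 s")
        if self.mode not in ("event_overlap", "epoch"):
            raise AdlSenseError(f"unknown matching mode '{self.mode}'")


@dataclass
class ConfusionCounts:
    """Per-label one-vs-rest event counts; N = TP + FN is the number of
    times the activity was performed."""

    tp: int = 0
    fn: int = 0
    fp: int = 0
    tn: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.fn


def _qualifies(truth: ADLEvent, classified: ADLEvent, threshold: float) -> bool:
    inter = truth.overlap_s(classified)
    shorter = min(truth.duration_s, classified.duration_s)
    return shorter > 0 and inter >= threshold * shorter


def match_events(
    classified: Sequence[ADLEvent],
    truth: Sequence[ADLEvent] | GroundTruthLog,
    config: MatchConfig | None = None,
) -> dict[ADLLabel, ConfusionCounts]:
    """Correlate classifier output with the ground-truth protocol."""
    cfg = config or MatchConfig()
    truth_events = truth.sorted() if isinstance(truth, GroundTruthLog) else sorted(
        truth, key=lambda e: e.start
    )
    classified = sorted(classified, key=lambda e: e.start)
    if cfg.mode == "epoch":
        return _match_epoch(classified, truth_events, cfg)

    counts = {label: ConfusionCounts() for label in ADL_LABELS}
    matched_classified: set[int] = set()
    # greedy one-to-one same-label matching in time order
    for t in truth_events:
        hit = None
        for j, c in enumerate(classified):
            if j in matched_classified or c.label is not t.label:
                continue
            if _qualifies(t, c, cfg.overlap_threshold):
                hit = j
                break
        if hit is None:
            counts[t.label].fn += 1
        else:
            matched_classified.add(hit)
            counts[t.label].tp += 1

    false_positives: dict[ADLLabel, list[ADLEvent]] = {l: [] for l in ADL_LABELS}
    for j, c in enumerate(classified):
        if j not in matched_classified:
            counts[c.label].fp += 1
            false_positives[c.label].append(c)

    # negatives, one-vs-rest: truth events of other labels; a false
    # positive "claims" (at most) one overlapping other-label truth event
    for label in ADL_LABELS:
        others = [t for t in truth_events if t.label is not label]
        claimed: set[int] = set()
        for c in false_positives[label]:
            for i, t in enumerate(others):
                if i in claimed:
                    continue
                if _qualifies(t, c, cfg.overlap_threshold):
                    claimed.add(i)
                    break
        counts[label].tn = len(others) - len(claimed)
    return counts


def _match_epoch(
    classified: Sequence[ADLEvent],
    truth_events: Sequence[ADLEvent],
    cfg: MatchConfig,
) -> dict[ADLLabel, ConfusionCounts]:
    events = list(classified) + list(truth_events)
    if not events:
        return {label: ConfusionCounts() for label in ADL_LABELS}
    lo = min(e.start for e in events)
    hi = max(e.end for e in events)
    n_epochs = int(math.ceil((hi - lo).total_seconds() / cfg.epoch_s))
    t_label = np.full(n_epochs, -1, dtype=np.int32)
    c_label = np.full(n_epochs, -1, dtype=np.int32)
    label_idx = {label: i for i, label in enumerate(ADL_LABELS)}

    def paint(arr: np.ndarray, evs: Sequence[ADLEvent]) -> None:
        for e in evs:
            i0 = int(((e.start - lo).total_seconds() + cfg.epoch_s / 2) // cfg.epoch_s)
            i1 = int(((e.end - lo).total_seconds() + cfg.epoch_s / 2) // cfg.epoch_s)
            arr[max(i0, 0) : min(i1, n_epochs)] = label_idx[e.label]

    paint(t_label, truth_events)
    paint(c_label, classified)
    counts = {}
    for label, i in label_idx.items():
        t_pos = t_label == i
        c_pos = c_label == i
        counts[label] = ConfusionCounts(
            tp=int((t_pos & c_pos).sum()),
            fn=int((t_pos & ~c_pos).sum()),
            fp=int((~t_pos & c_pos).sum()),
            tn=int((~t_pos & ~c_pos).sum()),
        )
    return counts


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def sensitivity(counts: ConfusionCounts) -> float | None:
    """100·TP/(TP+FN), 2 dp; None (undefined) when the activity was never
    performed — never silently zero."""
    if counts.n == 0:
        return None
    return round(100.0 * counts.tp / counts.n, 2)


def specificity(counts: ConfusionCounts) -> float | None:
    """100·TN/(TN+FP), 2 dp; None when the negative universe is empty."""
    denom = counts.tn + counts.fp
    if denom == 0:
        return None
    return round(100.0 * counts.tn / denom, 2)


def macro_average(values: Iterable[float | None]) -> float:
    """Unweighted mean over the eight per-ADL values, 2 dp.

    This is the arithmetic that turns the eight per-ADL percentages into
    the overall figures.  Missing (None) entries or a count other than
    eight raise :class:`MetricError` listing what is absent.
    """
    vals = list(values)
    missing = [i for i, v in enumerate(vals) if v is None]
    if len(vals) != len(ADL_LABELS) or missing:
        raise MetricError(
            f"macro average needs {len(ADL_LABELS)} defined per-ADL values; "
            f"got {len(vals)} with undefined indices {missing}"
        )
    return round(sum(vals) / len(vals), 2)


@dataclass
class MetricsTable:
    """Per-ADL confusion counts and metrics plus macro averages and grand
    totals, mirroring the classifier-performance table layout."""

    counts: dict[ADLLabel, ConfusionCounts]

    @property
    def per_label(self) -> dict[ADLLabel, dict]:
        out = {}
        for label in ADL_LABELS:
            c = self.counts[label]
            out[label] = {
                "n": c.n,
                "classified_correctly": c.tp,
                "missed": c.fn,
                "false_positives": c.fp,
                "sensitivity_pct": sensitivity(c),
                "specificity_pct": specificity(c),
            }
        return out

    @property
    def macro_sensitivity_pct(self) -> float:
        return macro_average(sensitivity(self.counts[l]) for l in ADL_LABELS)

    @property
    def macro_specificity_pct(self) -> float:
        return macro_average(specificity(self.counts[l]) for l in ADL_LABELS)

    @property
    def totals(self) -> dict:
        return {
            "n": sum(c.n for c in self.counts.values()),
            "classified_correctly": sum(c.tp for c in self.counts.values()),
            "missed": sum(c.fn for c in self.counts.values()),
            "false_positives": sum(c.fp for c in self.counts.values()),
        }

    def to_dict(self) -> dict:
        try:
            overall_sens = self.macro_sensitivity_pct
            overall_spec = self.macro_specificity_pct
        except MetricError:  # some activity never occurred: macro undefined
            overall_sens = overall_spec = None
        return {
            "per_adl": {l.value: row for l, row in self.per_label.items()},
            "totals": self.totals,
            "overall_sensitivity_pct": overall_sens,
            "overall_specificity_pct": overall_spec,
        }

    def __str__(self) -> str:
        lines = [
            f"{'ADL':<22}{'N':>6}{'TP':>6}{'FN':>6}{'FP':>6}"
            f"{'Sens %':>9}{'Spec %':>9}"
        ]
        for label, row in self.per_label.items():
            s = row["sensitivity_pct"]
            p = row["specificity_pct"]
            lines.append(
                f"{label.value:<22}{row['n']:>6}{row['classified_correctly']:>6}"
                f"{row['missed']:>6}{row['false_positives']:>6}"
                f"{s if s is not None else '--':>9}{p if p is not None else '--':>9}"
            )
        t = self.totals
        d = self.to_dict()
        ms = d["overall_sensitivity_pct"]
        mp = d["overall_specificity_pct"]
        lines.append(
            f"{'Total':<22}{t['n']:>6}{t['classified_correctly']:>6}"
            f"{t['missed']:>6}{t['false_positives']:>6}"
            f"{ms if ms is not None else '--':>9}{mp if mp is not None else '--':>9}"
        )
        return "\n".join(lines)


def metrics_table(
    classified: Sequence[ADLEvent],
    truth: Sequence[ADLEvent] | GroundTruthLog,
    config: MatchConfig | None = None,
) -> MetricsTable:
    return MetricsTable(match_events(classified, truth, config))


# ---------------------------------------------------------------------------
# Activity maps
# ---------------------------------------------------------------------------


@dataclass
class ActivityMap:
    """Day × time-of-day grid of ADL labels (-1 = no activity)."""

    start_date: dt.date
    n_days: int
    bin_s: float
    grid: np.ndarray  # (n_days, bins_per_day) int codes into ADL_LABELS

    @property
    def bins_per_day(self) -> int:
        return self.grid.shape[1]

    def regularity_score(self) -> float:
        """Mean day-to-day bin agreement (consecutive day pairs), in
        [0, 1]; 1 means a perfectly repeated schedule."""
        if self.n_days < 2:
            return 1.0
        agree = self.grid[:-1] == self.grid[1:]
        return float(agree.mean())


def build_activity_map(
    events: Sequence[ADLEvent],
    start_date: dt.date,
    n_days: int,
    bin_s: float = 300.0,
) -> ActivityMap:
    """Rasterize events onto a day × time-of-day grid.

    Each bin takes the label covering the majority of it; ties go to the
    earlier-starting event.  Bins partition the 24 h timeline exactly.
    """
    bins_per_day = int(SECONDS_PER_DAY // bin_s)
    coverage = np.zeros((n_days * bins_per_day, len(ADL_LABELS)))
    order = np.full((n_days * bins_per_day, len(ADL_LABELS)), np.inf)
    label_idx = {label: i for i, label in enumerate(ADL_LABELS)}
    for e in sorted(events, key=lambda ev: ev.start):
        li = label_idx[e.label]
        s = (e.start - dt.datetime.combine(start_date, dt.time())).total_seconds()
        t = (e.end - dt.datetime.combine(start_date, dt.time())).total_seconds()
        s, t = max(s, 0.0), min(t, n_days * SECONDS_PER_DAY)
        b0, b1 = int(s // bin_s), int(math.ceil(t / bin_s))
        for b in range(b0, min(b1, n_days * bins_per_day)):
            lo, hi = b * bin_s, (b + 1) * bin_s
            coverage[b, li] += max(0.0, min(t, hi) - max(s, lo))
            order[b, li] = min(order[b, li], s)
    best = coverage.max(axis=1)
    grid = np.full(n_days * bins_per_day, -1, dtype=np.int32)
    occupied = best > 0
    for b in np.flatnonzero(occupied):
        contenders = np.flatnonzero(coverage[b] == best[b])
        if contenders.size == 1:
            grid[b] = contenders[0]
        else:  # tie: earlier-starting event wins
            grid[b] = contenders[np.argmin(order[b, contenders])]
    return ActivityMap(
        start_date=start_date,
        n_days=n_days,
        bin_s=bin_s,
        grid=grid.reshape(n_days, bins_per_day),
    )


def plot_activity_map(activity_map: ActivityMap, path, title: str | None = None):
    """Render the activity map to an image file (one row per day)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm, ListedColormap
    from matplotlib.patches import Patch

    palette = [
        "#26316e", "#7dafff", "#2a9d8f", "#9b5de5",
        "#e76f51", "#f4a261", "#e9c46a", "#8ab17d",
    ]
    cmap = ListedColormap(["#f0f0f0"] + palette)
    norm = BoundaryNorm(np.arange(-1.5, len(ADL_LABELS) + 0.5), cmap.N)
    fig, ax = plt.subplots(figsize=(10, 0.5 + 0.35 * activity_map.n_days))
    ax.imshow(
        activity_map.grid,
        aspect="auto",
        interpolation="nearest",
        cmap=cmap,
        norm=norm,
        extent=(0, 24, activity_map.n_days, 0),
    )
    ax.set_xlabel("time of day [h]")
    ax.set_ylabel("day")
    ax.set_xticks(range(0, 25, 4))
    if title:
        ax.set_title(title)
    handles = [
        Patch(color=palette[i], label=label.value) for i, label in enumerate(ADL_LABELS)
    ]
    ax.legend(
        handles=handles, loc="upper left", bbox_to_anchor=(1.01, 1.0), fontsize=8
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
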