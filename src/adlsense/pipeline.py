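"""End-to-end orchestration: simulate -> sort -> classify -> evaluate.

`run_home` executes the full chain for one home in memory; `run_pipeline`
drives a configured multi-home run with artifacts and a manifest on disk;
`run_synthetic_benchmark` is the closed-loop benchmark used by the test
suite and the acceptance script (simulated residents scored against their
own ground truth).
"""
from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
import os
from dataclasses import dataclass, replace

import numpy as np

from . import codec
from .domain import (
    ADLEvent,
    AdlSenseError,
    GroundTruthLog,
    HomeLayout,
    default_layout,
    layout_from_dict,
    validate_layout,
    write_events_csv,
)
from .evaluate import (
    ActivityMap,
    MatchConfig,
    MetricsTable,
    build_activity_map,
    metrics_table,
    plot_activity_map,
)
from .features import (
    EmptyMatrixError,
    FeatureConfig,
    SortedStreams,
    build_matrix,
    extract_features,
    segment_candidates,
)
from .rules import FactDatabase, RuleRepository, default_rulebase, forward_chain, parse_rules
from .simulate import (
    ChannelReport,
    EmissionModel,
    ResidentProfile,
    SimConfig,
    alzheimer_profile,
    default_profile,
    derive_home_seeds,
    simulate_home,
)
from .sortpipe import IntegrityReport, integrity_report, sort_packets

logger = logging.getLogger(__name__)

PROFILES = {"default": default_profile, "alzheimer": alzheimer_profile}


def classify_streams(
    streams: SortedStreams,
    layout: HomeLayout,
    repo: RuleRepository | None = None,
    feature_config: FeatureConfig | None = None,
    prior_facts: list[ADLEvent] | None = None,
) -> list[ADLEvent]:
    """Segment, featurize, and forward-chain one home's sorted streams."""
    repo = repo or default_rulebase()
    candidates = segment_candidates(streams, layout)
    usable = []
    for cand in candidates:
        try:
            matrix = build_matrix(cand, streams, layout)
        except EmptyMatrixError:
            continue
        cand.features = extract_features(matrix, feature_config)
        usable.append(cand)
    db = FactDatabase(list(prior_facts or []))
    return forward_chain(db, usable, repo)


@dataclass
class HomeResult:
    home: int
    truth: GroundTruthLog
    classified: list[ADLEvent]
    report: ChannelReport


def run_home(
    layout: HomeLayout,
    profile: ResidentProfile,
    emission: EmissionModel,
    n_days: int,
    seed: int,
    packet_loss_rate: float = 0.0047,
    bit_corruption_rate: float = 0.0005,
    repo: RuleRepository | None = None,
    start_date: dt.date = dt.date(2023, 3, 6),
) -> HomeResult:
    """Full chain for a single home: behavior, ambient rendering, lossy
    packet link, integrity-filtered sorting, rule-based classification."""
    config = SimConfig(
        layout=layout,
        profile=profile,
        emission=emission,
        n_days=n_days,
        start_date=start_date,
        packet_loss_rate=packet_loss_rate,
        bit_corruption_rate=bit_corruption_rate,
        seed=seed,
    )
    truth, _streams, packets, report = simulate_home(config)
    sorted_streams, _integrity = sort_packets(packets, layout, expected=report.sent)
    streams = SortedStreams.from_sorted(sorted_streams, layout)
    classified = classify_streams(streams, layout, repo)
    return HomeResult(home=0, truth=truth, classified=classified, report=report)


def observable_events(
    events, range_end: dt.datetime, dropped_sleep_starts: list[dt.datetime] | None = None
):
    """Events fully observed within the rendered range.

    A final sleeping block running past the end of observation is
    excluded (its evidence is truncated by the recording boundary), and so
    is the getting-ready-for-bed interval attached to it, whose defining
    context (the following sleep) is unobservable.
    """
    from .domain import ADLLabel

    if dropped_sleep_starts is None:
        dropped_sleep_starts = [
            e.start
            for e in events
            if e.end > range_end and e.label is ADLLabel.SLEEPING
        ]
    out = []
    for e in events:
        if e.end > range_end:
            continue
        if e.label is ADLLabel.GETTING_READY_FOR_BED and any(
            abs((s - e.end).total_seconds()) < 2.0 for s in dropped_sleep_starts
        ):
            continue
        out.append(e)
    return out


@dataclass
class BenchmarkResult:
    metrics: MetricsTable
    integrity: IntegrityReport
    n_truth_events: int
    n_classified_events: int
    per_home: list[HomeResult]


def run_synthetic_benchmark(
    n_homes: int = 10,
    n_days: int = 5,
    seed: int = 42,
    packet_loss_rate: float = 0.0047,
    bit_corruption_rate: float = 0.0005,
    noise_free: bool = False,
    profile: ResidentProfile | None = None,
    match_config: MatchConfig | None = None,
    keep_homes: bool = False,
) -> BenchmarkResult:
    """Closed-loop benchmark: simulated residents classified with the
    default rulebase and scored against their own ground truth.

    Homes run sequentially with per-home seeds derived from the master
    seed; events are pooled before computing the metrics table.
    """
    layout = default_layout()
    prof = profile or default_profile()
    emission = EmissionModel.noise_free() if noise_free else EmissionModel()
    repo = default_rulebase()
    seeds = derive_home_seeds(seed, n_homes)
    truth_all: list[ADLEvent] = []
    classified_all: list[ADLEvent] = []
    sent = lost = corrupted = 0
    homes: list[HomeResult] = []
    for h in range(n_homes):
        result = run_home(
            layout,
            prof,
            emission,
            n_days,
            seeds[h],
            packet_loss_rate,
            bit_corruption_rate,
            repo,
        )
        result.home = h
        # score only fully observed events: the final night runs past the
        # end of the recording for both truth and classifier
        range_end = dt.datetime(2023, 3, 6) + dt.timedelta(days=n_days)
        truth_obs = observable_events(result.truth.events, range_end)
        dropped = [e for e in result.truth.events if e not in truth_obs]
        classified_obs = [
            c
            for c in result.classified
            if not any(c.overlap_s(d) > 0.5 * c.duration_s for d in dropped)
        ]
        # pooled scoring must not cross-match events of different homes:
        # homes share a calendar, so shift each home by a disjoint window
        offset = dt.timedelta(days=h * (n_days + 2))
        truth_all.extend(
            ADLEvent(e.label, e.start + offset, e.end + offset, e.compartment,
                     e.source, e.provenance)
            for e in truth_obs
        )
        classified_all.extend(
            ADLEvent(e.label, e.start + offset, e.end + offset, e.compartment,
                     e.source, e.provenance)
            for e in classified_obs
        )
        sent += result.report.sent
        lost += result.report.lost
        corrupted += result.report.corrupted
        if keep_homes:
            homes.append(result)
        logger.info("home %d: %d truth / %d classified events",
                    h, len(result.truth.events), len(result.classified))
    table = metrics_table(classified_all, GroundTruthLog(truth_all), match_config)
    integrity = IntegrityReport(captured=sent - lost, lost=lost, corrupted=corrupted)
    return BenchmarkResult(
        metrics=table,
        integrity=integrity,
        n_truth_events=len(truth_all),
        n_classified_events=len(classified_all),
        per_home=homes,
    )


# ---------------------------------------------------------------------------
# Configured runs
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """One reproducible end-to-end run.

    File-path fields are optional; when omitted the shipped defaults
    (five-room layout, regular resident, default rulebase) are used.
    Everything is validated before any stage executes.
    """

    out_dir: str
    n_homes: int = 1
    n_days: int = 3
    seed: int = 42
    packet_loss_rate: float = 0.0047
    bit_corruption_rate: float = 0.0005
    matching_mode: str = "event_overlap"
    profile: str = "default"
    layout_path: str | None = None
    rules_path: str | None = None
    noise_free: bool = False
    map_bin_s: float = 300.0

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            obj = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(obj) - known
        if unknown:
            raise AdlSenseError(f"unknown run-config fields: {sorted(unknown)}")
        return cls(**obj)

    def load(self) -> tuple[HomeLayout, ResidentProfile, RuleRepository, MatchConfig]:
        if self.layout_path:
            with open(self.layout_path) as fh:
                layout = layout_from_dict(json.load(fh))
        else:
            layout = default_layout()
        violations = validate_layout(layout)
        if violations:
            raise AdlSenseError("invalid layout: " + "; ".join(violations))
        if self.profile not in PROFILES:
            raise AdlSenseError(
                f"unknown profile '{self.profile}' (expected {sorted(PROFILES)})"
            )
        profile = PROFILES[self.profile]()
        repo = parse_rules(self.rules_path) if self.rules_path else default_rulebase()
        match = MatchConfig(mode=self.matching_mode)
        return layout, profile, repo, match


def run_pipeline(config: RunConfig) -> dict:
    """Execute the whole chain and write a run directory.

    Outputs: per-home truth and classified event CSVs, metrics JSON,
    integrity JSON, an activity map image, and a manifest sufficient to
    reproduce the run.  Any stage failure aborts with the stage name.
    """
    stage = "validate"
    try:
        layout, profile, repo, match = config.load()
        os.makedirs(config.out_dir, exist_ok=True)
        emission = EmissionModel.noise_free() if config.noise_free else EmissionModel()
        seeds = derive_home_seeds(config.seed, config.n_homes)
        truth_all: list[ADLEvent] = []
        classified_all: list[ADLEvent] = []
        sent = lost = corrupted = 0
        start_date = dt.date(2023, 3, 6)
        start_date_dt = dt.datetime(2023, 3, 6)
        for h in range(config.n_homes):
            stage = f"simulate+classify home {h}"
            result = run_home(
                layout,
                profile,
                emission,
                config.n_days,
                seeds[h],
                config.packet_loss_rate,
                config.bit_corruption_rate,
                repo,
                start_date=start_date,
            )
            write_events_csv(
                result.truth.sorted(),
                os.path.join(config.out_dir, f"home{h:02d}.truth.csv"),
            )
            write_events_csv(
                result.classified,
                os.path.join(config.out_dir, f"home{h:02d}.events.csv"),
            )
            range_end = start_date_dt + dt.timedelta(days=config.n_days)
            truth_obs = observable_events(result.truth.events, range_end)
            dropped = [e for e in result.truth.events if e not in truth_obs]
            classified_obs = [
                c
                for c in result.classified
                if not any(c.overlap_s(d) > 0.5 * c.duration_s for d in dropped)
            ]
            offset = dt.timedelta(days=h * (config.n_days + 2))
            truth_all.extend(
                ADLEvent(e.label, e.start + offset, e.end + offset, e.compartment,
                         e.source, e.provenance)
                for e in truth_obs
            )
            classified_all.extend(
                ADLEvent(e.label, e.start + offset, e.end + offset, e.compartment,
                         e.source, e.provenance)
                for e in classified_obs
            )
            sent += result.report.sent
            lost += result.report.lost
            corrupted += result.report.corrupted

        stage = "evaluate"
        table = metrics_table(classified_all, GroundTruthLog(truth_all), match)
        integrity = IntegrityReport(captured=sent - lost, lost=lost, corrupted=corrupted)
        with open(os.path.join(config.out_dir, "metrics.json"), "w") as fh:
            json.dump(table.to_dict(), fh, indent=2, sort_keys=True)
        with open(os.path.join(config.out_dir, "integrity.json"), "w") as fh:
            json.dump(integrity.to_dict(), fh, indent=2, sort_keys=True)

        stage = "report"
        amap = build_activity_map(
            [e for e in classified_all], start_date, config.n_homes * (config.n_days + 2),
            config.map_bin_s,
        )
        plot_activity_map(amap, os.path.join(config.out_dir, "activity_map.png"))

        table_dict = table.to_dict()
        manifest = {
            "config": dataclasses.asdict(config),
            "home_seeds": seeds,
            "start_date": start_date.isoformat(),
            "n_truth_events": len(truth_all),
            "n_classified_events": len(classified_all),
            "overall_sensitivity_pct": table_dict["overall_sensitivity_pct"],
            "overall_specificity_pct": table_dict["overall_specificity_pct"],
            "reliability_pct": integrity.reliability_pct,
        }
        with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest
    except AdlSenseError as exc:
        raise AdlSenseError(f"stage '{stage}' failed: {exc}") from exc
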