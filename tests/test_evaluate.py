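import datetime as dt

import numpy as np
import pytest

from adlsense.domain import ADLEvent, ADLLabel, ADL_LABELS, GroundTruthLog
from adlsense.evaluate import (
    ConfusionCounts,
    Correction,
    MatchConfig,
    MergeError,
    MetricError,
    build_activity_map,
    macro_average,
    match_events,
    merge_logs,
    metrics_table,
    sensitivity,
    specificity,
)

T0 = dt.datetime(2023, 3, 6, 8, 0)


def ev(label, hours_from_t0, duration_min, compartment="living_room", source="classified"):
    start = T0 + dt.timedelta(hours=hours_from_t0)
    return ADLEvent(
        ADLLabel(label), start, start + dt.timedelta(minutes=duration_min),
        compartment, source=source,
    )


# --- merge_logs -------------------------------------------------------------


def device_log():
    return GroundTruthLog(
        [
            ev("cooking", 3, 30, "kitchen", "ground_truth"),
            ev("eating", 4, 20, "dining_room", "ground_truth"),
            ev("watching_tv", 12, 60, "living_room", "ground_truth"),
        ]
    )


def test_empty_corrections_leave_device_log_unchanged():
    log = device_log()
    merged = merge_logs(log, [])
    assert merged.sorted() == log.sorted()


def test_delete_wrong_switch_and_add_forgotten_adl():
    """The paper-logbook workflow: remove a wrongly flicked switch and add
    the activity the subject forgot to record."""
    log = device_log()
    wrong = log.events[2]
    corrections = [
        Correction("delete", wrong.label, wrong.start),
        Correction(
            "add",
            ADLLabel.SEATED_ACTIVITY,
            wrong.start,
            end=wrong.end,
            compartment="living_room",
        ),
    ]
    merged = merge_logs(log, corrections)
    labels = [e.label for e in merged.sorted()]
    assert ADLLabel.WATCHING_TV not in labels
    added = [e for e in merged.events if e.label is ADLLabel.SEATED_ACTIVITY]
    assert len(added) == 1 and added[0].provenance == "paper_logbook"


def test_correction_referencing_missing_event_fails():
    with pytest.raises(MergeError, match="non-existent"):
        merge_logs(device_log(), [Correction("delete", ADLLabel.SLEEPING, T0)])


def test_relabel_creating_same_label_overlap_is_reported():
    log = GroundTruthLog(
        [
            ev("cooking", 3, 30, "kitchen", "ground_truth"),
            ev("eating", 3.25, 30, "dining_room", "ground_truth"),
        ]
    )
    with pytest.raises(MergeError, match="overlap"):
        merge_logs(
            log,
            [Correction("relabel", ADLLabel.EATING, log.events[1].start,
                        new_label=ADLLabel.COOKING)],
        )


def test_retime_moves_event():
    log = device_log()
    target = log.events[0]
    new_start = target.start + dt.timedelta(minutes=5)
    merged = merge_logs(
        log, [Correction("retime", target.label, target.start, new_start=new_start)]
    )
    cooking = [e for e in merged.events if e.label is ADLLabel.COOKING]
    assert cooking[0].start == new_start


# --- match_events -----------------------------------------------------------


def test_perfect_classifier_scores_all_true_positives():
    truth = [ev("toileting", k, 8, "bathroom", "ground_truth") for k in range(6)]
    classified = [ev("toileting", k, 8, "bathroom") for k in range(6)]
    counts = match_events(classified, truth)
    c = counts[ADLLabel.TOILETING]
    assert (c.tp, c.fn, c.fp) == (6, 0, 0)
    for label in ADL_LABELS:
        if label is not ADLLabel.TOILETING:
            assert counts[label].fp == counts[label].fn == 0


def test_study_scale_grooming_row_arithmetic():
    """135 performed, 127 found: TP=127, FN=8 — the per-activity
    bookkeeping of the results table."""
    truth = [ev("grooming", 5 * k, 25, "bathroom", "ground_truth") for k in range(135)]
    classified = [ev("grooming", 5 * k, 25, "bathroom") for k in range(127)]
    counts = match_events(classified, truth)
    c = counts[ADLLabel.GROOMING]
    assert (c.n, c.tp, c.fn) == (135, 127, 8)
    assert sensitivity(c) == 94.07


def test_one_classified_event_matches_at_most_one_truth_event():
    truth = [
        ev("eating", 0, 30, "dining_room", "ground_truth"),
        ev("eating", 0.5, 30, "dining_room", "ground_truth"),
    ]
    spanning = [ev("eating", 0, 60, "dining_room")]
    counts = match_events(spanning, truth)
    c = counts[ADLLabel.EATING]
    assert (c.tp, c.fn, c.fp) == (1, 1, 0)  # greedy: earlier truth wins


def test_overlap_below_threshold_does_not_match():
    truth = [ev("eating", 0, 30, "dining_room", "ground_truth")]
    classified = [ev("eating", 0.4, 30, "dining_room")]  # 6/30 overlap
    counts = match_events(classified, truth)
    c = counts[ADLLabel.EATING]
    assert (c.tp, c.fn, c.fp) == (0, 1, 1)


def test_false_positive_claims_other_label_negative():
    truth = [
        ev("seated_activity", 0, 40, "living_room", "ground_truth"),
        ev("cooking", 2, 30, "kitchen", "ground_truth"),
    ]
    classified = [ev("watching_tv", 0, 40, "living_room")]
    counts = match_events(classified, truth)
    tv = counts[ADLLabel.WATCHING_TV]
    assert tv.fp == 1
    assert tv.tn == 1  # the cooking event; the seated one was claimed
    assert specificity(tv) == 50.0


def test_epoch_mode_counts_epochs():
    truth = [ev("watching_tv", 0, 60, "living_room", "ground_truth")]
    classified = [ev("watching_tv", 0, 30, "living_room")]
    counts = match_events(classified, truth, MatchConfig(mode="epoch", epoch_s=60))
    c = counts[ADLLabel.WATCHING_TV]
    assert c.tp == 30 and c.fn == 30 and c.fp == 0


def test_metrics_invariant_under_global_time_shift():
    truth = [ev("cooking", 3, 30, "kitchen", "ground_truth"),
             ev("eating", 4, 20, "dining_room", "ground_truth")]
    classified = [ev("cooking", 3.05, 30, "kitchen"),
                  ev("eating", 4.02, 20, "dining_room")]
    shift = dt.timedelta(days=40)
    shifted_truth = [ADLEvent(e.label, e.start + shift, e.end + shift, e.compartment,
                              e.source) for e in truth]
    shifted_classified = [ADLEvent(e.label, e.start + shift, e.end + shift,
                                   e.compartment, e.source) for e in classified]
    a = metrics_table(classified, GroundTruthLog(truth))
    b = metrics_table(shifted_classified, GroundTruthLog(shifted_truth))
    assert a.to_dict() == b.to_dict()


def test_tp_plus_fn_equals_truth_count_conservation(rng):
    labels = [l.value for l in ADL_LABELS]
    truth, classified = [], []
    for k in range(120):
        label = labels[int(rng.integers(len(labels)))]
        truth.append(ev(label, 3 * k, 20, "living_room", "ground_truth"))
        if rng.random() < 0.7:  # noisy classifier
            classified.append(ev(label, 3 * k + rng.uniform(-0.1, 0.1), 20,
                                 "living_room"))
        if rng.random() < 0.1:
            classified.append(ev(labels[int(rng.integers(len(labels)))],
                                 3 * k + 1.5, 20, "living_room"))
    counts = match_events(classified, truth)
    for label in ADL_LABELS:
        n_truth = sum(e.label is label for e in truth)
        assert counts[label].tp + counts[label].fn == n_truth


# --- metrics ----------------------------------------------------------------


def test_sensitivity_values_follow_count_ratios():
    assert sensitivity(ConfusionCounts(tp=127, fn=8)) == 94.07
    assert sensitivity(ConfusionCounts(tp=59, fn=11)) == 84.29
    assert sensitivity(ConfusionCounts(tp=10, fn=0)) == 100.00
    assert sensitivity(ConfusionCounts(tp=0, fn=0)) is None  # undefined, not zero


def test_specificity_values_follow_count_ratios():
    assert specificity(ConfusionCounts(fp=0, tn=50)) == 100.00
    assert specificity(ConfusionCounts(fp=10, tn=90)) == 90.00
    assert specificity(ConfusionCounts(fp=5, tn=0)) == 0.00
    assert specificity(ConfusionCounts(fp=0, tn=0)) is None


def test_macro_average_reproduces_overall_rates():
    sens = [93.64, 94.07, 94.79, 92.38, 84.29, 87.78, 93.17, 90.06]
    spec = [85.77, 96.98, 91.54, 94.48, 90.92, 94.83, 90.63, 94.98]
    assert macro_average(sens) == 91.27
    assert macro_average(spec) == 92.52
    assert macro_average([88.0] * 8) == 88.0


def test_macro_average_rejects_missing_labels():
    with pytest.raises(MetricError):
        macro_average([90.0] * 7)
    with pytest.raises(MetricError):
        macro_average([90.0] * 7 + [None])


# --- activity maps ----------------------------------------------------------


def test_single_all_day_event_yields_uniform_map():
    start = dt.date(2023, 3, 6)
    events = [
        ADLEvent(
            ADLLabel.SEATED_ACTIVITY,
            dt.datetime(2023, 3, 6),
            dt.datetime(2023, 3, 7),
            "living_room",
        )
    ]
    amap = build_activity_map(events, start, 1)
    assert (amap.grid == list(ADL_LABELS).index(ADLLabel.SEATED_ACTIVITY)).all()


def test_repeated_schedule_has_perfect_regularity():
    start = dt.date(2023, 3, 6)
    events = []
    for d in range(4):
        base = dt.datetime(2023, 3, 6) + dt.timedelta(days=d)
        events.append(ADLEvent(ADLLabel.COOKING, base + dt.timedelta(hours=11, minutes=30),
                               base + dt.timedelta(hours=12), "kitchen"))
        events.append(ADLEvent(ADLLabel.WATCHING_TV, base + dt.timedelta(hours=20),
                               base + dt.timedelta(hours=22), "living_room"))
    amap = build_activity_map(events, start, 4)
    assert amap.regularity_score() == 1.0


def test_bin_majority_and_tie_break():
    start = dt.date(2023, 3, 6)
    # cooking covers 40% of the first bin, eating 60% -> eating wins
    events = [
        ADLEvent(ADLLabel.COOKING, dt.datetime(2023, 3, 6, 0, 0),
                 dt.datetime(2023, 3, 6, 0, 2), "kitchen"),
        ADLEvent(ADLLabel.EATING, dt.datetime(2023, 3, 6, 0, 2),
                 dt.datetime(2023, 3, 6, 0, 5), "dining_room"),
    ]
    amap = build_activity_map(events, start, 1)
    assert amap.grid[0, 0] == list(ADL_LABELS).index(ADLLabel.EATING)
    # exact tie: the earlier-starting event wins
    events = [
        ADLEvent(ADLLabel.COOKING, dt.datetime(2023, 3, 6, 0, 0),
                 dt.datetime(2023, 3, 6, 0, 2, 30), "kitchen"),
        ADLEvent(ADLLabel.EATING, dt.datetime(2023, 3, 6, 0, 2, 30),
                 dt.datetime(2023, 3, 6, 0, 5), "dining_room"),
    ]
    amap = build_activity_map(events, start, 1)
    assert amap.grid[0, 0] == list(ADL_LABELS).index(ADLLabel.COOKING)


def test_activity_map_plot_writes_image(tmp_path):
    events = [ev("watching_tv", 12, 90, "living_room")]
    amap = build_activity_map(events, T0.date(), 2)
    out = tmp_path / "map.png"
    from adlsense.evaluate import plot_activity_map

    plot_activity_map(amap, out)
    assert out.stat().st_size > 0
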