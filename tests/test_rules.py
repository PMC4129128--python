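import datetime as dt
import json

import pytest

from adlsense.domain import ADLEvent, ADLLabel
from adlsense.features import CandidateWindow, FeatureVector
from adlsense.rules import (
    FactDatabase,
    RuleSchemaError,
    default_rulebase,
    forward_chain,
    parse_rules,
    resolve_conflicts,
)


def fv(compartment, duration_s, start_hour=12.0, **overrides):
    """Hand-built feature vector with quiet-room defaults."""
    base = dict(
        compartment=compartment,
        duration_s=duration_s,
        start_time_of_day_s=start_hour * 3600.0,
        is_daytime=8.0 <= start_hour < 19.0,
        motion_density=0.8,
        temperature_delta=0.0,
        humidity_delta=0.0,
        luminance_mean=150.0,
        luminance_range=200.0,
        luminance_change=True,
        tv_signature=False,
        flush_transients=0,
        fridge_transients=0,
    )
    base.update(overrides)
    return FeatureVector(**base)


def window(compartment, start, duration_s, **feature_overrides):
    end = start + dt.timedelta(seconds=duration_s)
    w = CandidateWindow(compartment, start, end)
    hour = start.hour + start.minute / 60.0
    w.features = fv(compartment, duration_s, hour, **feature_overrides)
    return w


# --- repository -------------------------------------------------------------


def test_default_rulebase_validates_and_round_trips(tmp_path):
    repo = default_rulebase()
    assert len(repo) >= 8
    assert {r.target for r in repo} == set(ADLLabel)
    priorities = [r.priority for r in repo]
    assert len(set(priorities)) == len(priorities)
    path = tmp_path / "rules.json"
    repo.to_json(path)
    reparsed = parse_rules(path)
    assert [r.to_dict() for r in reparsed] == [r.to_dict() for r in repo]


def test_empty_rule_list_is_a_valid_repository():
    repo = parse_rules({"rules": []})
    assert len(repo) == 0
    out = forward_chain(
        FactDatabase(),
        [window("bathroom", dt.datetime(2023, 3, 6, 10), 360, flush_transients=1)],
        repo,
    )
    assert out == []


@pytest.mark.parametrize(
    "mutation,fragment",
    [
        (lambda r: r.update(duration_s=[900, 120]), "duration min"),
        (lambda r: r["predicates"].clear(), "empty predicate"),
        (lambda r: r["predicates"].append({"feature": "bogus", "op": "<", "value": 1}), "unknown feature"),
        (lambda r: r.update(priority=1), "duplicate priority"),
    ],
)
def test_schema_violations_rejected_with_rule_id(mutation, fragment):
    repo_dict = json.loads(default_rulebase().to_json())
    mutation(repo_dict["rules"][3])
    with pytest.raises(RuleSchemaError, match=fragment):
        parse_rules(repo_dict)


# --- conflict resolution ----------------------------------------------------


def test_conflict_resolution_prefers_smaller_priority():
    repo = {r.rule_id: r for r in default_rulebase()}
    toileting, grooming = repo["toileting"], repo["grooming_shower"]
    assert grooming.priority < toileting.priority
    assert resolve_conflicts([toileting, grooming]) is grooming
    assert resolve_conflicts([toileting]) is toileting


# --- forward chaining -------------------------------------------------------


def test_toileting_worked_example():
    """Bathroom visit, a few minutes, light switched, one flush, no
    humidity/temperature shift -> toileting."""
    w = window(
        "bathroom",
        dt.datetime(2023, 3, 6, 10, 0),
        360,
        flush_transients=1,
        humidity_delta=0.3,
        temperature_delta=0.1,
    )
    events = forward_chain(FactDatabase(), [w], default_rulebase())
    assert [e.label for e in events] == [ADLLabel.TOILETING]


def test_long_humid_bathroom_window_is_grooming_not_toileting():
    w = window(
        "bathroom",
        dt.datetime(2023, 3, 6, 7, 0),
        25 * 60,
        humidity_delta=6.0,
        flush_transients=1,
    )
    events = forward_chain(FactDatabase(), [w], default_rulebase())
    assert [e.label for e in events] == [ADLLabel.GROOMING]


def test_no_candidates_leaves_database_unchanged():
    db = FactDatabase()
    assert forward_chain(db, [], default_rulebase()) == []
    assert len(db) == 0


def test_getting_ready_needs_second_iteration_for_sleeping_fact():
    """The pre-bed bathroom window can only fire after the sleeping fact
    exists — the n-step iteration of the engine."""
    bath = window("bathroom", dt.datetime(2023, 3, 6, 22, 45), 600)
    bed = window(
        "bedroom",
        dt.datetime(2023, 3, 6, 22, 57),
        7 * 3600,
        luminance_mean=2.0,
        luminance_range=5.0,
        luminance_change=False,
        motion_density=0.03,
    )
    db = FactDatabase()
    events = forward_chain(db, [bath, bed], default_rulebase())
    by_label = {e.label: e for e in events}
    assert set(by_label) == {ADLLabel.SLEEPING, ADLLabel.GETTING_READY_FOR_BED}
    # with a single pass the prerequisite fact cannot exist yet
    single = forward_chain(FactDatabase(), [bath, bed], default_rulebase(), max_iterations=1)
    assert [e.label for e in single] == [ADLLabel.SLEEPING]


def test_eating_requires_recent_cooking_fact():
    kitchen = window(
        "kitchen",
        dt.datetime(2023, 3, 6, 11, 30),
        1500,
        fridge_transients=2,
        temperature_delta=1.8,
    )
    dining = window(
        "dining_room",
        dt.datetime(2023, 3, 6, 12, 5),
        1200,
        motion_density=0.4,
    )
    events = forward_chain(FactDatabase(), [kitchen, dining], default_rulebase())
    assert [e.label for e in events] == [ADLLabel.COOKING, ADLLabel.EATING]
    # the same dining window with no cooking beforehand stays unlabeled
    alone = forward_chain(FactDatabase(), [dining], default_rulebase())
    assert alone == []


def test_forward_chain_is_deterministic_and_monotone():
    wins = [
        window("kitchen", dt.datetime(2023, 3, 6, 11, 30), 1500,
               fridge_transients=1, temperature_delta=1.5),
        window("dining_room", dt.datetime(2023, 3, 6, 12, 5), 1200,
               motion_density=0.4),
        window("bathroom", dt.datetime(2023, 3, 6, 16, 40), 420,
               flush_transients=1),
    ]
    db1, db2 = FactDatabase(), FactDatabase()
    a = forward_chain(db1, wins, default_rulebase())
    b = forward_chain(db2, wins, default_rulebase())
    assert a == b
    assert len(db1) == len(a)  # every new event was appended, nothing lost


def test_forward_chain_terminates_within_iteration_cap():
    # 30 candidate windows, arbitrary mixture: must terminate and label
    # each window at most once
    wins = []
    for k in range(30):
        start = dt.datetime(2023, 3, 6, 8, 0) + dt.timedelta(minutes=20 * k)
        wins.append(window("bathroom", start, 360, flush_transients=1))
    events = forward_chain(FactDatabase(), wins, default_rulebase(), max_iterations=5)
    assert len(events) == 30
    assert len({(e.start, e.compartment) for e in events}) == 30


def test_classified_events_stay_inside_their_windows():
    wins = [
        window("bathroom", dt.datetime(2023, 3, 6, 10, 0), 360, flush_transients=1),
        window("kitchen", dt.datetime(2023, 3, 6, 11, 30), 1500,
               fridge_transients=1, humidity_delta=1.4),
    ]
    events = forward_chain(FactDatabase(), wins, default_rulebase())
    for e in events:
        w = next(w for w in wins if w.compartment == e.compartment)
        assert e.start == w.start and e.end == w.end
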