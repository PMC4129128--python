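"""Rule repository and forward-chaining inference engine.

A rule is parameterized behavioral knowledge: a target ADL, a compartment
scope, duration bounds, a conjunction of feature predicates (with any-of
groups for disjunctions), optional prior-fact requirements, and a unique
priority.  A parser turns a JSON rule file into an in-memory look-up
table; the engine repeatedly sweeps the unlabeled candidate windows,
labels each with the highest-priority fully satisfied rule, appends the
new event to the fact database, and iterates until a fixpoint or the
iteration cap.  Fact-dependent rules (getting ready for bed needs an
adjacent sleeping fact; eating needs a recent cooking fact) can only fire
once their prerequisites exist — this is what the n-step iteration is
for.

Conflict resolution follows the order in which the rules were authored:
the satisfied rule with the smallest priority number wins, so specific,
evidence-rich rules beat the catch-all seated-activity fallback.
"""
from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .domain import ADLEvent, ADLLabel, AdlSenseError, CLASSIFIED
from .features import FEATURE_NAMES, CandidateWindow, FeatureVector

logger = logging.getLogger(__name__)

_COMPARATORS = {
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    ">": lambda a, b: a > b,
    ">=": lambda a, b: a >= b,
    "==": lambda a, b: a == b,
    "!=": lambda a, b: a != b,
    "in_range": lambda a, b: b[0] <= a <= b[1],
}


class RuleSchemaError(AdlSenseError):
    """A rule file violates the published schema; the message carries the
    offending rule id."""


@dataclass(frozen=True)
class Clause:
    feature: str
    op: str
    value: float | tuple[float, float]

    def holds(self, features: dict[str, float]) -> bool:
        return _COMPARATORS[self.op](features[self.feature], self.value)

    def to_dict(self) -> dict:
        v = list(self.value) if isinstance(self.value, tuple) else self.value
        return {"feature": self.feature, "op": self.op, "value": v}


@dataclass(frozen=True)
class AnyOf:
    """Disjunctive predicate group: satisfied when any clause holds."""

    clauses: tuple[Clause, ...]

    def holds(self, features: dict[str, float]) -> bool:
        return any(c.holds(features) for c in self.clauses)

    def to_dict(self) -> dict:
        return {"any_of": [c.to_dict() for c in self.clauses]}


@dataclass(frozen=True)
class FactRequirement:
    """A prior classified fact the rule depends on.

    ``followed_by``: a ``label`` fact must start within ``window_s`` after
    the candidate ends.  ``preceded_by``: a ``label`` fact must end within
    ``window_s`` before the candidate starts.  A small slack absorbs
    segmentation edge effects.
    """

    label: ADLLabel
    relation: str  # followed_by | preceded_by
    window_s: float
    slack_s: float = 300.0

    def satisfied(self, window: CandidateWindow, facts: Sequence[ADLEvent]) -> bool:
        for f in facts:
            if f.label is not self.label:
                continue
            if self.relation == "followed_by":
                delta = (f.start - window.end).total_seconds()
                if -self.slack_s <= delta <= self.window_s:
                    return True
            else:
                delta = (window.start - f.end).total_seconds()
                if -self.slack_s <= delta <= self.window_s:
                    return True
        return False

    def to_dict(self) -> dict:
        return {
            "label": self.label.value,
            "relation": self.relation,
            "window_s": self.window_s,
            "slack_s": self.slack_s,
        }


@dataclass(frozen=True)
class Rule:
    rule_id: str
    target: ADLLabel
    scope: tuple[str, ...]  # compartments; empty tuple = any
    duration_s: tuple[float, float]
    predicates: tuple[Clause | AnyOf, ...]
    priority: int
    requires: tuple[FactRequirement, ...] = ()

    def in_scope(self, compartment: str) -> bool:
        return not self.scope or compartment in self.scope

    def satisfied(
        self,
        window: CandidateWindow,
        features: FeatureVector,
        facts: Sequence[ADLEvent],
    ) -> bool:
        if not self.in_scope(features.compartment):
            return False
        if not self.duration_s[0] <= features.duration_s <= self.duration_s[1]:
            return False
        fdict = features.as_dict()
        if not all(p.holds(fdict) for p in self.predicates):
            return False
        return all(r.satisfied(window, facts) for r in self.requires)

    def to_dict(self) -> dict:
        return {
            "id": self.rule_id,
            "target": self.target.value,
            "scope": list(self.scope),
            "duration_s": list(self.duration_s),
            "predicates": [p.to_dict() for p in self.predicates],
            "requires": [r.to_dict() for r in self.requires],
            "priority": self.priority,
        }


@dataclass
class RuleRepository:
    """Validated, uniquely prioritized rules plus their parsed look-up
    form (rules pre-sorted by priority, resident in memory)."""

    rules: list[Rule]

    def __post_init__(self) -> None:
        self._validate()
        self.lookup: list[Rule] = sorted(self.rules, key=lambda r: r.priority)

    def _validate(self) -> None:
        priorities: set[int] = set()
        ids: set[str] = set()
        for rule in self.rules:
            rid = rule.rule_id
            if rid in ids:
                raise RuleSchemaError(f"rule '{rid}': duplicate rule id")
            ids.add(rid)
            if rule.priority in priorities:
                raise RuleSchemaError(
                    f"rule '{rid}': duplicate priority {rule.priority}"
                )
            priorities.add(rule.priority)
            if rule.duration_s[0] > rule.duration_s[1]:
                raise RuleSchemaError(
                    f"rule '{rid}': duration min {rule.duration_s[0]} exceeds "
                    f"max {rule.duration_s[1]}"
                )
            if not rule.predicates:
                raise RuleSchemaError(f"rule '{rid}': empty predicate list")
            for pred in rule.predicates:
                clauses = pred.clauses if isinstance(pred, AnyOf) else (pred,)
                for c in clauses:
                    if c.feature not in FEATURE_NAMES:
                        raise RuleSchemaError(
                            f"rule '{rid}': unknown feature '{c.feature}'"
                        )
                    if c.op not in _COMPARATORS:
                        raise RuleSchemaError(
                            f"rule '{rid}': unknown comparator '{c.op}'"
                        )

    def __iter__(self):
        return iter(self.lookup)

    def __len__(self) -> int:
        return len(self.rules)

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps({"rules": [r.to_dict() for r in self.lookup]}, indent=indent)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _parse_clause(obj: dict, rid: str) -> Clause:
    try:
        value = obj["value"]
        if isinstance(value, list):
            value = tuple(float(v) for v in value)
        else:
            value = float(value)
        return Clause(feature=str(obj["feature"]), op=str(obj["op"]), value=value)
    except (KeyError, TypeError, ValueError) as exc:
        raise RuleSchemaError(f"rule '{rid}': malformed clause {obj!r}: {exc}") from exc


def parse_rules(source) -> RuleRepository:
    """Parse a rule file (path, JSON text, or dict) into a repository.

    Round-trips with :meth:`RuleRepository.to_json`.  Schema violations
    raise :class:`RuleSchemaError` carrying the rule id.
    """
    if isinstance(source, dict):
        obj = source
    else:
        text = None
        try:
            with open(source) as fh:
                text = fh.read()
        except (OSError, TypeError):
            text = source
        try:
            obj = json.loads(text)
        except (json.JSONDecodeError, TypeError) as exc:
            raise RuleSchemaError(f"rule file is not valid JSON: {exc}") from exc
    if not isinstance(obj, dict) or "rules" not in obj:
        raise RuleSchemaError("rule file must be an object with a 'rules' list")
    rules: list[Rule] = []
    for i, r in enumerate(obj["rules"]):
        rid = str(r.get("id", f"#{i}"))
        try:
            predicates: list[Clause | AnyOf] = []
            for p in r.get("predicates", []):
                if "any_of" in p:
                    predicates.append(
                        AnyOf(tuple(_parse_clause(c, rid) for c in p["any_of"]))
                    )
                else:
                    predicates.append(_parse_clause(p, rid))
            requires = tuple(
                FactRequirement(
                    label=ADLLabel(q["label"]),
                    relation=str(q["relation"]),
                    window_s=float(q["window_s"]),
                    slack_s=float(q.get("slack_s", 300.0)),
                )
                for q in r.get("requires", [])
            )
            for q in requires:
                if q.relation not in ("followed_by", "preceded_by"):
                    raise RuleSchemaError(
                        f"rule '{rid}': unknown fact relation '{q.relation}'"
                    )
            rules.append(
                Rule(
                    rule_id=rid,
                    target=ADLLabel(r["target"]),
                    scope=tuple(r.get("scope", [])),
                    duration_s=(
                        float(r["duration_s"][0]),
                        float(r["duration_s"][1]),
                    ),
                    predicates=tuple(predicates),
                    priority=int(r["priority"]),
                    requires=requires,
                )
            )
        except RuleSchemaError:
            raise
        except (KeyError, TypeError, ValueError) as exc:
            raise RuleSchemaError(f"rule '{rid}': {exc}") from exc
    return RuleRepository(rules)


def default_rulebase() -> RuleRepository:
    """The shipped 8-ADL rulebase.

    Thresholds are calibrated against the default emission model of the
    simulator (shower pulse +6 g/m³, cooking pulse +2 °C, lamp 200 lx, TV
    40 lx, flush/fridge transient 3 m/s²); they are configuration, not
    empirical claims.  Priority expresses authoring order for conflict
    resolution: specific, evidence-rich rules first, seated activity as
    the low-priority daytime fallback.
    """
    H = 3600.0
    rules = [
        Rule(
            "sleeping",
            ADLLabel.SLEEPING,
            scope=("bedroom",),
            duration_s=(1 * H, 14 * H),
            predicates=(
                Clause("luminance_mean", "<=", 20.0),
                Clause("motion_density", "<=", 0.05),
            ),
            priority=1,
        ),
        Rule(
            "grooming_shower",
            ADLLabel.GROOMING,
            scope=("bathroom",),
            duration_s=(600.0, 3600.0),
            predicates=(Clause("humidity_delta", ">=", 3.0),),
            priority=2,
        ),
        Rule(
            "grooming_long",
            ADLLabel.GROOMING,
            scope=("bathroom",),
            duration_s=(900.0, 3600.0),
            predicates=(Clause("luminance_change", "==", 1.0),),
            priority=3,
        ),
        Rule(
            "getting_ready_for_bed",
            ADLLabel.GETTING_READY_FOR_BED,
            scope=("bathroom",),
            duration_s=(120.0, 1200.0),
            predicates=(Clause("luminance_change", "==", 1.0),),
            requires=(
                FactRequirement(ADLLabel.SLEEPING, "followed_by", 1800.0),
            ),
            priority=4,
        ),
        Rule(
            "toileting",
            ADLLabel.TOILETING,
            scope=("bathroom",),
            duration_s=(120.0, 900.0),
            predicates=(
                Clause("luminance_change", "==", 1.0),
                Clause("flush_transients", ">=", 1.0),
                Clause("humidity_delta_abs", "<", 2.0),
                Clause("temperature_delta_abs", "<", 1.0),
            ),
            priority=5,
        ),
        Rule(
            "cooking",
            ADLLabel.COOKING,
            scope=("kitchen",),
            duration_s=(600.0, 5400.0),
            predicates=(
                Clause("fridge_transients", ">=", 1.0),
                AnyOf(
                    (
                        Clause("temperature_delta", ">=", 0.5),
                        Clause("humidity_delta", ">=", 1.0),
                    )
                ),
            ),
            priority=6,
        ),
        Rule(
            "eating",
            ADLLabel.EATING,
            scope=("dining_room", "kitchen"),
            duration_s=(600.0, 3600.0),
            predicates=(Clause("motion_density", "<=", 0.6),),
            requires=(
                FactRequirement(ADLLabel.COOKING, "preceded_by", 2700.0),
            ),
            priority=7,
        ),
        Rule(
            "watching_tv",
            ADLLabel.WATCHING_TV,
            scope=("living_room",),
            duration_s=(1200.0, 5 * H),
            predicates=(
                Clause("tv_signature", "==", 1.0),
                Clause("motion_density", "<=", 0.3),
            ),
            priority=8,
        ),
        Rule(
            "seated_activity",
            ADLLabel.SEATED_ACTIVITY,
            scope=("living_room",),
            duration_s=(1200.0, 5 * H),
            predicates=(
                Clause("is_daytime", "==", 1.0),
                Clause("tv_signature", "==", 0.0),
                Clause("motion_density", "<=", 0.5),
            ),
            priority=9,
        ),
    ]
    return RuleRepository(rules)


def resolve_conflicts(satisfied: Sequence[Rule]) -> Rule:
    """Among the satisfied rules for one candidate, the rule the experts
    authored first (smallest priority number) wins.  Deterministic."""
    if not satisfied:
        raise AdlSenseError("resolve_conflicts called with no satisfied rules")
    return min(satisfied, key=lambda r: r.priority)


@dataclass
class FactDatabase:
    """Sorted sensor data context plus every classified event so far
    (the engine's historical data).  Append-only during one run."""

    events: list[ADLEvent] = field(default_factory=list)

    def append(self, event: ADLEvent) -> None:
        self.events.append(event)

    def __len__(self) -> int:
        return len(self.events)


def forward_chain(
    db: FactDatabase,
    candidates: Sequence[CandidateWindow],
    repo: RuleRepository,
    max_iterations: int = 5,
) -> list[ADLEvent]:
    """Run the inference engine over feature-bearing candidate windows.

    Sweeps candidates in time order; each unlabeled candidate is labeled
    by its highest-priority satisfied rule and the event is appended to
    the fact database immediately, so later candidates in the same pass
    already see it.  Passes repeat until no new fact is added; hitting
    ``max_iterations`` with facts still being added logs a warning and
    returns the partial result.

    Every candidate must carry a precomputed ``features`` vector.
    """
    ordered = sorted(candidates, key=lambda w: (w.start, w.compartment))
    labeled: set[int] = set()
    new_events: list[ADLEvent] = []
    for iteration in range(max_iterations):
        added = 0
        for idx, cand in enumerate(ordered):
            if idx in labeled:
                continue
            if cand.features is None:
                raise AdlSenseError(
                    f"candidate {cand.compartment} @ {cand.start} has no features"
                )
            satisfied = [
                r for r in repo if r.satisfied(cand, cand.features, db.events)
            ]
            if not satisfied:
                continue
            winner = resolve_conflicts(satisfied)
            logger.debug(
                "iteration %d: %s window %s–%s -> %s (rule %s, %d satisfied)",
                iteration,
                cand.compartment,
                cand.start,
                cand.end,
                winner.target.value,
                winner.rule_id,
                len(satisfied),
            )
            event = ADLEvent(
                label=winner.target,
                start=cand.start,
                end=cand.end,
                compartment=cand.compartment,
                source=CLASSIFIED,
                provenance="classifier",
            )
            db.append(event)
            new_events.append(event)
            labeled.add(idx)
            added += 1
        if added == 0:
            break
    else:
        logger.warning(
            "forward chaining stopped at max_iterations=%d with facts still "
            "being added; returning partial result",
            max_iterations,
        )
    return sorted(new_events, key=lambda e: (e.start, e.compartment))
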