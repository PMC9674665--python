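"""Propositional recommendation rules, goal scoring and message generation.

The rule base holds five activity rules — one per daily activity level,
each of the shape ``(antecedent) IMPLIES (proposition variable) -> message``
— plus one satisfiability rule stating that exactly one "once a day"
proposition may fire per input. Rule evaluation follows a binary tree:
non-leaf nodes hold rules, edges hold the True/False decision, leaves hold
the recommendation messages, which makes every delivered message
explainable by its evaluation trace.

Weekly goal scoring sums the seven predicted daily scores, compares the
total against the preference-defined target (default 21, i.e. medium
active every day) and instantiates the formal/informal message templates;
the guideline constraints (weekly moderate-equivalent minutes > 150,
daily floor >= 21.45, daily score >= 3, weekly score >= 21) are reported
as booleans alongside.

Antecedent formulas use the operators NOT, AND, OR and IMPLIES (precedence
in that order, IMPLIES right-associative) over named variables; a small
recursive-descent parser evaluates them.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import re
from typing import Iterable, Mapping, Sequence

from .labeling import ActivityLevel, daily_score

__all__ = [
    "Preferences",
    "GoalConstraints",
    "Rule",
    "RuleBase",
    "WeeklyReport",
    "DailyEvaluation",
    "SatisfiabilityVerdict",
    "parse_formula",
    "default_rule_base",
    "evaluate_daily",
    "check_satisfiability",
    "weekly_evaluate",
    "render_notification",
]

MAX_SAT_VARIABLES = 20

DELIVERY_MODES = ("text", "audio", "graph")

#: Input variable set by the day's level, one-hot.
LEVEL_VARS = {
    ActivityLevel.SEDENTARY: "level_sedentary",
    ActivityLevel.LOW_ACTIVE: "level_low_active",
    ActivityLevel.ACTIVE: "level_active",
    ActivityLevel.MEDIUM_ACTIVE: "level_medium_active",
    ActivityLevel.HIGHLY_ACTIVE: "level_highly_active",
}

#: Proposition codes for the daily levels and weekly outcomes; remappable.
DAILY_PROPOSITIONS = {
    ActivityLevel.SEDENTARY: "A-1",
    ActivityLevel.LOW_ACTIVE: "A-2",
    ActivityLevel.ACTIVE: "A-3",
    ActivityLevel.MEDIUM_ACTIVE: "A-4",
    ActivityLevel.HIGHLY_ACTIVE: "A-5",
}
WEEKLY_PROPOSITIONS = {"well_done": "A-9", "satisfactory": "A-10", "improve": "A-11"}

FORMAL_BEHIND = ("You are {difference} points behind to reach your weekly goal. "
                 "Work hard on the following week.")
FORMAL_MET = "You have reached your weekly goal. Keep it up!"
FORMAL_AHEAD = "You are {ahead} points ahead of your weekly goal. Excellent work!"
INFORMAL = {
    "well_done": "Well done! Keep up the good work! \U0001f600",
    "satisfactory": "Satisfactory performance! Push a little more next week. \U0001f610",
    "improve": "Improve your performance to meet the goal! ☹",
}


# ---------------------------------------------------------------------------
# Propositional formulas
# ---------------------------------------------------------------------------

_TOKEN = re.compile(r"\s*(\(|\)|NOT|AND|OR|IMPLIES|[A-Za-z_][\w\-]*)")


class _Node:
    __slots__ = ("op", "args")

    def __init__(self, op: str, *args):
        self.op = op
        self.args = args

    def evaluate(self, env: Mapping[str, bool]) -> bool:
        if self.op == "var":
            name = self.args[0]
            if name not in env:
                raise KeyError(f"unknown proposition variable {name!r}")
            return bool(env[name])
        if self.op == "NOT":
            return not self.args[0].evaluate(env)
        if self.op == "AND":
            return self.args[0].evaluate(env) and self.args[1].evaluate(env)
        if self.op == "OR":
            return self.args[0].evaluate(env) or self.args[1].evaluate(env)
        # IMPLIES
        return (not self.args[0].evaluate(env)) or self.args[1].evaluate(env)

    def variables(self) -> set[str]:
        if self.op == "var":
            return {self.args[0]}
        return set().union(*(a.variables() for a in self.args))


def _tokenize(text: str) -> list[str]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m:
            if text[pos:].strip():
                raise ValueError(f"cannot tokenize formula near {text[pos:]!r}")
            break
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


def parse_formula(text: str) -> _Node:
    """Parse a propositional formula over NOT/AND/OR/IMPLIES.

    Precedence: NOT > AND > OR > IMPLIES; IMPLIES is right-associative;
    parentheses group as usual.
    """
    tokens = _tokenize(text)
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take(expected=None):
        nonlocal pos
        tok = peek()
        if tok is None or (expected and tok != expected):
            raise ValueError(f"malformed formula {text!r}: expected "
                             f"{expected or 'token'}, got {tok!r}")
        pos += 1
        return tok

    def atom():
        tok = peek()
        if tok == "(":
            take("(")
            node = implies()
            take(")")
            return node
        if tok == "NOT":
            take("NOT")
            return _Node("NOT", atom())
        if tok in (None, ")", "AND", "OR", "IMPLIES"):
            raise ValueError(f"malformed formula {text!r}: unexpected {tok!r}")
        return _Node("var", take())

    def conj():
        node = atom()
        while peek() == "AND":
            take("AND")
            node = _Node("AND", node, atom())
        return node

    def disj():
        node = conj()
        while peek() == "OR":
            take("OR")
            node = _Node("OR", node, conj())
        return node

    def implies():
        node = disj()
        if peek() == "IMPLIES":
            take("IMPLIES")
            return _Node("IMPLIES", node, implies())
        return node

    node = implies()
    if pos != len(tokens):
        raise ValueError(f"malformed formula {text!r}: trailing tokens")
    return node


# ---------------------------------------------------------------------------
# Rules and the rule base
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class Rule:
    """``(antecedent) IMPLIES (consequent proposition) -> bound message``."""

    id: str
    antecedent: str
    consequent: str
    category: str = "activity"  # or "satisfiability"

    def __post_init__(self) -> None:
        if self.category not in ("activity", "satisfiability"):
            raise ValueError(f"unknown rule category {self.category!r}")
        parse_formula(self.antecedent)  # well-formedness check


@dataclasses.dataclass(frozen=True)
class RuleBase:
    """Activity rules plus one exactly-one satisfiability rule and the
    proposition → message-template catalog."""

    rules: tuple[Rule, ...]
    catalog: Mapping[str, str]

    def __post_init__(self) -> None:
        sat = [r for r in self.rules if r.category == "satisfiability"]
        if len(sat) > 1:
            raise ValueError("rule base may contain at most one satisfiability rule")
        consequents = [r.consequent for r in self.activity_rules]
        if len(consequents) != len(set(consequents)):
            raise ValueError("activity-rule proposition variables must be unique")

    @property
    def activity_rules(self) -> tuple[Rule, ...]:
        return tuple(r for r in self.rules if r.category == "activity")

    def variables(self) -> set[str]:
        out: set[str] = set()
        for r in self.activity_rules:
            out |= parse_formula(r.antecedent).variables()
            out.add(r.consequent)
        return out


def default_rule_base() -> RuleBase:
    """Five daily activity rules (one per level) plus the exactly-one rule."""
    messages = {
        "A-1": ("You were sedentary today. Try a short walk tomorrow to get "
                "moving."),
        "A-2": ("You were low active today. Add some moderate activity "
                "tomorrow to raise your score."),
        "A-3": "You were active today. Keep building on this momentum.",
        "A-4": "You were medium active today. Great progress toward your goal.",
        "A-5": "You were highly active today. Excellent work!",
    }
    rules = [
        Rule(f"Rule-{i + 1}", LEVEL_VARS[level], DAILY_PROPOSITIONS[level])
        for i, level in enumerate(ActivityLevel)
    ]
    rules.append(Rule("Rule-6", "exactly_one_daily_message",
                      "satisfiable", category="satisfiability"))
    return RuleBase(tuple(rules), messages)


@dataclasses.dataclass(frozen=True)
class DailyEvaluation:
    variable: str
    message: str
    #: binary-tree evaluation trace: (rule id, edge decision) pairs ending
    #: at the leaf that holds the returned message
    trace: tuple[tuple[str, bool], ...]


def _level_env(level: ActivityLevel) -> dict[str, bool]:
    return {var: lvl is level for lvl, var in LEVEL_VARS.items()}


def _fired(rulebase: RuleBase, env: Mapping[str, bool]) -> list[Rule]:
    return [r for r in rulebase.activity_rules
            if parse_formula(r.antecedent).evaluate(env)]


def evaluate_daily(level: ActivityLevel, rulebase: RuleBase | None = None
                   ) -> DailyEvaluation:
    """Fire the (single) daily rule matching the level and return its message.

    All activity rules are evaluated; zero or two-plus triggered
    propositions violate the exactly-one satisfiability contract and raise,
    naming the offending rules. The returned trace walks the binary rule
    tree: each non-leaf decision is (rule id, True/False) and the leaf is
    the message.
    """
    rulebase = rulebase or default_rule_base()
    env = _level_env(level)
    fired = _fired(rulebase, env)
    if len(fired) != 1:
        names = [r.id for r in fired] or ["<none>"]
        raise ValueError(
            f"satisfiability violation for level {level.name}: "
            f"{len(fired)} rules triggered ({', '.join(names)})"
        )
    trace = []
    for rule in rulebase.activity_rules:
        decision = parse_formula(rule.antecedent).evaluate(env)
        trace.append((rule.id, decision))
        if decision:
            break
    winner = fired[0]
    message = rulebase.catalog.get(winner.consequent,
                                   f"<no message bound to {winner.consequent}>")
    return DailyEvaluation(winner.consequent, message, tuple(trace))


@dataclasses.dataclass(frozen=True)
class SatisfiabilityVerdict:
    passed: bool
    counterexample: dict | None = None


def check_satisfiability(rulebase: RuleBase) -> SatisfiabilityVerdict:
    """Exhaustively verify the exactly-one-message contract.

    Enumerates every truth assignment reachable from the five-level input
    domain and checks that exactly one "once a day" proposition fires for
    each; on failure the verdict carries the offending assignment and the
    triggered rules as a counterexample.
    """
    if not rulebase.activity_rules:
        raise ValueError("rule base has no activity rules; nothing can trigger")
    n_vars = len(rulebase.variables())
    if n_vars > MAX_SAT_VARIABLES:
        raise ValueError(
            f"{n_vars} proposition variables exceed the exhaustive-search "
            f"bound of {MAX_SAT_VARIABLES}; decompose the rule base"
        )
    for level in ActivityLevel:
        env = _level_env(level)
        fired = _fired(rulebase, env)
        if len(fired) != 1:
            return SatisfiabilityVerdict(
                passed=False,
                counterexample={
                    "input_level": level.name,
                    "assignment": env,
                    "triggered": [r.id for r in fired],
                },
            )
    return SatisfiabilityVerdict(passed=True)


# ---------------------------------------------------------------------------
# Preferences and weekly goal evaluation
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class Preferences:
    """Personal goal and delivery settings.

    Defaults mirror the system-defined weekly preference profile: stay
    medium active all week (target score 21 = 7 days x score 3), text
    delivery at 08:00.
    """

    goal_setting: str = "weekly"
    nature_of_goal: str = "system_defined"
    frequency: str = "weekly"
    target_goal: str = "To stay medium active for the entire week"
    target_score: int = 21
    mode: str = "text"
    delivery_time: dt.time = dt.time(8, 0)

    def __post_init__(self) -> None:
        if self.goal_setting not in ("daily", "weekly", "monthly"):
            raise ValueError(f"unknown goal setting {self.goal_setting!r}")
        if self.target_score < 0:
            raise ValueError("target_score must be non-negative")
        if self.goal_setting == "weekly" and self.target_score > 28:
            raise ValueError("weekly target_score cannot exceed 28 (7 days x 4)")


@dataclasses.dataclass(frozen=True)
class GoalConstraints:
    """Guideline thresholds; defaults as used for the weekly goal check."""

    weekly_moderate_minutes: float = 150.0   # strict: sum > 150
    daily_moderate_floor: float = 21.45
    daily_score_floor: int = 3
    weekly_score_target: int = 21


#: Emoji banding relative to the target (configurable via these bounds):
#: well_done at >= 100% of target, satisfactory at >= this fraction.
SATISFACTORY_FRACTION = 0.8


@dataclasses.dataclass(frozen=True)
class WeeklyReport:
    participant_id: str
    daily_levels: tuple[ActivityLevel, ...]
    daily_scores: tuple[int, ...]
    achieved: int
    target: int
    difference: int
    formal_message: str
    informal_message: str
    emoji_category: str
    triggered_variables: tuple[str, ...]
    constraint_checks: Mapping[str, object]


def _emoji_category(achieved: int, target: int) -> str:
    if achieved >= target:
        return "well_done"
    if achieved >= SATISFACTORY_FRACTION * target:
        return "satisfactory"
    return "improve"


def weekly_evaluate(
    levels: Sequence[ActivityLevel],
    prefs: Preferences | None = None,
    constraints: GoalConstraints | None = None,
    participant_id: str = "P-1",
    moderate_minutes: Sequence[float] | None = None,
) -> WeeklyReport:
    """Score a seven-day window of predicted levels against the weekly goal.

    ``achieved`` is the sum of the daily scores; ``difference`` is
    target - achieved (negative when the goal is exceeded). The formal
    message states how far behind (or ahead) the participant is, the
    informal message carries the emoji category. ``moderate_minutes``
    (daily moderate-equivalent minutes, 2*VPA + MPA) enables the weekly
    guideline-minute checks; without it those checks are reported as None.
    """
    prefs = prefs or Preferences()
    constraints = constraints or GoalConstraints()
    if prefs.goal_setting != "weekly":
        raise ValueError("weekly_evaluate requires weekly goal_setting")
    levels = tuple(ActivityLevel(l) for l in levels)
    if len(levels) != 7:
        raise ValueError(f"expected exactly 7 daily levels, got {len(levels)}")
    scores = tuple(daily_score(l) for l in levels)
    achieved = sum(scores)
    difference = prefs.target_score - achieved
    category = _emoji_category(achieved, prefs.target_score)

    if difference > 0:
        formal = FORMAL_BEHIND.format(difference=difference)
    elif difference == 0:
        formal = FORMAL_MET
    else:
        formal = FORMAL_AHEAD.format(ahead=-difference)
    informal = INFORMAL[category]

    checks: dict[str, object] = {
        "weekly_score_met": achieved >= constraints.weekly_score_target,
        "daily_score_floor_met": tuple(s >= constraints.daily_score_floor
                                       for s in scores),
    }
    if moderate_minutes is not None:
        if len(moderate_minutes) != 7:
            raise ValueError("moderate_minutes must cover exactly 7 days")
        checks["weekly_moderate_met"] = (
            sum(moderate_minutes) > constraints.weekly_moderate_minutes)
        checks["daily_moderate_floor_met"] = tuple(
            m >= constraints.daily_moderate_floor for m in moderate_minutes)
    else:
        checks["weekly_moderate_met"] = None
        checks["daily_moderate_floor_met"] = None

    triggered = tuple(DAILY_PROPOSITIONS[l] for l in levels) + (
        WEEKLY_PROPOSITIONS[category],)
    return WeeklyReport(
        participant_id=participant_id,
        daily_levels=levels,
        daily_scores=scores,
        achieved=achieved,
        target=prefs.target_score,
        difference=difference,
        formal_message=formal,
        informal_message=informal,
        emoji_category=category,
        triggered_variables=triggered,
        constraint_checks=checks,
    )


def render_notification(report: WeeklyReport, prefs: Preferences | None = None
                        ) -> dict:
    """Shape a weekly report into a delivery payload for the preferred mode."""
    prefs = prefs or Preferences()
    if prefs.mode not in DELIVERY_MODES:
        raise ValueError(
            f"unsupported delivery mode {prefs.mode!r}; supported modes: "
            f"{', '.join(DELIVERY_MODES)}"
        )
    payload = {
        "participant_id": report.participant_id,
        "mode": prefs.mode,
        "scheduled_time": prefs.delivery_time.isoformat(timespec="minutes"),
        "formal_message": report.formal_message,
        "informal_message": report.informal_message,
        "emoji_category": report.emoji_category,
        "achieved": report.achieved,
        "target": report.target,
        "difference": report.difference,
    }
    if prefs.mode == "text":
        payload["notification"] = {
            "title": "Your weekly activity summary",
            "body": report.formal_message,
        }
    return payload
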