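"""Feature selection and the sequential rule-based EA1/EA2 classifier.

Feature selection keeps features that separate the groups significantly
(p < alpha, AUC confidence interval clear of 0.5) and then restricts to
high-specificity features (> 90% by default), dropping an expert-consensus
exclusion list of hard-to-curate symptoms. The classifier applies ordered
high-specificity rules sequentially: the first matching rule's vote is the
label, missing features are skipped, and a case no rule can decide stays
``indeterminate`` — a first-class outcome for decision support.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cohort import Cohort, CaseRecord
from .features import DurationCategory, case_features
from .stats import DiagnosticAccuracy

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionConfig",
    "Rule",
    "RuleSet",
    "ClassificationResult",
    "ClassifierEvaluation",
    "select_features",
    "default_ruleset",
    "classify_case",
    "evaluate_classifier",
    "RuleSetError",
]

INDETERMINATE = "indeterminate"


class RuleSetError(ValueError):
    """A rule set violated a structural invariant."""


@dataclass
class SelectionConfig:
    """Feature-selection thresholds.

    ``alpha`` — significance level for the association test;
    ``specificity_floor`` — features must exceed this specificity;
    ``exclusion_list`` — features removed by expert consensus regardless of
    performance (defaults: the fatigue trigger, too subjective; ictal
    gastrointestinal symptoms, too heterogeneous in reports).
    """

    alpha: float = 0.05
    specificity_floor: float = 0.90
    exclusion_list: tuple[str, ...] = ("fatigue", "ictal_gi_symptoms")

    def __post_init__(self) -> None:
        if not 0 < self.specificity_floor < 1:
            raise ValueError("specificity_floor must lie in (0, 1)")


def select_features(
    rows: list[DiagnosticAccuracy], config: SelectionConfig | None = None
) -> list[DiagnosticAccuracy]:
    """Filter and rank diagnostic-accuracy rows for algorithm construction.

    Keeps rows with p < alpha whose AUC CI lower bound exceeds 0.5, then
    those with specificity above the floor, minus the exclusion list;
    sorted by descending specificity, ties broken by descending sensitivity
    then feature name (so the output is permutation-invariant).
    """
    config = config or SelectionConfig()
    survivors = [
        r
        for r in rows
        if r.p_value < config.alpha
        and r.auc_ci[0] > 0.5
        and r.specificity > config.specificity_floor
        and r.feature not in config.exclusion_list
    ]
    if not survivors:
        logger.warning("feature selection produced an empty list")
    return sorted(survivors, key=lambda r: (-r.specificity, -r.sensitivity, r.feature))


@dataclass(frozen=True)
class Rule:
    """One diagnostic rule: feature state -> vote.

    ``feature`` may be a single matrix column or an any-of disjunction
    joined with ``|`` (e.g. ``kinesigenic|startle``). ``state`` is
    ``present``/``absent`` for binary features, or ``in:<level,...>`` for an
    ordinal predicate (e.g. ``in:prolonged,protracted`` on
    ``duration_category``). ``provenance`` records the specificity that
    justified inclusion.
    """

    rank: int
    feature: str
    state: str
    vote: str
    provenance: float | None = None

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise RuleSetError(f"rule rank must be positive, got {self.rank}")
        if self.vote not in ("EA1", "EA2"):
            raise RuleSetError(f"rule vote must be EA1 or EA2, got {self.vote!r}")
        if not (self.state in ("present", "absent") or self.state.startswith("in:")):
            raise RuleSetError(f"unrecognized rule state {self.state!r}")

    def evaluate(self, row: dict[str, float]) -> str:
        """'matched' | 'failed' | 'skipped-missing' against an engineered row."""
        if self.state.startswith("in:"):
            value = row.get(self.feature, np.nan)
            if np.isnan(value):
                return "skipped-missing"
            wanted = {DurationCategory[n.strip().upper()].value
                      for n in self.state[3:].split(",")}
            return "matched" if int(value) in wanted else "failed"
        parts = self.feature.split("|")
        values = [row.get(p, np.nan) for p in parts]
        target = 1.0 if self.state == "present" else 0.0
        if any(v == target for v in values):
            # any-of semantics for 'present'; for 'absent' all must be absent
            if self.state == "present" or all(v == 0.0 for v in values):
                return "matched"
        if all(np.isnan(v) for v in values):
            return "skipped-missing"
        return "failed"


@dataclass
class RuleSet:
    """Ordered diagnostic rules with a conflict policy.

    ``first_match`` labels with the first matching rule's vote;
    ``specificity_weighted_vote`` sums each vote's matched-rule provenance
    weights and labels with the heavier side (tie -> indeterminate).
    """

    rules: list[Rule] = field(default_factory=list)
    conflict_policy: str = "first_match"
    default_label: str = INDETERMINATE

    def __post_init__(self) -> None:
        ranks = [r.rank for r in self.rules]
        if len(set(ranks)) != len(ranks):
            raise RuleSetError("duplicate rule ranks")
        if self.conflict_policy not in ("first_match", "specificity_weighted_vote"):
            raise RuleSetError(f"unknown conflict policy {self.conflict_policy!r}")
        votes = {r.vote for r in self.rules}
        if self.rules and votes != {"EA1", "EA2"}:
            raise RuleSetError("rule set must contain at least one rule per diagnosis")
        self.rules = sorted(self.rules, key=lambda r: r.rank)

    @classmethod
    def from_file(cls, path: str | Path, conflict_policy: str = "first_match") -> "RuleSet":
        """Load rules from a YAML or JSON list of {rank, feature, state, vote}."""
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if isinstance(raw, dict):
            conflict_policy = raw.get("conflict_policy", conflict_policy)
            raw = raw["rules"]
        try:
            rules = [Rule(**{k: v for k, v in r.items()}) for r in raw]
        except TypeError as exc:
            raise RuleSetError(f"malformed rule entry in {path}: {exc}") from None
        return cls(rules=rules, conflict_policy=conflict_policy)

    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "conflict_policy": self.conflict_policy,
            "rules": [
                {"rank": r.rank, "feature": r.feature, "state": r.state,
                 "vote": r.vote, "provenance": r.provenance}
                for r in self.rules
            ],
        }
        if path.suffix == ".json":
            path.write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")
        else:
            path.write_text(yaml.safe_dump(payload, sort_keys=False), encoding="utf-8")
        return path


def default_ruleset() -> RuleSet:
    """The shipped sequential rule set, ordered by specificity evidence.

    High-specificity EA1 markers (brief attacks, interictal peripheral
    muscular signs, kinesigenic/startle triggers) interleave with EA2
    markers (interictal nystagmus, ictal headache, interictal ataxia,
    prolonged-or-protracted attacks). Provenance values are the core-cohort
    specificities of each feature. Fully overridable from a config file via
    :meth:`RuleSet.from_file`.
    """
    return RuleSet(
        rules=[
            Rule(1, "brief_attacks", "present", "EA1", provenance=0.940),
            Rule(2, "peripheral_muscular_interictal", "present", "EA1", provenance=0.992),
            Rule(3, "interictal_nystagmus", "present", "EA2", provenance=0.988),
            Rule(4, "ictal_headache", "present", "EA2", provenance=0.957),
            Rule(5, "kinesigenic|startle", "present", "EA1", provenance=0.947),
            Rule(6, "interictal_ataxia", "present", "EA2", provenance=0.912),
            Rule(7, "duration_category", "in:prolonged,protracted", "EA2", provenance=0.877),
        ],
        conflict_policy="first_match",
    )


@dataclass
class ClassificationResult:
    label: str  # "EA1" | "EA2" | "indeterminate"
    fired_rules: list[Rule] = field(default_factory=list)
    trace: list[tuple[int, str, str]] = field(default_factory=list)  # (rank, feature, status)


@dataclass
class ClassifierEvaluation:
    """Confusion counts (true label -> predicted label incl. indeterminate)."""

    confusion: dict[tuple[str, str], int] = field(default_factory=dict)
    sensitivity: dict[str, float] = field(default_factory=dict)
    specificity: dict[str, float] = field(default_factory=dict)
    n: int = 0

    @property
    def wrong_label_rate(self) -> float:
        """Wrong-label rate among decided (non-indeterminate) cases."""
        wrong = sum(
            c for (t, p), c in self.confusion.items() if p != INDETERMINATE and p != t
        )
        decided = sum(c for (_, p), c in self.confusion.items() if p != INDETERMINATE)
        return wrong / decided if decided else 0.0


def _classify_row(row: dict[str, float], rules: RuleSet) -> ClassificationResult:
    trace: list[tuple[int, str, str]] = []
    matched: list[Rule] = []
    for rule in rules.rules:
        status = rule.evaluate(row)
        trace.append((rule.rank, rule.feature, status))
        if status == "matched":
            matched.append(rule)
            if rules.conflict_policy == "first_match":
                return ClassificationResult(label=rule.vote, fired_rules=[rule], trace=trace)
    if not matched:
        return ClassificationResult(label=rules.default_label, trace=trace)
    # specificity_weighted_vote
    weights: dict[str, float] = {"EA1": 0.0, "EA2": 0.0}
    for r in matched:
        weights[r.vote] += r.provenance if r.provenance is not None else 1.0
    if weights["EA1"] == weights["EA2"]:
        return ClassificationResult(label=INDETERMINATE, fired_rules=matched, trace=trace)
    label = "EA1" if weights["EA1"] > weights["EA2"] else "EA2"
    return ClassificationResult(label=label, fired_rules=matched, trace=trace)


def classify_case(case: CaseRecord, rules: RuleSet | None = None) -> ClassificationResult:
    """Classify one case with the rule set (default: the shipped rules).

    Rules are evaluated in rank order; rules whose feature is unknown are
    skipped and recorded in the trace; a case no rule decides is
    indeterminate. Total: never raises on case content.
    """
    rules = rules or default_ruleset()
    return _classify_row(case_features(case), rules)


def classify_cohort(
    cohort: Cohort, rules: RuleSet | None = None
) -> list[ClassificationResult]:
    rules = rules or default_ruleset()
    return [_classify_row(case_features(c), rules) for c in cohort]


def evaluate_classifier(cohort: Cohort, rules: RuleSet | None = None) -> ClassifierEvaluation:
    """Confusion matrix and per-diagnosis sensitivity/specificity on a labeled cohort.

    Indeterminate predictions count as misses for sensitivity. Unlabeled
    cases are excluded with a warning.
    """
    rules = rules or default_ruleset()
    ev = ClassifierEvaluation()
    unlabeled = 0
    for case in cohort:
        if case.diagnosis is None:
            unlabeled += 1
            continue
        result = _classify_row(case_features(case), rules)
        key = (case.diagnosis.value, result.label)
        ev.confusion[key] = ev.confusion.get(key, 0) + 1
        ev.n += 1
    if unlabeled:
        logger.warning("evaluate_classifier: excluded %d unlabeled cases", unlabeled)
    for dx in ("EA1", "EA2"):
        with_dx = sum(c for (t, _), c in ev.confusion.items() if t == dx)
        correct = ev.confusion.get((dx, dx), 0)
        ev.sensitivity[dx] = correct / with_dx if with_dx else float("nan")
        others = sum(c for (t, _), c in ev.confusion.items() if t != dx)
        flagged = sum(c for (t, p), c in ev.confusion.items() if t != dx and p == dx)
        ev.specificity[dx] = (others - flagged) / others if others else float("nan")
    return ev
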