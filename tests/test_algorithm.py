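"""Feature selection and the sequential rule classifier."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from eadiff import (
    CaseRecord,
    Cohort,
    Diagnosis,
    Rule,
    RuleSet,
    SelectionConfig,
    TriState,
    classify_case,
    default_ruleset,
    evaluate_classifier,
    select_features,
)
from eadiff.algorithm import INDETERMINATE, RuleSetError
from eadiff.features import build_feature_matrix
from eadiff.report import TABLE2_FEATURES
from eadiff.stats import feature_accuracy


@pytest.fixture(scope="module")
def accuracy_rows(core_matrix):
    return [feature_accuracy(core_matrix, f, g) for f, g in TABLE2_FEATURES]


EXPECTED_SELECTED = {
    "kinesigenic",
    "startle",
    "anxiety",
    "brief_attacks",
    "ictal_rigidity",
    "ictal_myokymia",
    "ictal_headache",
    "interictal_ataxia",
    "interictal_nystagmus",
    "interictal_clinical_myokymia",
    "interictal_neuromyotonia",
    "interictal_emg_myokymia",
    "peripheral_muscular_interictal",
}

EXPECTED_DROPPED = {
    "non_kinesigenic",          # specificity 27.2
    "physiological_stress",     # 79.1
    "daily_attacks",            # 84.1
    "ictal_limb_ataxia",        # 88.7
    "ictal_axial_ataxia",       # 58.8
    "ictal_vertigo",            # 76.3
    "ictal_gi_symptoms",        # 91.5 but excluded by consensus
}


def test_select_features_survivors(accuracy_rows):
    """>90%-specificity significant features survive; GI symptoms are removed
    by the consensus exclusion; every low-specificity row is dropped."""
    kept = {r.feature for r in select_features(accuracy_rows)}
    assert kept == EXPECTED_SELECTED
    assert kept.isdisjoint(EXPECTED_DROPPED)


def test_select_features_sorted_by_specificity(accuracy_rows):
    rows = select_features(accuracy_rows)
    specs = [r.specificity for r in rows]
    assert specs == sorted(specs, reverse=True)


def test_select_features_permutation_invariant(accuracy_rows):
    rng = np.random.default_rng(3)
    base = select_features(accuracy_rows)
    for _ in range(5):
        shuffled = list(accuracy_rows)
        rng.shuffle(shuffled)
        assert [r.feature for r in select_features(shuffled)] == [
            r.feature for r in base
        ]


def test_ci_overlapping_half_is_dropped(accuracy_rows):
    row = next(r for r in accuracy_rows if r.feature == "kinesigenic")
    import copy

    weak = copy.copy(row)
    weak.auc_ci = (0.49, 0.70)
    assert weak.feature not in {r.feature for r in select_features([weak])}


def test_empty_input_gives_empty_output():
    assert select_features([]) == []


def test_selection_config_validates_floor():
    with pytest.raises(ValueError):
        SelectionConfig(specificity_floor=1.5)


# ---------------------------------------------------------------------------
# rule sets
# ---------------------------------------------------------------------------

def test_default_ruleset_structure():
    rs = default_ruleset()
    assert len(rs.rules) == 7
    assert {r.vote for r in rs.rules} == {"EA1", "EA2"}
    assert [r.rank for r in rs.rules] == sorted(r.rank for r in rs.rules)


def test_duplicate_ranks_rejected():
    with pytest.raises(RuleSetError, match="duplicate"):
        RuleSet(rules=[
            Rule(1, "brief_attacks", "present", "EA1"),
            Rule(1, "interictal_nystagmus", "present", "EA2"),
        ])


def test_ruleset_file_roundtrip(tmp_path):
    rs = default_ruleset()
    path = rs.to_file(tmp_path / "rules.yaml")
    back = RuleSet.from_file(path)
    assert [(r.rank, r.feature, r.state, r.vote) for r in back.rules] == [
        (r.rank, r.feature, r.state, r.vote) for r in rs.rules
    ]


def test_two_rule_override_file(tmp_path):
    path = tmp_path / "two.yaml"
    path.write_text(
        "rules:\n"
        "- {rank: 1, feature: brief_attacks, state: present, vote: EA1}\n"
        "- {rank: 2, feature: interictal_nystagmus, state: present, vote: EA2}\n"
    )
    rs = RuleSet.from_file(path)
    assert len(rs.rules) == 2


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _case(**kw):
    case = CaseRecord(subject_id="S", **kw)
    return case


def test_brief_attacks_win_at_rank_one():
    case = _case(attack_duration_minutes=5)
    case.interictal_signs["clinical_myokymia"] = TriState.PRESENT
    result = classify_case(case)
    assert result.label == "EA1"
    assert result.fired_rules[0].rank == 1
    assert result.trace[0] == (1, "brief_attacks", "matched")


def test_nystagmus_routes_to_ea2():
    case = _case(attack_duration_minutes=120)
    case.interictal_signs["nystagmus"] = TriState.PRESENT
    case.ictal_signs["headache"] = TriState.PRESENT
    result = classify_case(case)
    assert result.label == "EA2"
    assert result.fired_rules[0].rank == 3


def test_all_unknown_is_indeterminate():
    result = classify_case(_case())
    assert result.label == INDETERMINATE
    assert result.fired_rules == []
    assert all(status == "skipped-missing" for _, _, status in result.trace)


def test_missing_features_are_skipped_in_trace():
    case = _case()  # duration unknown
    case.interictal_signs["nystagmus"] = TriState.PRESENT
    result = classify_case(case)
    assert result.label == "EA2"
    statuses = {rank: status for rank, _, status in result.trace}
    assert statuses[1] == "skipped-missing"
    assert statuses[3] == "matched"


def test_any_of_disjunction_rule():
    case = _case(trigger_data_available=True)
    case.triggers["startle"] = TriState.PRESENT
    result = classify_case(case)
    assert result.label == "EA1"
    assert result.fired_rules[0].feature == "kinesigenic|startle"


def test_ordinal_predicate_rule():
    case = _case(attack_duration_minutes=3000)  # protracted
    assert classify_case(case).label == "EA2"


def test_prefix_stability():
    """Adding a lower-priority rule never changes a decision made earlier."""
    rs = default_ruleset()
    case = _case(attack_duration_minutes=5)
    before = classify_case(case, rs)
    extended = RuleSet(
        rules=rs.rules + [Rule(8, "ictal_vertigo", "present", "EA2")]
    )
    after = classify_case(case, extended)
    assert before.label == after.label == "EA1"
    assert before.fired_rules[0].rank == after.fired_rules[0].rank


def test_classification_deterministic_and_order_invariant(core_cohort):
    rs = default_ruleset()
    labels = [classify_case(c, rs).label for c in core_cohort]
    reversed_labels = [classify_case(c, rs).label for c in reversed(core_cohort.cases)]
    assert labels == list(reversed(reversed_labels))


def test_weighted_vote_policy():
    rules = RuleSet(
        rules=[
            Rule(1, "brief_attacks", "present", "EA1", provenance=0.9),
            Rule(2, "interictal_nystagmus", "present", "EA2", provenance=0.95),
        ],
        conflict_policy="specificity_weighted_vote",
    )
    case = _case(attack_duration_minutes=5)
    case.interictal_signs["nystagmus"] = TriState.PRESENT
    assert classify_case(case, rules).label == "EA2"  # heavier vote wins


def test_evaluate_perfect_cohort():
    """Deterministic feature patterns per label classify perfectly."""
    cases = []
    for i in range(10):
        ea1 = _case(attack_duration_minutes=5)
        ea1.subject_id = f"a{i}"
        ea1.diagnosis = Diagnosis.EA1
        ea2 = _case(attack_duration_minutes=300)
        ea2.subject_id = f"b{i}"
        ea2.diagnosis = Diagnosis.EA2
        ea2.interictal_signs["nystagmus"] = TriState.PRESENT
        cases += [ea1, ea2]
    ev = evaluate_classifier(Cohort(cases=cases))
    assert ev.sensitivity == {"EA1": 1.0, "EA2": 1.0}
    assert ev.wrong_label_rate == 0.0
    assert sum(ev.confusion.values()) == 20


def test_all_indeterminate_cohort():
    cases = [
        CaseRecord(subject_id=f"s{i}", diagnosis=Diagnosis.EA2) for i in range(4)
    ]
    ev = evaluate_classifier(Cohort(cases=cases))
    assert ev.sensitivity["EA2"] == 0.0
    assert ev.confusion == {("EA2", INDETERMINATE): 4}


def test_indeterminate_has_no_fired_rules_property(core_cohort):
    for case in core_cohort:
        result = classify_case(case)
        if result.label != INDETERMINATE:
            assert result.fired_rules
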