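"""Statistical engine: metrics, ROC/AUC, exact-test oracles.

The Fisher and Mann-Whitney oracles here are written from first principles
(hypergeometric probability mass enumeration; exhaustive label
permutations) and are independent of the scipy-backed implementation they
check.
"""

import itertools
import math
from math import comb

import numpy as np
import pytest
from hypothesis import given, strategies as st

from eadiff import (
    ContingencyTable2x2,
    accuracy_metrics,
    association_test,
    auc_confidence_interval,
    binary_auc,
    build_contingency,
    build_feature_matrix,
    compare_continuous,
    core_prevalence_fixture,
    ordinal_roc,
    response_rates,
)
from eadiff.stats import (
    DegenerateTableError,
    InsufficientDataError,
    UndefinedMetricError,
    mann_whitney_p,
    round_half_up,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def fisher_oracle(tp, fn, fp, tn):
    """Two-sided Fisher exact p by hypergeometric tail enumeration:
    sum of probabilities of all tables (fixed margins) no more probable
    than the observed one."""
    r1, r2 = tp + fn, fp + tn
    c1 = tp + fp
    n = r1 + r2

    def pmf(k):
        return comb(r1, k) * comb(r2, c1 - k) / comb(n, c1)

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = pmf(tp)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-12))


def mann_whitney_permutation_oracle(a, b):
    """Two-sided exact Mann-Whitney p over all C(n1+n2, n1) group relabelings."""
    pooled = list(a) + list(b)
    n1 = len(a)

    def u_stat(group_a, group_b):
        u = 0.0
        for x in group_a:
            for y in group_b:
                u += 1.0 if x > y else 0.5 if x == y else 0.0
        return u

    u_obs = u_stat(a, b)
    us = []
    idx = range(len(pooled))
    for combo in itertools.combinations(idx, n1):
        in_a = set(combo)
        ga = [pooled[i] for i in idx if i in in_a]
        gb = [pooled[i] for i in idx if i not in in_a]
        us.append(u_stat(ga, gb))
    us = np.array(us)
    p_le = np.mean(us <= u_obs + 1e-12)
    p_ge = np.mean(us >= u_obs - 1e-12)
    return min(1.0, 2 * min(p_le, p_ge))


# ---------------------------------------------------------------------------
# 2x2 metrics
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "table,sens,spec",
    [
        ((54, 25, 6, 108), 0.684, 0.947),   # kinesigenic triggers
        ((61, 20, 11, 172), 0.753, 0.940),  # brief attacks
        ((1, 0, 0, 1), 1.0, 1.0),
    ],
)
def test_accuracy_metrics(table, sens, spec):
    s, p, acc = accuracy_metrics(ContingencyTable2x2(*table))
    assert round_half_up(s, 3) == pytest.approx(sens, abs=5e-4)
    assert round_half_up(p, 3) == pytest.approx(spec, abs=5e-4)
    tp, fn, fp, tn = table
    assert acc == (tp + tn) / sum(table)


def test_zero_margin_is_an_error():
    with pytest.raises(UndefinedMetricError, match="sensitivity"):
        accuracy_metrics(ContingencyTable2x2(0, 0, 3, 4))


@pytest.mark.parametrize(
    "sens,spec,expected",
    [
        (0.634, 0.988, 0.811),      # interictal nystagmus
        (54 / 79, 108 / 114, 0.815),  # kinesigenic
        (0.0, 1.0, 0.5),
    ],
)
def test_binary_auc(sens, spec, expected):
    assert binary_auc(sens, spec) == pytest.approx(expected, abs=5e-4)


def test_binary_auc_equals_two_level_ordinal(core_matrix):
    """For every binary feature, the single-cut-point AUC equals the
    two-level ordinal ROC's trapezoidal area."""
    targets = {
        "kinesigenic": "KCNA1", "brief_attacks": "KCNA1",
        "interictal_nystagmus": "CACNA1A", "ictal_headache": "CACNA1A",
        "startle": "KCNA1", "daily_attacks": "KCNA1",
    }
    for feature, gene in targets.items():
        table = build_contingency(core_matrix, feature, gene)
        sens, spec, _ = accuracy_metrics(table)
        roc = ordinal_roc(core_matrix, feature, "higher_favors_target", gene)
        assert roc.auc == pytest.approx(binary_auc(sens, spec), abs=1e-12)


def test_auc_group_swap_symmetry(core_matrix):
    """1 - AUC symmetry: swapping the target group (same orientation) or
    reversing the orientation (same target) complements the AUC, and doing
    both leaves it invariant."""
    for feature in ("duration_category", "frequency_category"):
        a = ordinal_roc(core_matrix, feature, "lower_favors_target", "KCNA1").auc
        b = ordinal_roc(core_matrix, feature, "lower_favors_target", "CACNA1A").auc
        c = ordinal_roc(core_matrix, feature, "higher_favors_target", "KCNA1").auc
        d = ordinal_roc(core_matrix, feature, "higher_favors_target", "CACNA1A").auc
        assert a + b == pytest.approx(1.0, abs=1e-12)
        assert a + c == pytest.approx(1.0, abs=1e-12)
        assert a == pytest.approx(d, abs=1e-12)


def test_duration_ordinal_roc_points(core_matrix):
    """Duration ROC has one point per cumulative category threshold."""
    roc = ordinal_roc(core_matrix, "duration_category", "lower_favors_target", "KCNA1")
    assert roc.points[0] == (0.0, 0.0)
    assert roc.points[-1] == (1.0, 1.0)
    assert len(roc.points) == 5
    assert roc.points[1] == pytest.approx((11 / 183, 61 / 81))
    assert roc.auc == pytest.approx(0.8745, abs=5e-4)


def test_degenerate_single_level_roc(core_matrix):
    cohort = core_prevalence_fixture()
    matrix = build_feature_matrix(cohort)
    matrix.data["startle"] = matrix.data["startle"] * 0.0  # force one level
    with pytest.warns(UserWarning, match="single observed level"):
        roc = ordinal_roc(matrix, "startle", "higher_favors_target", "KCNA1")
    assert roc.auc == 0.5


# ---------------------------------------------------------------------------
# confidence interval
# ---------------------------------------------------------------------------

def test_auc_ci_contains_auc_and_is_deterministic():
    ci1 = auc_confidence_interval(0.846, 81, 183)
    ci2 = auc_confidence_interval(0.846, 81, 183)
    assert ci1 == ci2
    assert ci1[0] < 0.846 < ci1[1]
    assert 0.0 <= ci1[0] and ci1[1] <= 1.0
    # width comparable to the published 0.787-0.906 interval
    assert (ci1[1] - ci1[0]) == pytest.approx(0.906 - 0.787, abs=0.03)


def test_auc_ci_tightens_with_n():
    wide = auc_confidence_interval(0.5, 10, 10)
    tight = auc_confidence_interval(0.5, 10000, 10000)
    assert tight[1] - tight[0] < 0.02 < wide[1] - wide[0]


# ---------------------------------------------------------------------------
# association tests
# ---------------------------------------------------------------------------

def test_startle_uses_fisher_with_zero_cell():
    p, used = association_test(ContingencyTable2x2(38, 39, 0, 114))
    assert used == "fisher"
    assert p < 0.001


def test_sex_comparison_uses_chi_square():
    p, used = association_test(ContingencyTable2x2(58, 36, 111, 165))
    assert used == "chi_square"
    # Pearson chi-square without continuity correction on these counts
    assert p == pytest.approx(3.042e-4, rel=1e-3)


def test_degenerate_margin_gives_p_one():
    with pytest.warns(UserWarning, match="degenerate"):
        p, used = association_test(ContingencyTable2x2(0, 0, 5, 7))
    assert p == 1.0 and used == "degenerate"


@given(
    st.tuples(
        st.integers(1, 12), st.integers(1, 12), st.integers(1, 12), st.integers(1, 12)
    ).filter(lambda t: sum(t) <= 30)
)
def test_fisher_matches_hypergeometric_enumeration(cells):
    """Whenever Fisher is selected, its p equals the enumeration oracle."""
    table = ContingencyTable2x2(*cells)
    p, used = association_test(table)
    if used == "fisher":
        assert p == pytest.approx(fisher_oracle(*cells), rel=1e-9)


def test_fisher_small_table_examples():
    for cells in [(1, 8, 11, 3), (5, 0, 1, 4), (2, 2, 2, 2), (8, 1, 1, 8)]:
        table = ContingencyTable2x2(*cells)
        p, used = association_test(table)
        assert used == "fisher"
        assert p == pytest.approx(fisher_oracle(*cells), rel=1e-9)


def test_null_chi_square_p_roughly_uniform():
    """Under independence with large expected counts, p-values are ~U(0,1)."""
    rng = np.random.default_rng(7)
    ps = []
    for _ in range(400):
        a = rng.binomial(60, 0.5)
        b = rng.binomial(60, 0.5)
        t = ContingencyTable2x2(a, 60 - a, b, 60 - b)
        p, used = association_test(t)
        if used == "chi_square":
            ps.append(p)
    ps = np.array(ps)
    assert abs(np.mean(ps < 0.5) - 0.5) < 0.1
    assert np.mean(ps < 0.05) < 0.12


# ---------------------------------------------------------------------------
# continuous comparison
# ---------------------------------------------------------------------------

def test_identical_multisets_give_p_one():
    vals = [1, 2, 2, 3, 5]
    p, used = compare_continuous(vals, vals)
    assert p == 1.0


def test_separated_groups_match_permutation_enumeration():
    a = list(range(1, 9))
    b = list(range(101, 109))
    assert mann_whitney_p(a, b) == pytest.approx(
        mann_whitney_permutation_oracle(a, b), rel=1e-9
    )


@given(
    a=st.lists(st.integers(0, 40), min_size=3, max_size=7),
    b=st.lists(st.integers(0, 40), min_size=3, max_size=7),
)
def test_mann_whitney_matches_permutation_for_small_groups(a, b):
    """Exact MW p equals the exhaustive permutation p on tie-free samples."""
    if len(set(a) | set(b)) < len(a) + len(b):
        return  # exact method applies to tie-free data only
    assert mann_whitney_p(a, b) == pytest.approx(
        mann_whitney_permutation_oracle(a, b), rel=1e-9
    )


def test_skewed_groups_use_mann_whitney():
    rng = np.random.default_rng(0)
    a = np.exp(rng.normal(0, 1.5, 40))
    b = np.exp(rng.normal(0.5, 1.5, 40))
    _, used = compare_continuous(a, b)
    assert used == "mann_whitney"


def test_normal_groups_use_t_test():
    rng = np.random.default_rng(1)
    _, used = compare_continuous(rng.normal(0, 1, 50), rng.normal(1, 1, 50))
    assert used == "t_test"


def test_insufficient_data_raises():
    with pytest.raises(InsufficientDataError):
        compare_continuous([1.0], [2.0, 3.0])


# ---------------------------------------------------------------------------
# drug response
# ---------------------------------------------------------------------------

def test_acetazolamide_response_rates(core_cohort):
    rr = response_rates(core_cohort, "acetazolamide")
    assert rr.responders == {"KCNA1": 17, "CACNA1A": 139}
    assert rr.evaluable == {"KCNA1": 33, "CACNA1A": 162}
    assert rr.proportions["CACNA1A"] == pytest.approx(139 / 162)
    assert rr.proportions["KCNA1"] == pytest.approx(17 / 33)
    assert rr.p_value < 0.001


def test_single_group_drug_skips_test(core_cohort):
    rr = response_rates(core_cohort, "four_ap")
    assert rr.proportions["CACNA1A"] == 1.0
    assert math.isnan(rr.proportions["KCNA1"])
    assert rr.p_value is None


def test_all_unknown_feature_is_degenerate(core_matrix):
    with pytest.raises(DegenerateTableError):
        build_contingency(core_matrix, "interictal_tremor", "KCNA1")
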