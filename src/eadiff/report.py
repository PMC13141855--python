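"""Cohort summary and diagnostic-accuracy report tables.

``table_one`` summarizes demographics, attack duration and frequency per
diagnostic group with group-comparison p-values; ``table_two`` computes one
diagnostic-accuracy row per analysed feature (target gene, sensitivity %,
specificity %, AUC, 95% CI, p, N). Percentages print rounded half-up to one
decimal and AUCs to three decimals.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cohort import Cohort, Diagnosis, Sex
from .features import (
    DurationCategory,
    FrequencyCategory,
    build_feature_matrix,
)
from .stats import (
    ContingencyTable2x2,
    DegenerateTableError,
    UndefinedMetricError,
    association_test,
    compare_continuous,
    feature_accuracy,
    round_half_up,
)

logger = logging.getLogger(__name__)

__all__ = ["table_one", "table_two", "TABLE2_FEATURES"]

#: Analysed features and their target gene, in report order.
TABLE2_FEATURES: tuple[tuple[str, str], ...] = (
    ("kinesigenic", "KCNA1"),
    ("startle", "KCNA1"),
    ("non_kinesigenic", "KCNA1"),
    ("physiological_stress", "KCNA1"),
    ("anxiety", "KCNA1"),
    ("brief_attacks", "KCNA1"),
    ("daily_attacks", "KCNA1"),
    ("ictal_limb_ataxia", "KCNA1"),
    ("ictal_axial_ataxia", "KCNA1"),
    ("ictal_rigidity", "KCNA1"),
    ("ictal_myokymia", "KCNA1"),
    ("ictal_vertigo", "CACNA1A"),
    ("ictal_headache", "CACNA1A"),
    ("ictal_gi_symptoms", "CACNA1A"),
    ("interictal_ataxia", "CACNA1A"),
    ("interictal_nystagmus", "CACNA1A"),
    ("interictal_clinical_myokymia", "KCNA1"),
    ("interictal_neuromyotonia", "KCNA1"),
    ("interictal_emg_myokymia", "KCNA1"),
    ("peripheral_muscular_interictal", "KCNA1"),
)


def _group_category_counts(matrix, col: str, dx: str, levels) -> list[int]:
    sel = (matrix.diagnosis == dx) & matrix.data[col].notna()
    vals = matrix.data.loc[sel, col]
    return [int((vals == lv).sum()) for lv in levels]


def table_one(cohort: Cohort) -> pd.DataFrame:
    """Per-group demographic and attack-metric summary with p-values.

    Rows: group size, female sex, age of onset, one row per duration and
    frequency category, and missing-data counts. With a single labeled
    group the p column stays blank.
    """
    groups = [dx.value for dx in Diagnosis
              if any(c.diagnosis is dx for c in cohort)]
    if not groups:
        raise ValueError("table_one requires a labeled cohort")
    matrix = build_feature_matrix(cohort)
    two_groups = len(groups) == 2

    def pct(k: int, n: int) -> str:
        return f"{k} ({round_half_up(100 * k / n, 1)}%)" if n else "0"

    rows: list[dict] = []

    def add(label: str, values: dict[str, str], p=None):
        row = {"variable": label, **values}
        row["p"] = "" if p is None else f"{p:.3g}"
        rows.append(row)

    sizes = {
        dx: sum(c.diagnosis is not None and c.diagnosis.value == dx for c in cohort)
        for dx in groups
    }
    add("Subjects (N)", {dx: str(sizes[dx]) for dx in groups})

    females = {
        dx: sum(
            c.sex is Sex.FEMALE for c in cohort
            if c.diagnosis is not None and c.diagnosis.value == dx
        )
        for dx in groups
    }
    p_sex = None
    if two_groups:
        p_sex, _ = association_test(ContingencyTable2x2(
            tp=females[groups[0]], fn=sizes[groups[0]] - females[groups[0]],
            fp=females[groups[1]], tn=sizes[groups[1]] - females[groups[1]],
        ))
    add("Female sex", {dx: pct(females[dx], sizes[dx]) for dx in groups}, p_sex)

    ages = {
        dx: [c.age_onset for c in cohort
             if c.diagnosis is not None and c.diagnosis.value == dx
             and c.age_onset is not None]
        for dx in groups
    }
    p_age = None
    if two_groups and all(len(a) >= 2 for a in ages.values()):
        p_age, _ = compare_continuous(ages[groups[0]], ages[groups[1]])
    add(
        "Age of onset, y (median, IQR, [range])",
        {
            dx: (
                f"{np.median(a):.1f}, {np.percentile(a, 25):.0f}-"
                f"{np.percentile(a, 75):.0f} [{min(a):.2g}-{max(a):.2g}]"
                if a else "n/a"
            )
            for dx, a in ages.items()
        },
        p_age,
    )

    for col, levels, header in (
        ("duration_category", DurationCategory, "Attack duration"),
        ("frequency_category", FrequencyCategory, "Attack frequency"),
    ):
        counts = {dx: _group_category_counts(matrix, col, dx, levels) for dx in groups}
        evaluable = {dx: sum(counts[dx]) for dx in groups}
        order = list(levels) if col == "duration_category" else list(reversed(levels))
        for lv in order:
            k = {dx: counts[dx][list(levels).index(lv)] for dx in groups}
            p = None
            if two_groups and all(evaluable.values()):
                p, _ = association_test(ContingencyTable2x2(
                    tp=k[groups[0]], fn=evaluable[groups[0]] - k[groups[0]],
                    fp=k[groups[1]], tn=evaluable[groups[1]] - k[groups[1]],
                ))
            add(f"{header}: {lv.label}", {dx: pct(k[dx], evaluable[dx]) for dx in groups}, p)
        add(
            f"Missing {header.lower()} data",
            {dx: str(sizes[dx] - evaluable[dx]) for dx in groups},
        )
    return pd.DataFrame(rows)


def table_two(
    cohort: Cohort, features: tuple[tuple[str, str], ...] = TABLE2_FEATURES
) -> pd.DataFrame:
    """Diagnostic-accuracy table: one row per feature.

    Columns: feature, target gene, N, sensitivity %, specificity %, AUC,
    95% CI, p-value and test used. Features with no evaluable cases are
    omitted with a warning.
    """
    dx = {c.diagnosis for c in cohort if c.diagnosis is not None}
    if len(dx) < 2:
        raise ValueError("table_two requires both diagnostic groups")
    matrix = build_feature_matrix(cohort)
    rows = []
    for feature, gene in features:
        try:
            acc = feature_accuracy(matrix, feature, gene)
        except (DegenerateTableError, UndefinedMetricError) as exc:
            logger.warning("skipping feature %s: %s", feature, exc)
            continue
        rows.append(
            {
                "feature": feature,
                "gene": gene,
                "n": acc.n,
                "sensitivity_pct": round_half_up(100 * acc.sensitivity, 1),
                "specificity_pct": round_half_up(100 * acc.specificity, 1),
                "auc": round_half_up(acc.auc, 3),
                "ci_low": round_half_up(acc.auc_ci[0], 3),
                "ci_high": round_half_up(acc.auc_ci[1], 3),
                "p_value": acc.p_value,
                "test_used": acc.test_used,
            }
        )
    return pd.DataFrame(rows)
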