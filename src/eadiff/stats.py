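"""Diagnostic-accuracy statistics on 2x2 tables and ordinal ROC curves.

Every feature is evaluated against the molecular diagnosis on complete
cases only (subjects with unknown feature values leave the denominator).
For a binary feature the ROC has a single interior operating point, so
AUC = (sensitivity + specificity) / 2; ordinal features get one point per
cumulative threshold and a trapezoidal AUC. Confidence intervals use the
Hanley-McNeil standard error with a normal quantile. Group association uses
Pearson chi-square without continuity correction, switching to the
two-sided Fisher exact test when any expected cell count falls below 5.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import Cohort, Diagnosis, DrugResponse
from .features import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable2x2",
    "DiagnosticAccuracy",
    "RocCurve",
    "build_contingency",
    "accuracy_metrics",
    "binary_auc",
    "ordinal_roc",
    "auc_confidence_interval",
    "association_test",
    "compare_continuous",
    "mann_whitney_p",
    "response_rates",
    "feature_accuracy",
    "round_half_up",
    "DegenerateTableError",
    "UndefinedMetricError",
    "InsufficientDataError",
]


class DegenerateTableError(ValueError):
    """No informative 2x2 table could be formed (e.g., all values missing)."""


class UndefinedMetricError(ValueError):
    """A requested metric has a zero margin in its denominator."""


class InsufficientDataError(ValueError):
    """Too few observations for the requested comparison."""


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round half away from zero, as clinical tables conventionally print."""
    factor = 10.0 ** ndigits
    return math.floor(abs(value) * factor + 0.5) / factor * (1 if value >= 0 else -1)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts cross-classifying diagnosis by feature among complete cases.

    "Positive" means feature present; "case" means the feature's target-gene
    group, so tp = target-gene subjects with the feature.
    """

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def n_target(self) -> int:
        return self.tp + self.fn

    @property
    def n_other(self) -> int:
        return self.fp + self.tn

    def as_array(self) -> np.ndarray:
        return np.array([[self.tp, self.fn], [self.fp, self.tn]])


@dataclass
class DiagnosticAccuracy:
    """One feature's diagnostic performance against its target gene."""

    feature: str
    target_gene: str
    sensitivity: float
    specificity: float
    accuracy: float
    n: int
    auc: float = float("nan")
    auc_ci: tuple[float, float] = (float("nan"), float("nan"))
    p_value: float = float("nan")
    test_used: str = ""
    table: ContingencyTable2x2 | None = None


@dataclass
class RocCurve:
    """ROC points from (0,0) to (1,1) with trapezoidal AUC."""

    points: list[tuple[float, float]]
    auc: float

    def __post_init__(self) -> None:
        fpr = [p[0] for p in self.points]
        tpr = [p[1] for p in self.points]
        if fpr != sorted(fpr) or tpr != sorted(tpr):
            raise ValueError("ROC points must be monotone non-decreasing")


_GENE_TO_DX = {"KCNA1": "EA1", "CACNA1A": "EA2"}


def build_contingency(
    matrix: FeatureMatrix, feature: str, target_gene: str
) -> ContingencyTable2x2:
    """Cross-classify diagnosis by a binary feature on complete cases.

    Cases with unknown feature value or unknown diagnosis are excluded.
    """
    target_gene = target_gene.upper()
    if feature not in matrix.data.columns:
        raise KeyError(f"feature {feature!r} not in matrix")
    target_dx = _GENE_TO_DX[target_gene]
    values = matrix.data[feature]
    labeled = matrix.diagnosis.notna() & values.notna()
    if not labeled.any():
        raise DegenerateTableError(f"no labeled complete cases for {feature!r}")
    vals = values[labeled]
    is_target = (matrix.diagnosis[labeled] == target_dx).to_numpy()
    present = (vals == 1.0).to_numpy()
    return ContingencyTable2x2(
        tp=int((is_target & present).sum()),
        fn=int((is_target & ~present).sum()),
        fp=int((~is_target & present).sum()),
        tn=int((~is_target & ~present).sum()),
    )


def accuracy_metrics(table: ContingencyTable2x2) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) of a 2x2 table."""
    if table.n_target == 0:
        raise UndefinedMetricError("sensitivity undefined: no target-group cases")
    if table.n_other == 0:
        raise UndefinedMetricError("specificity undefined: no comparison-group cases")
    sens = table.tp / table.n_target
    spec = table.tn / table.n_other
    acc = (table.tp + table.tn) / table.n
    return sens, spec, acc


def binary_auc(sensitivity: float, specificity: float) -> float:
    """AUC of a single binary feature: the trapezoidal area of the three-point
    ROC {(0,0), (1-specificity, sensitivity), (1,1)} = (sens + spec) / 2."""
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    return (sensitivity + specificity) / 2.0


def ordinal_roc(
    matrix: FeatureMatrix,
    feature: str,
    direction: str,
    target_gene: str,
) -> RocCurve:
    """ROC over an ordinal feature, one point per cumulative threshold.

    ``direction`` is ``lower_favors_target`` or ``higher_favors_target``:
    the side of the ordering on which target-group cases concentrate.
    """
    if direction not in ("lower_favors_target", "higher_favors_target"):
        raise ValueError(f"unknown direction {direction!r}")
    target_dx = _GENE_TO_DX[target_gene.upper()]
    values = matrix.data[feature]
    mask = matrix.diagnosis.notna() & values.notna()
    if not mask.any():
        raise DegenerateTableError(f"no labeled complete cases for {feature!r}")
    vals = values[mask].to_numpy()
    is_target = (matrix.diagnosis[mask] == target_dx).to_numpy()
    levels = np.unique(vals)
    if direction == "higher_favors_target":
        levels = levels[::-1]
    if len(levels) < 2:
        warnings.warn(f"feature {feature!r} has a single observed level; AUC = 0.5")
        return RocCurve(points=[(0.0, 0.0), (1.0, 1.0)], auc=0.5)
    n_t = int(is_target.sum())
    n_o = int((~is_target).sum())
    points = [(0.0, 0.0)]
    cum_t = cum_o = 0
    for lv in levels:
        at = vals == lv
        cum_t += int((at & is_target).sum())
        cum_o += int((at & ~is_target).sum())
        points.append((cum_o / n_o, cum_t / n_t))
    xs, ys = zip(*points)
    auc = float(np.trapezoid(ys, xs))
    return RocCurve(points=points, auc=auc)


def auc_confidence_interval(
    auc: float, n_target: int, n_other: int, level: float = 0.95
) -> tuple[float, float]:
    """Hanley-McNeil normal-approximation CI for an AUC, clipped to [0, 1]."""
    if n_target < 1 or n_other < 1:
        raise ValueError("both group sizes must be at least 1")
    q1 = auc / (2 - auc)
    q2 = 2 * auc * auc / (1 + auc)
    var = (
        auc * (1 - auc)
        + (n_target - 1) * (q1 - auc * auc)
        + (n_other - 1) * (q2 - auc * auc)
    ) / (n_target * n_other)
    se = math.sqrt(max(var, 0.0))
    z = sps.norm.ppf(0.5 + level / 2)
    return (max(0.0, auc - z * se), min(1.0, auc + z * se))


def association_test(table: ContingencyTable2x2) -> tuple[float, str]:
    """Group-association p-value for a 2x2 table.

    Pearson chi-square without continuity correction unless any expected
    cell count is below 5 or any observed cell is zero (where the
    chi-square approximation degenerates), in which case the two-sided
    Fisher exact test is used. Degenerate margins give p = 1 with a warning.
    """
    arr = table.as_array()
    row = arr.sum(axis=1)
    col = arr.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        warnings.warn("degenerate 2x2 margins; association p-value set to 1")
        return 1.0, "degenerate"
    expected = np.outer(row, col) / table.n
    if (expected < 5).any() or (arr == 0).any():
        p = float(sps.fisher_exact(arr, alternative="two-sided")[1])
        return p, "fisher"
    chi2, p, _, _ = sps.chi2_contingency(arr, correction=False)
    return float(p), "chi_square"


def compare_continuous(values_a, values_b) -> tuple[float, str]:
    """Two-group comparison of a scale variable.

    Shapiro-Wilk normality at alpha = 0.05 in each group gates the choice:
    both normal -> Welch t-test; otherwise Mann-Whitney U (exact on small
    tie-free samples, normal approximation with tie correction otherwise).
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each group needs at least 2 observations")

    def normal(x: np.ndarray) -> bool:
        if len(x) < 3 or np.ptp(x) == 0:
            return False
        return sps.shapiro(x).pvalue > 0.05

    if normal(a) and normal(b):
        p = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
        return p, "t_test"
    return mann_whitney_p(a, b), "mann_whitney"


def mann_whitney_p(values_a, values_b) -> float:
    """Two-sided Mann-Whitney U p-value: exact on small tie-free samples,
    normal approximation with tie correction otherwise."""
    return float(
        sps.mannwhitneyu(values_a, values_b, alternative="two-sided", method="auto").pvalue
    )


@dataclass
class ResponseRates:
    """Per-gene drug response proportions (response = complete or partial)."""

    drug: str
    responders: dict[str, int] = field(default_factory=dict)
    evaluable: dict[str, int] = field(default_factory=dict)
    proportions: dict[str, float] = field(default_factory=dict)
    p_value: float | None = None
    test_used: str | None = None


def response_rates(cohort: Cohort, drug: str) -> ResponseRates:
    """Per-gene response proportions for a drug, plus the 2x2 association test.

    Unknown responses leave the denominator; the test is skipped (p None)
    when a group has no evaluable subjects.
    """
    out = ResponseRates(drug=drug)
    for dx in (Diagnosis.EA1, Diagnosis.EA2):
        resp = ev = 0
        for case in cohort:
            if case.diagnosis is not dx:
                continue
            r = case.drug_responses.get(drug, DrugResponse.UNKNOWN)
            if r is DrugResponse.UNKNOWN:
                continue
            ev += 1
            if r in (DrugResponse.COMPLETE, DrugResponse.PARTIAL):
                resp += 1
        gene = dx.gene
        out.responders[gene] = resp
        out.evaluable[gene] = ev
        out.proportions[gene] = resp / ev if ev else float("nan")
    if all(out.evaluable.values()):
        table = ContingencyTable2x2(
            tp=out.responders["KCNA1"],
            fn=out.evaluable["KCNA1"] - out.responders["KCNA1"],
            fp=out.responders["CACNA1A"],
            tn=out.evaluable["CACNA1A"] - out.responders["CACNA1A"],
        )
        out.p_value, out.test_used = association_test(table)
    elif not any(out.evaluable.values()):
        raise InsufficientDataError(f"no evaluable {drug} responses in either group")
    else:
        logger.info("%s: single-group data only; association test skipped", drug)
    return out


def feature_accuracy(
    matrix: FeatureMatrix, feature: str, target_gene: str, level: float = 0.95
) -> DiagnosticAccuracy:
    """Full diagnostic-accuracy row (metrics, AUC + CI, association test)."""
    table = build_contingency(matrix, feature, target_gene)
    sens, spec, acc = accuracy_metrics(table)
    auc = binary_auc(sens, spec)
    ci = auc_confidence_interval(auc, table.n_target, table.n_other, level=level)
    p, test = association_test(table)
    return DiagnosticAccuracy(
        feature=feature,
        target_gene=target_gene.upper(),
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        n=table.n,
        auc=auc,
        auc_ci=ci,
        p_value=p,
        test_used=test,
        table=table,
    )
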