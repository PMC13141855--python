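"""Synthetic labeled cohorts with the marginal structure of the curated data.

Each diagnostic group is described by a :class:`GroupSpec`: per-feature
Bernoulli prevalences (computed among subjects with non-missing data),
four-level ordinal category probabilities for attack duration and
frequency, a log-normal age of onset matched to the published median/IQR,
and per-feature missingness rates. Features are independent within a group
by default — the published marginals are the only stated structure — with an
optional pairwise Gaussian-copula ``correlation_plan`` for stress tests.

:func:`study_spec` returns the study conditions: EA1 n=94 vs EA2 n=276 at
the published prevalences and missingness rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cohort import (
    Cohort,
    CaseRecord,
    Diagnosis,
    DrugResponse,
    Sex,
    TRIGGERS,
    TriState,
)
from .features import (
    DurationCategory,
    FrequencyCategory,
    MINUTES_PER_DAY,
    DAYS_PER_MONTH,
    DAYS_PER_WEEK,
    build_feature_matrix,
)

__all__ = ["GroupSpec", "CohortSpec", "generate_cohort", "recover_parameters", "study_spec"]

#: Sampling intervals (min, max) for a raw duration in minutes per category;
#: protracted attacks are capped at 7 days.
_DURATION_INTERVALS = {
    DurationCategory.BRIEF: (1.0, 10.0),
    DurationCategory.INTERMEDIATE: (10.0 + 1e-9, 60.0),
    DurationCategory.PROLONGED: (60.0 + 1e-9, MINUTES_PER_DAY - 1e-9),
    DurationCategory.PROTRACTED: (MINUTES_PER_DAY, 7 * MINUTES_PER_DAY),
}

_WEEKLY_CUT = DAYS_PER_MONTH / DAYS_PER_WEEK  # 30/7 attacks per month

#: Sampling intervals for a raw frequency in attacks per month per category.
_FREQUENCY_INTERVALS = {
    FrequencyCategory.RARE_SPORADIC: (0.1, 1.0 - 1e-9),
    FrequencyCategory.MONTHLY: (1.0, _WEEKLY_CUT - 1e-9),
    FrequencyCategory.WEEKLY: (_WEEKLY_CUT, DAYS_PER_MONTH - 1e-9),
    FrequencyCategory.DAILY: (DAYS_PER_MONTH, 3 * DAYS_PER_MONTH),
}


@dataclass
class GroupSpec:
    """Generating distribution for one diagnostic group.

    ``feature_prevalence`` maps engineered feature names (trigger names,
    ``ictal_*``, ``interictal_*``, ``progressive_ataxia``,
    ``cerebellar_atrophy``) to Bernoulli probabilities conditional on the
    feature being observed. Category probability vectors are in ordinal
    order (brief..protracted; rare_sporadic..daily). ``missingness`` maps
    the same names — plus ``duration``, ``frequency``, ``trigger_block``
    and ``age_onset`` — to probabilities of unknown.
    """

    diagnosis: Diagnosis
    n: int
    feature_prevalence: dict[str, float] = field(default_factory=dict)
    duration_category_probs: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    frequency_category_probs: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    age_onset_median: float = 8.0
    age_onset_iqr: tuple[float, float] = (4.0, 14.0)
    female_prob: float = 0.5
    missingness: dict[str, float] = field(default_factory=dict)
    drug_response: dict[str, tuple[float, float]] = field(default_factory=dict)
    # drug -> (P(evaluable), P(responder | evaluable))

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError("group size must be non-negative")
        for name, p in {**self.feature_prevalence, **self.missingness,
                        "female_prob": self.female_prob}.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability for {name!r} outside [0, 1]: {p}")
        for vec in (self.duration_category_probs, self.frequency_category_probs):
            if len(vec) != 4 or abs(sum(vec) - 1.0) > 1e-9 or min(vec) < 0:
                raise ValueError(f"category probabilities must be a 4-vector summing to 1: {vec}")
        q1, q3 = self.age_onset_iqr
        if not 0 < q1 <= self.age_onset_median <= q3:
            raise ValueError("age IQR must bracket the median and be positive")


@dataclass
class CohortSpec:
    """A full simulation: one GroupSpec per diagnosis, a seed, optional correlations."""

    groups: list[GroupSpec]
    seed: int = 0
    label: str = "synthetic"
    correlation_plan: dict[tuple[str, str], float] = field(default_factory=dict)

    def validate(self) -> None:
        dx = [g.diagnosis for g in self.groups]
        if len(set(dx)) != len(dx):
            raise ValueError("group diagnoses must be distinct")
        for g in self.groups:
            g.validate()
        for (a, b), rho in self.correlation_plan.items():
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"correlation for ({a}, {b}) outside [-1, 1]")


def _set_feature(case: CaseRecord, name: str, state: TriState) -> None:
    if name in TRIGGERS:
        case.triggers[name] = state
    elif name.startswith("ictal_"):
        case.ictal_signs[name[len("ictal_"):]] = state
    elif name.startswith("interictal_"):
        case.interictal_signs[name[len("interictal_"):]] = state
    elif name in ("progressive_ataxia", "cerebellar_atrophy"):
        setattr(case, name, state)
    else:
        raise KeyError(f"unknown feature name {name!r}")


def _lognormal_params(median: float, iqr: tuple[float, float]) -> tuple[float, float]:
    """Log-scale (mu, sigma) matching a median and interquartile range."""
    mu = math.log(median)
    z_width = 1.3489795  # z(0.75) - z(0.25)
    sigma = math.log(iqr[1] / iqr[0]) / z_width
    return mu, sigma


def _sample_binary(
    rng: np.random.Generator,
    features: list[str],
    prevalence: dict[str, float],
    n: int,
    plan: dict[tuple[str, str], float],
) -> np.ndarray:
    """(n, len(features)) boolean presence matrix; Gaussian copula when a plan is given."""
    relevant = {
        (a, b): r for (a, b), r in plan.items() if a in features and b in features
    }
    if not relevant:
        u = rng.random((n, len(features)))
        p = np.array([prevalence[f] for f in features])
        return u < p
    k = len(features)
    cov = np.eye(k)
    idx = {f: i for i, f in enumerate(features)}
    for (a, b), rho in relevant.items():
        cov[idx[a], idx[b]] = cov[idx[b], idx[a]] = rho
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise ValueError("correlation_plan does not form a positive-definite matrix") from None
    z = rng.standard_normal((n, k)) @ chol.T
    from scipy.stats import norm

    thresholds = norm.ppf([prevalence[f] for f in features])
    return z < thresholds


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Sample a labeled cohort; identical output for identical spec + seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    cases: list[CaseRecord] = []
    for g in spec.groups:
        features = sorted(g.feature_prevalence)  # fixed draw order
        presence = _sample_binary(rng, features, g.feature_prevalence, g.n, spec.correlation_plan)
        miss = rng.random((g.n, len(features)))
        dur_cat = rng.choice(4, size=g.n, p=g.duration_category_probs)
        dur_u = rng.random(g.n)
        freq_cat = rng.choice(4, size=g.n, p=g.frequency_category_probs)
        freq_u = rng.random(g.n)
        mu, sigma = _lognormal_params(g.age_onset_median, g.age_onset_iqr)
        ages = np.exp(rng.normal(mu, sigma, g.n))
        female = rng.random(g.n) < g.female_prob
        blocked = rng.random(g.n) < g.missingness.get("trigger_block", 0.0)
        dur_missing = rng.random(g.n) < g.missingness.get("duration", 0.0)
        freq_missing = rng.random(g.n) < g.missingness.get("frequency", 0.0)
        age_missing = rng.random(g.n) < g.missingness.get("age_onset", 0.0)
        drug_draws = {
            d: (rng.random(g.n), rng.random(g.n)) for d in sorted(g.drug_response)
        }
        for i in range(g.n):
            case = CaseRecord(
                subject_id=f"{g.diagnosis.value}-sim-{i:04d}",
                source_ref=spec.label,
                diagnosis=g.diagnosis,
                sex=Sex.FEMALE if female[i] else Sex.MALE,
                age_onset=None if age_missing[i] else float(round(ages[i], 2)),
                trigger_data_available=True,  # adjusted below
            )
            if not dur_missing[i]:
                lo, hi = _DURATION_INTERVALS[DurationCategory(int(dur_cat[i]))]
                case.attack_duration_minutes = float(lo + dur_u[i] * (hi - lo))
            if not freq_missing[i]:
                lo, hi = _FREQUENCY_INTERVALS[FrequencyCategory(int(freq_cat[i]))]
                case.attack_frequency_per_month = float(lo + freq_u[i] * (hi - lo))
            any_trigger_known = False
            for k, name in enumerate(features):
                is_trigger = name in TRIGGERS
                if is_trigger and blocked[i]:
                    continue
                if miss[i, k] < g.missingness.get(name, 0.0):
                    continue
                state = TriState.PRESENT if presence[i, k] else TriState.ABSENT
                if is_trigger:
                    any_trigger_known = True
                _set_feature(case, name, state)
            case.trigger_data_available = any_trigger_known
            for d, (ev_u, resp_u) in drug_draws.items():
                p_ev, p_resp = g.drug_response[d]
                if ev_u[i] < p_ev:
                    case.drug_responses[d] = (
                        DrugResponse.COMPLETE if resp_u[i] < p_resp else DrugResponse.NONE
                    )
            case.validate()
            cases.append(case)
    return Cohort(cases=cases, label=spec.label)


def recover_parameters(cohort: Cohort) -> dict[str, GroupSpec]:
    """Empirical GroupSpec per diagnosis: prevalences among non-missing cases,
    ordinal category proportions, age-of-onset median and IQR."""
    matrix = build_feature_matrix(cohort)
    out: dict[str, GroupSpec] = {}
    for dx in (Diagnosis.EA1, Diagnosis.EA2):
        sel = matrix.diagnosis == dx.value
        n = int(sel.sum())
        if n == 0:
            continue
        sub = matrix.data[sel]
        prevalence = {
            col: float(sub[col].mean())
            for col in sub.columns
            if col not in ("duration_category", "frequency_category")
            and sub[col].notna().any()
        }
        def cat_probs(col: str) -> tuple[float, ...]:
            v = sub[col].dropna()
            if v.empty:
                return (math.nan,) * 4
            return tuple(float((v == k).mean()) for k in range(4))

        ages = np.array([
            c.age_onset for c in cohort
            if c.diagnosis is dx and c.age_onset is not None
        ])
        q1, med, q3 = (np.percentile(ages, [25, 50, 75]) if len(ages)
                       else (math.nan,) * 3)
        sexes = [c.sex for c in cohort if c.diagnosis is dx and c.sex is not Sex.UNKNOWN]
        out[dx.value] = GroupSpec(
            diagnosis=dx,
            n=n,
            feature_prevalence=prevalence,
            duration_category_probs=cat_probs("duration_category"),
            frequency_category_probs=cat_probs("frequency_category"),
            age_onset_median=float(med),
            age_onset_iqr=(float(q1), float(q3)),
            female_prob=(sum(s is Sex.FEMALE for s in sexes) / len(sexes)
                         if sexes else math.nan),
            missingness={
                col: float(sub[col].isna().mean()) for col in sub.columns
            },
        )
    return out


# --------------------------------------------------------------------------
# Study conditions
# --------------------------------------------------------------------------

#: Published per-group prevalences among evaluable subjects.
_EA1_PREVALENCE = {
    "kinesigenic": 54 / 79, "startle": 38 / 77, "non_kinesigenic": 71 / 79,
    "exercise_induced": 8 / 79, "physiological_stress": 35 / 73,
    "caffeine": 11 / 77, "anxiety": 20 / 77, "menstruation": 6 / 77, "heat": 2 / 77,
    "ictal_limb_ataxia": 46 / 94, "ictal_axial_ataxia": 64 / 94,
    "ictal_rigidity": 25 / 94, "ictal_myokymia": 22 / 94, "ictal_vertigo": 22 / 93,
    "ictal_headache": 4 / 94, "ictal_gi_symptoms": 8 / 94,
    "interictal_ataxia": 7 / 80, "interictal_nystagmus": 1 / 80,
    "interictal_clinical_myokymia": 32 / 80, "interictal_neuromyotonia": 16 / 80,
    "interictal_emg_myokymia": 38 / 79, "interictal_peripheral_other": 0.0,
}

_EA2_PREVALENCE = {
    "kinesigenic": 6 / 114, "startle": 0.0, "non_kinesigenic": 83 / 114,
    "exercise_induced": 15 / 114, "physiological_stress": 23 / 110,
    "caffeine": 5 / 114, "anxiety": 9 / 114, "menstruation": 0.0, "heat": 14 / 114,
    "ictal_limb_ataxia": 25 / 221, "ictal_axial_ataxia": 91 / 221,
    "ictal_rigidity": 1 / 220, "ictal_myokymia": 1 / 220, "ictal_vertigo": 139 / 220,
    "ictal_headache": 55 / 220, "ictal_gi_symptoms": 98 / 220,
    "interictal_ataxia": 106 / 246, "interictal_nystagmus": 156 / 246,
    "interictal_clinical_myokymia": 1 / 246, "interictal_neuromyotonia": 0.0,
    "interictal_emg_myokymia": 0.0, "interictal_peripheral_other": 1 / 246,
}

_EA1_MISSINGNESS = {
    "duration": 13 / 94, "frequency": 28 / 94, "trigger_block": 15 / 94,
    "startle": 2 / 79, "physiological_stress": 6 / 79, "caffeine": 2 / 79,
    "anxiety": 2 / 79, "menstruation": 2 / 79, "heat": 2 / 79,
    "ictal_vertigo": 1 / 94,
    **{f: 14 / 94 for f in (
        "interictal_ataxia", "interictal_nystagmus", "interictal_clinical_myokymia",
        "interictal_neuromyotonia", "interictal_peripheral_other")},
    "interictal_emg_myokymia": 15 / 94,
}

_EA2_MISSINGNESS = {
    "duration": 93 / 276, "frequency": 138 / 276, "trigger_block": 162 / 276,
    "physiological_stress": 4 / 114,
    **{f: 55 / 276 for f in (
        "ictal_limb_ataxia", "ictal_axial_ataxia")},
    **{f: 56 / 276 for f in (
        "ictal_rigidity", "ictal_myokymia", "ictal_vertigo", "ictal_headache",
        "ictal_gi_symptoms")},
    **{f: 30 / 276 for f in (
        "interictal_ataxia", "interictal_nystagmus", "interictal_clinical_myokymia",
        "interictal_neuromyotonia", "interictal_emg_myokymia",
        "interictal_peripheral_other")},
}


def study_spec(
    n_ea1: int = 94,
    n_ea2: int = 276,
    seed: int = 0,
    missingness: bool = True,
    label: str = "synthetic-core",
) -> CohortSpec:
    """The study conditions: group sizes, prevalences, ordinal category
    proportions, ages and missingness of the curated core data set.

    ``missingness=False`` zeroes all missingness rates (fully observed
    cohorts, as used for classifier operating-point checks).
    """
    ea1 = GroupSpec(
        diagnosis=Diagnosis.EA1,
        n=n_ea1,
        feature_prevalence=dict(_EA1_PREVALENCE),
        duration_category_probs=(61 / 81, 9 / 81, 9 / 81, 2 / 81),
        frequency_category_probs=(9 / 66, 7 / 66, 25 / 66, 25 / 66),
        age_onset_median=7.0,
        age_onset_iqr=(4.0, 10.0),
        female_prob=58 / 94,
        missingness=dict(_EA1_MISSINGNESS) if missingness else {},
        drug_response={"acetazolamide": (33 / 94, 17 / 33)},
    )
    ea2 = GroupSpec(
        diagnosis=Diagnosis.EA2,
        n=n_ea2,
        feature_prevalence=dict(_EA2_PREVALENCE),
        duration_category_probs=(11 / 183, 33 / 183, 119 / 183, 20 / 183),
        frequency_category_probs=(10 / 138, 34 / 138, 72 / 138, 22 / 138),
        age_onset_median=10.0,
        age_onset_iqr=(5.0, 15.0),
        female_prob=111 / 276,
        missingness=dict(_EA2_MISSINGNESS) if missingness else {},
        drug_response={"acetazolamide": (162 / 276, 139 / 162)},
    )
    return CohortSpec(groups=[ea1, ea2], seed=seed, label=label)
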