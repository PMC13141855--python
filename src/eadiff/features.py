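"""Feature engineering: ordinal attack categories, trigger taxonomy, feature matrix.

Raw attack metrics are normalized once at curation time (range collapse),
then binned into the ordinal categories used throughout the analysis:

* duration — brief (<=10 min), intermediate (>10 to <=60 min), prolonged
  (>1 h to <1 day), protracted (>=1 day);
* frequency — daily (>=1/day), weekly (>=1/week), monthly (>=1/month),
  rare/sporadic (<1/month), under a 30-day-month / 7-day-week convention.

:func:`build_feature_matrix` turns a cohort into the per-case binary/ordinal
matrix analysed downstream, with per-column non-missing counts (complete-case
denominators).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import IntEnum
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    Cohort,
    CaseRecord,
    Diagnosis,
    ICTAL_SIGNS,
    TRIGGERS,
    TriState,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DurationCategory",
    "FrequencyCategory",
    "TriggerTaxon",
    "FeatureMatrix",
    "collapse_range",
    "bin_duration",
    "bin_frequency",
    "map_trigger",
    "build_feature_matrix",
    "FEATURE_COLUMNS",
    "ORDINAL_COLUMNS",
    "MissingDataError",
]

MINUTES_PER_DAY = 1440.0
DAYS_PER_MONTH = 30.0
DAYS_PER_WEEK = 7.0


class MissingDataError(ValueError):
    """All inputs to a collapse/binning operation were absent."""


class DurationCategory(IntEnum):
    """Ordinal attack-duration category; integer order = clinical order."""

    BRIEF = 0
    INTERMEDIATE = 1
    PROLONGED = 2
    PROTRACTED = 3

    @property
    def label(self) -> str:
        return self.name.lower()


class FrequencyCategory(IntEnum):
    """Ordinal attack-frequency category, rare/sporadic < monthly < weekly < daily."""

    RARE_SPORADIC = 0
    MONTHLY = 1
    WEEKLY = 2
    DAILY = 3

    @property
    def label(self) -> str:
        return self.name.lower()


@dataclass(frozen=True)
class TriggerTaxon:
    """A trigger's place in the kinesigenic / exercise-induced / non-kinesigenic taxonomy."""

    category: str
    subtype: str = "none"

    def __post_init__(self) -> None:
        if self.subtype != "none" and self.category != "non_kinesigenic":
            raise ValueError("subtypes apply only to non-kinesigenic triggers")


def collapse_range(
    min_value: float | None = None,
    max_value: float | None = None,
    mean_value: float | None = None,
) -> float:
    """Collapse a reported range/mean/single value to one number.

    A range keeps its largest value; a mean-only report keeps the mean; a
    single value passes through. Raises :class:`MissingDataError` when
    nothing was reported.
    """
    if max_value is not None:
        return float(max_value)
    if min_value is not None:
        return float(min_value)
    if mean_value is not None:
        return float(mean_value)
    raise MissingDataError("no value reported")


def bin_duration(minutes: float) -> DurationCategory:
    """Bin an attack duration in minutes into its ordinal category."""
    if not minutes > 0:
        raise ValueError(f"attack duration must be positive, got {minutes}")
    if minutes <= 10:
        return DurationCategory.BRIEF
    if minutes <= 60:
        return DurationCategory.INTERMEDIATE
    if minutes < MINUTES_PER_DAY:
        return DurationCategory.PROLONGED
    return DurationCategory.PROTRACTED


def bin_frequency(attacks_per_month: float) -> FrequencyCategory:
    """Bin an attack frequency (attacks per 30-day month) into its category."""
    if not attacks_per_month > 0:
        raise ValueError(f"attack frequency must be positive, got {attacks_per_month}")
    if attacks_per_month >= DAYS_PER_MONTH:
        return FrequencyCategory.DAILY
    if attacks_per_month >= DAYS_PER_MONTH / DAYS_PER_WEEK:
        return FrequencyCategory.WEEKLY
    if attacks_per_month >= 1:
        return FrequencyCategory.MONTHLY
    return FrequencyCategory.RARE_SPORADIC


@lru_cache(maxsize=1)
def _synonyms() -> dict[str, TriggerTaxon]:
    text = resources.files("eadiff.data").joinpath("trigger_synonyms.yaml").read_text()
    raw = yaml.safe_load(text)
    return {
        label.strip().lower(): TriggerTaxon(category=cat, subtype=sub)
        for label, (cat, sub) in raw.items()
    }


def map_trigger(raw_label: str) -> TriggerTaxon:
    """Map a free-text trigger label onto the trigger taxonomy.

    Case-insensitive lookup in the shipped synonym dictionary; unmatched
    labels fall back to non-kinesigenic / other with a warning.
    """
    taxon = _synonyms().get(raw_label.strip().lower())
    if taxon is None:
        logger.warning("unrecognized trigger label %r -> non_kinesigenic/other", raw_label)
        return TriggerTaxon("non_kinesigenic", "other")
    return taxon


# --------------------------------------------------------------------------
# Feature matrix
# --------------------------------------------------------------------------

#: Components of the composite interictal "peripheral muscular symptoms" column.
PERIPHERAL_COMPONENTS = (
    "interictal_clinical_myokymia",
    "interictal_neuromyotonia",
    "interictal_emg_myokymia",
    "interictal_peripheral_other",
)

ORDINAL_COLUMNS = ("duration_category", "frequency_category")

#: Binary columns of the engineered matrix, in report order.
FEATURE_COLUMNS: tuple[str, ...] = (
    *TRIGGERS,
    "brief_attacks",
    "daily_attacks",
    *(f"ictal_{s}" for s in ICTAL_SIGNS if s != "aura"),
    "interictal_ataxia",
    "interictal_nystagmus",
    "interictal_clinical_myokymia",
    "interictal_neuromyotonia",
    "interictal_emg_myokymia",
    "interictal_peripheral_other",
    "interictal_headache",
    "interictal_tremor",
    "peripheral_muscular_interictal",
    "progressive_ataxia",
    "cerebellar_atrophy",
)


@dataclass
class FeatureMatrix:
    """Engineered per-case features with tri-state entries.

    ``data`` holds one row per case: binary columns coded 1.0 (present) /
    0.0 (absent) / NaN (unknown); ordinal columns hold category integers or
    NaN. ``diagnosis`` is an aligned Series of "EA1"/"EA2"/None.
    """

    data: pd.DataFrame
    diagnosis: pd.Series

    @property
    def n(self) -> pd.Series:
        """Per-column non-missing count (each feature's complete-case N)."""
        return self.data.notna().sum()

    def __len__(self) -> int:
        return len(self.data)


def _tri_num(value: TriState) -> float:
    if value is TriState.PRESENT:
        return 1.0
    if value is TriState.ABSENT:
        return 0.0
    return np.nan


def case_features(case: CaseRecord) -> dict[str, float]:
    """Engineered feature vector for a single case (NaN = unknown)."""
    row: dict[str, float] = {}
    for t in TRIGGERS:
        row[t] = _tri_num(case.triggers[t])
    for s in ICTAL_SIGNS:
        if s != "aura":  # collected but not analysed
            row[f"ictal_{s}"] = _tri_num(case.ictal_signs[s])
    inter_map = {
        "ataxia": "interictal_ataxia",
        "nystagmus": "interictal_nystagmus",
        "clinical_myokymia": "interictal_clinical_myokymia",
        "neuromyotonia": "interictal_neuromyotonia",
        "emg_myokymia": "interictal_emg_myokymia",
        "peripheral_other": "interictal_peripheral_other",
        "headache": "interictal_headache",
        "tremor": "interictal_tremor",
    }
    for raw, col in inter_map.items():
        row[col] = _tri_num(case.interictal_signs[raw])
    row["progressive_ataxia"] = _tri_num(case.progressive_ataxia)
    row["cerebellar_atrophy"] = _tri_num(case.cerebellar_atrophy)

    # composite: any peripheral muscular interictal sign
    comps = [row[c] for c in PERIPHERAL_COMPONENTS]
    if any(c == 1.0 for c in comps):
        row["peripheral_muscular_interictal"] = 1.0
    elif all(np.isnan(c) for c in comps):
        row["peripheral_muscular_interictal"] = np.nan
    else:
        row["peripheral_muscular_interictal"] = 0.0

    if case.attack_duration_minutes is not None:
        cat = bin_duration(case.attack_duration_minutes)
        row["duration_category"] = float(cat)
        row["brief_attacks"] = 1.0 if cat is DurationCategory.BRIEF else 0.0
    else:
        row["duration_category"] = np.nan
        row["brief_attacks"] = np.nan
    if case.attack_frequency_per_month is not None:
        cat = bin_frequency(case.attack_frequency_per_month)
        row["frequency_category"] = float(cat)
        row["daily_attacks"] = 1.0 if cat is FrequencyCategory.DAILY else 0.0
    else:
        row["frequency_category"] = np.nan
        row["daily_attacks"] = np.nan
    return row


def build_feature_matrix(cohort: Cohort) -> FeatureMatrix:
    """Engineer the analysis feature matrix for a cohort.

    Missingness propagates: unknown raw entries give NaN engineered entries,
    and the composite peripheral-muscular column is unknown only when every
    component is unknown.
    """
    index = [f"{c.source_ref}:{c.subject_id}" if c.source_ref else c.subject_id for c in cohort]
    rows = [case_features(c) for c in cohort]
    columns = list(FEATURE_COLUMNS) + list(ORDINAL_COLUMNS)
    data = pd.DataFrame(rows, index=index, columns=columns, dtype=float)
    diagnosis = pd.Series(
        [c.diagnosis.value if c.diagnosis else None for c in cohort],
        index=index, dtype=object, name="diagnosis",
    )
    return FeatureMatrix(data=data, diagnosis=diagnosis)
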