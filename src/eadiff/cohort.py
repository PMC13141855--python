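"""Case-record data model for episodic ataxia cohorts.

One :class:`CaseRecord` per published subject, with tri-state
(present / absent / unknown) semantics for every phenotype feature so that
missing literature data is excluded from denominators rather than counted
as absent. Cohorts round-trip losslessly through a flat CSV dialect and a
nested JSON dialect (see ``data/schema.md`` for the column reference).
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable

logger = logging.getLogger(__name__)

__all__ = [
    "Diagnosis",
    "TriState",
    "Sex",
    "DrugResponse",
    "CaseRecord",
    "Cohort",
    "TRIGGERS",
    "ICTAL_SIGNS",
    "INTERICTAL_SIGNS",
    "DRUGS",
    "read_cohort",
    "write_cohort",
    "filter_cohort",
    "CohortError",
    "ParseError",
    "ValidationError",
]


class CohortError(Exception):
    """Base class for cohort data errors."""


class ParseError(CohortError):
    """A file did not conform to the cohort schema."""


class ValidationError(CohortError):
    """A record or cohort violated an invariant."""


class Diagnosis(str, Enum):
    """Molecularly confirmed diagnosis: EA1 = pathogenic KCNA1, EA2 = pathogenic CACNA1A."""

    EA1 = "EA1"
    EA2 = "EA2"

    @property
    def gene(self) -> str:
        return {"EA1": "KCNA1", "EA2": "CACNA1A"}[self.value]

    @classmethod
    def for_gene(cls, gene: str) -> "Diagnosis":
        try:
            return {"KCNA1": cls.EA1, "CACNA1A": cls.EA2}[gene.upper()]
        except KeyError:
            raise ValidationError(f"no EA diagnosis maps to gene {gene!r}") from None


class TriState(str, Enum):
    """Presence of a feature; ``unknown`` drops the case from that feature's denominator."""

    PRESENT = "present"
    ABSENT = "absent"
    UNKNOWN = "unknown"

    def __bool__(self) -> bool:  # pragma: no cover - guard against accidental truthiness
        raise TypeError("TriState is not boolean; compare against members explicitly")


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"


class DrugResponse(str, Enum):
    COMPLETE = "complete"
    PARTIAL = "partial"
    NONE = "none"
    UNKNOWN = "unknown"


# Canonical feature vocabularies. Trigger names follow the curation taxonomy
# (kinesigenic / exercise-induced / non-kinesigenic subtypes); sign names are
# the clinical terms used in case reports.
TRIGGERS: tuple[str, ...] = (
    "kinesigenic",
    "exercise_induced",
    "non_kinesigenic",
    "alcohol",
    "tobacco",
    "sleep_deprivation",
    "physiological_stress",
    "fatigue",
    "fasting",
    "caffeine",
    "startle",
    "heat",
    "anxiety",
    "menstruation",
    "excitement",
    "emotional_stress",
    "other",
)

ICTAL_SIGNS: tuple[str, ...] = (
    "limb_ataxia",
    "axial_ataxia",
    "rigidity",
    "myokymia",
    "vertigo",
    "headache",
    "gi_symptoms",
    "autonomic",
    "aura",  # collected but not analysed downstream
)

INTERICTAL_SIGNS: tuple[str, ...] = (
    "ataxia",
    "nystagmus",
    "clinical_myokymia",
    "neuromyotonia",
    "emg_myokymia",
    "peripheral_other",
    "headache",
    "tremor",
)

DRUGS: tuple[str, ...] = (
    "acetazolamide",
    "four_ap",
    "phenytoin",
    "carbamazepine",
    "pyridostigmine",
    "flunarizine",
    "valproic_acid",
    "topiramate",
)


def _tristate_map(names: Iterable[str]) -> dict[str, TriState]:
    return {name: TriState.UNKNOWN for name in names}


@dataclass
class VariantRecord:
    """A curated variant in KCNA1 or CACNA1A.

    Transcript and HGVS strings are stored verbatim as annotation anchors;
    no coordinate arithmetic is performed on them. ``nmd_predicted`` is a
    curator-supplied flag (nonsense-mediated-decay prediction), not computed.
    """

    gene: str
    mutational_effect: str = "other"
    acmg_class: str = "vus"
    transcript: str = ""
    hgvs_c: str = ""
    hgvs_p: str = ""
    nmd_predicted: TriState = TriState.UNKNOWN
    functional_study: str = "none"
    dominant_negative: bool = False

    GENES = ("KCNA1", "CACNA1A")
    EFFECTS = (
        "missense",
        "nonsense",
        "frameshift",
        "splice",
        "inframe_deletion",
        "outofframe_deletion",
        "other",
        "repeat_expansion",
    )
    ACMG = ("pathogenic", "likely_pathogenic", "vus", "likely_benign", "benign", "unmappable")
    FUNCTIONAL = ("decreased_function", "increased_function", "none")

    def __post_init__(self) -> None:
        self.gene = self.gene.upper()
        if self.gene not in self.GENES:
            raise ValidationError(f"unknown gene {self.gene!r}")
        if self.mutational_effect not in self.EFFECTS:
            raise ValidationError(f"unknown mutational effect {self.mutational_effect!r}")
        if self.acmg_class not in self.ACMG:
            raise ValidationError(f"unknown ACMG class {self.acmg_class!r}")
        if self.functional_study not in self.FUNCTIONAL:
            raise ValidationError(f"unknown functional study result {self.functional_study!r}")
        if not isinstance(self.nmd_predicted, TriState):
            self.nmd_predicted = TriState(self.nmd_predicted)


@dataclass
class CaseRecord:
    """One curated subject.

    ``diagnosis`` may be ``None`` (genotype unknown) for classifier input;
    diagnostic-accuracy computations reject unlabeled cases. Attack duration
    is stored in minutes after range collapse; attack frequency in attacks
    per month (30-day month convention).
    """

    subject_id: str
    source_ref: str = ""
    diagnosis: Diagnosis | None = None
    sex: Sex = Sex.UNKNOWN
    age_onset: float | None = None
    age_at_report: float | None = None
    attack_duration_minutes: float | None = None
    attack_frequency_per_month: float | None = None
    trigger_data_available: bool = False
    triggers: dict[str, TriState] = field(default_factory=lambda: _tristate_map(TRIGGERS))
    ictal_signs: dict[str, TriState] = field(default_factory=lambda: _tristate_map(ICTAL_SIGNS))
    interictal_signs: dict[str, TriState] = field(
        default_factory=lambda: _tristate_map(INTERICTAL_SIGNS)
    )
    progressive_ataxia: TriState = TriState.UNKNOWN
    cerebellar_atrophy: TriState = TriState.UNKNOWN
    drug_responses: dict[str, DrugResponse] = field(
        default_factory=lambda: {d: DrugResponse.UNKNOWN for d in DRUGS}
    )
    variant: VariantRecord | None = None

    def __post_init__(self) -> None:
        for name in TRIGGERS:
            self.triggers.setdefault(name, TriState.UNKNOWN)
        for name in ICTAL_SIGNS:
            self.ictal_signs.setdefault(name, TriState.UNKNOWN)
        for name in INTERICTAL_SIGNS:
            self.interictal_signs.setdefault(name, TriState.UNKNOWN)
        for name in DRUGS:
            self.drug_responses.setdefault(name, DrugResponse.UNKNOWN)
        self.validate()

    @property
    def key(self) -> tuple[str, str]:
        """Uniqueness key: (source_ref, subject_id) to allow multi-paper merges."""
        return (self.source_ref, self.subject_id)

    def validate(self) -> None:
        if self.age_onset is not None and self.age_onset < 0:
            raise ValidationError(f"{self.subject_id}: negative age of onset")
        if (
            self.age_onset is not None
            and self.age_at_report is not None
            and self.age_onset > self.age_at_report
        ):
            raise ValidationError(f"{self.subject_id}: age_onset exceeds age_at_report")
        if self.attack_duration_minutes is not None and self.attack_duration_minutes <= 0:
            raise ValidationError(f"{self.subject_id}: non-positive attack duration")
        if self.attack_frequency_per_month is not None and self.attack_frequency_per_month <= 0:
            raise ValidationError(f"{self.subject_id}: non-positive attack frequency")
        if not self.trigger_data_available:
            bad = [t for t, v in self.triggers.items() if v is not TriState.UNKNOWN]
            if bad:
                raise ValidationError(
                    f"{self.subject_id}: trigger data unavailable but {bad[0]} is set"
                )


@dataclass
class Cohort:
    """An ordered collection of case records with unique (source_ref, subject_id)."""

    cases: list[CaseRecord] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for case in self.cases:
            if case.key in seen:
                raise ValidationError(f"duplicate subject key {case.key}")
            seen.add(case.key)

    def __len__(self) -> int:
        return len(self.cases)

    def __iter__(self):
        return iter(self.cases)


# --------------------------------------------------------------------------
# Serialization
# --------------------------------------------------------------------------

_VARIANT_COLUMNS = (
    "variant_gene",
    "variant_transcript",
    "variant_hgvs_c",
    "variant_hgvs_p",
    "variant_effect",
    "variant_acmg",
    "variant_nmd",
    "variant_functional_study",
    "variant_dominant_negative",
)

CSV_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "source_ref",
    "diagnosis",
    "sex",
    "age_onset",
    "age_at_report",
    "attack_duration_minutes",
    "attack_frequency_per_month",
    "trigger_data_available",
    *(f"trigger_{t}" for t in TRIGGERS),
    *(f"ictal_{s}" for s in ICTAL_SIGNS),
    *(f"interictal_{s}" for s in INTERICTAL_SIGNS),
    "progressive_ataxia",
    "cerebellar_atrophy",
    *(f"drug_{d}" for d in DRUGS),
    *_VARIANT_COLUMNS,
)


def _tri_to_cell(value: TriState) -> str:
    return {TriState.PRESENT: "1", TriState.ABSENT: "0", TriState.UNKNOWN: ""}[value]


def _cell_to_tri(cell: str, where: str) -> TriState:
    cell = cell.strip()
    if cell == "":
        return TriState.UNKNOWN
    if cell in ("1", "present"):
        return TriState.PRESENT
    if cell in ("0", "absent"):
        return TriState.ABSENT
    raise ParseError(f"{where}: unrecognized tri-state value {cell!r}")


def _num(cell: str, where: str) -> float | None:
    cell = cell.strip()
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise ParseError(f"{where}: not a number: {cell!r}") from None


def _fmt_num(value: float | None) -> str:
    if value is None:
        return ""
    if float(value).is_integer():
        return str(int(value))
    return repr(float(value))


def _case_to_row(case: CaseRecord) -> dict[str, str]:
    row = {
        "subject_id": case.subject_id,
        "source_ref": case.source_ref,
        "diagnosis": case.diagnosis.value if case.diagnosis else "",
        "sex": "" if case.sex is Sex.UNKNOWN else case.sex.value,
        "age_onset": _fmt_num(case.age_onset),
        "age_at_report": _fmt_num(case.age_at_report),
        "attack_duration_minutes": _fmt_num(case.attack_duration_minutes),
        "attack_frequency_per_month": _fmt_num(case.attack_frequency_per_month),
        "trigger_data_available": "1" if case.trigger_data_available else "0",
        "progressive_ataxia": _tri_to_cell(case.progressive_ataxia),
        "cerebellar_atrophy": _tri_to_cell(case.cerebellar_atrophy),
    }
    for t in TRIGGERS:
        row[f"trigger_{t}"] = _tri_to_cell(case.triggers[t])
    for s in ICTAL_SIGNS:
        row[f"ictal_{s}"] = _tri_to_cell(case.ictal_signs[s])
    for s in INTERICTAL_SIGNS:
        row[f"interictal_{s}"] = _tri_to_cell(case.interictal_signs[s])
    for d in DRUGS:
        resp = case.drug_responses[d]
        row[f"drug_{d}"] = "" if resp is DrugResponse.UNKNOWN else resp.value
    v = case.variant
    if v is None:
        for col in _VARIANT_COLUMNS:
            row[col] = ""
    else:
        row.update(
            variant_gene=v.gene,
            variant_transcript=v.transcript,
            variant_hgvs_c=v.hgvs_c,
            variant_hgvs_p=v.hgvs_p,
            variant_effect=v.mutational_effect,
            variant_acmg=v.acmg_class,
            variant_nmd=_tri_to_cell(v.nmd_predicted),
            variant_functional_study="" if v.functional_study == "none" else v.functional_study,
            variant_dominant_negative="1" if v.dominant_negative else "0",
        )
    return row


def _row_to_case(row: dict[str, str], rownum: int) -> CaseRecord:
    def where(col: str) -> str:
        return f"row {rownum}, column {col!r}"

    def enum_cell(col: str, enum_cls, default):
        cell = row.get(col, "").strip().lower()
        if cell == "":
            return default
        try:
            return enum_cls(cell if enum_cls is not Diagnosis else cell.upper())
        except ValueError:
            raise ParseError(f"{where(col)}: unrecognized value {row[col]!r}") from None

    variant = None
    if row.get("variant_gene", "").strip():
        fs = row.get("variant_functional_study", "").strip().lower() or "none"
        try:
            variant = VariantRecord(
                gene=row["variant_gene"].strip(),
                transcript=row.get("variant_transcript", "").strip(),
                hgvs_c=row.get("variant_hgvs_c", "").strip(),
                hgvs_p=row.get("variant_hgvs_p", "").strip(),
                mutational_effect=row.get("variant_effect", "other").strip().lower() or "other",
                acmg_class=row.get("variant_acmg", "vus").strip().lower() or "vus",
                nmd_predicted=_cell_to_tri(row.get("variant_nmd", ""), where("variant_nmd")),
                functional_study=fs,
                dominant_negative=row.get("variant_dominant_negative", "").strip() == "1",
            )
        except ValidationError as exc:
            raise ParseError(f"{where('variant_gene')}: {exc}") from None

    try:
        return CaseRecord(
            subject_id=row["subject_id"].strip(),
            source_ref=row.get("source_ref", "").strip(),
            diagnosis=enum_cell("diagnosis", Diagnosis, None),
            sex=enum_cell("sex", Sex, Sex.UNKNOWN),
            age_onset=_num(row.get("age_onset", ""), where("age_onset")),
            age_at_report=_num(row.get("age_at_report", ""), where("age_at_report")),
            attack_duration_minutes=_num(
                row.get("attack_duration_minutes", ""), where("attack_duration_minutes")
            ),
            attack_frequency_per_month=_num(
                row.get("attack_frequency_per_month", ""), where("attack_frequency_per_month")
            ),
            trigger_data_available=row.get("trigger_data_available", "").strip() == "1",
            triggers={
                t: _cell_to_tri(row.get(f"trigger_{t}", ""), where(f"trigger_{t}"))
                for t in TRIGGERS
            },
            ictal_signs={
                s: _cell_to_tri(row.get(f"ictal_{s}", ""), where(f"ictal_{s}"))
                for s in ICTAL_SIGNS
            },
            interictal_signs={
                s: _cell_to_tri(row.get(f"interictal_{s}", ""), where(f"interictal_{s}"))
                for s in INTERICTAL_SIGNS
            },
            progressive_ataxia=_cell_to_tri(
                row.get("progressive_ataxia", ""), where("progressive_ataxia")
            ),
            cerebellar_atrophy=_cell_to_tri(
                row.get("cerebellar_atrophy", ""), where("cerebellar_atrophy")
            ),
            drug_responses={
                d: enum_cell(f"drug_{d}", DrugResponse, DrugResponse.UNKNOWN) for d in DRUGS
            },
            variant=variant,
        )
    except ValidationError as exc:
        raise ParseError(f"row {rownum}: {exc}") from None


def _case_to_json(case: CaseRecord) -> dict:
    d = asdict(case)
    d["diagnosis"] = case.diagnosis.value if case.diagnosis else None
    d["sex"] = case.sex.value
    d["triggers"] = {k: v.value for k, v in case.triggers.items()}
    d["ictal_signs"] = {k: v.value for k, v in case.ictal_signs.items()}
    d["interictal_signs"] = {k: v.value for k, v in case.interictal_signs.items()}
    d["progressive_ataxia"] = case.progressive_ataxia.value
    d["cerebellar_atrophy"] = case.cerebellar_atrophy.value
    d["drug_responses"] = {k: v.value for k, v in case.drug_responses.items()}
    if case.variant is not None:
        d["variant"] = asdict(case.variant)
        d["variant"]["nmd_predicted"] = case.variant.nmd_predicted.value
    return d


def _case_from_json(d: dict, rownum: int) -> CaseRecord:
    try:
        variant = None
        if d.get("variant"):
            v = dict(d["variant"])
            v["nmd_predicted"] = TriState(v.get("nmd_predicted", "unknown"))
            variant = VariantRecord(**v)
        return CaseRecord(
            subject_id=d["subject_id"],
            source_ref=d.get("source_ref", ""),
            diagnosis=Diagnosis(d["diagnosis"]) if d.get("diagnosis") else None,
            sex=Sex(d.get("sex", "unknown")),
            age_onset=d.get("age_onset"),
            age_at_report=d.get("age_at_report"),
            attack_duration_minutes=d.get("attack_duration_minutes"),
            attack_frequency_per_month=d.get("attack_frequency_per_month"),
            trigger_data_available=bool(d.get("trigger_data_available", False)),
            triggers={k: TriState(v) for k, v in d.get("triggers", {}).items()},
            ictal_signs={k: TriState(v) for k, v in d.get("ictal_signs", {}).items()},
            interictal_signs={k: TriState(v) for k, v in d.get("interictal_signs", {}).items()},
            progressive_ataxia=TriState(d.get("progressive_ataxia", "unknown")),
            cerebellar_atrophy=TriState(d.get("cerebellar_atrophy", "unknown")),
            drug_responses={
                k: DrugResponse(v) for k, v in d.get("drug_responses", {}).items()
            },
            variant=variant,
        )
    except (KeyError, ValueError, ValidationError) as exc:
        raise ParseError(f"record {rownum}: {exc}") from None


def read_cohort(path: str | Path, format: str | None = None, label: str = "") -> Cohort:
    """Read a cohort from CSV or JSON.

    ``format`` is inferred from the file suffix when not given. Empty cells
    become ``unknown``; unrecognized enumeration spellings raise
    :class:`ParseError` naming the row and column.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            cases = [_row_to_case(row, i + 2) for i, row in enumerate(reader)]
    elif fmt == "json":
        payload = json.loads(path.read_text(encoding="utf-8"))
        records = payload["cases"] if isinstance(payload, dict) else payload
        label = label or (payload.get("label", "") if isinstance(payload, dict) else "")
        cases = [_case_from_json(d, i) for i, d in enumerate(records)]
    else:
        raise ParseError(f"unsupported cohort format {fmt!r}")
    return Cohort(cases=cases, label=label)


def write_cohort(cohort: Cohort, path: str | Path, format: str | None = None) -> Path:
    """Write a cohort to CSV or JSON, re-readable with full fidelity."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS, lineterminator="\n")
            writer.writeheader()
            for case in cohort:
                writer.writerow(_case_to_row(case))
    elif fmt == "json":
        payload = {"label": cohort.label, "cases": [_case_to_json(c) for c in cohort]}
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n", encoding="utf-8")
    else:
        raise ParseError(f"unsupported cohort format {fmt!r}")
    return path


# --------------------------------------------------------------------------
# Filtering
# --------------------------------------------------------------------------

def _filter_diagnostic(case: CaseRecord) -> bool:
    from .variants import is_diagnostic  # local import avoids a cycle

    return case.variant is not None and is_diagnostic(case.variant)


def _filter_gene(case: CaseRecord, gene: str) -> bool:
    return case.variant is not None and case.variant.gene == gene.upper()


def _filter_haplo(case: CaseRecord, group: str) -> bool:
    from .variants import assign_functional_group, is_diagnostic

    if case.variant is None or not is_diagnostic(case.variant):
        return False
    fg = assign_functional_group(case.variant)
    if group == "haploinsufficient":
        return fg.haploinsufficient
    if group == "non_haploinsufficient":
        return not fg.haploinsufficient
    raise ValidationError(f"unknown haploinsufficiency group {group!r}")


def _filter_has_field(case: CaseRecord, field_name: str) -> bool:
    value = getattr(case, field_name)
    if isinstance(value, TriState):
        return value is not TriState.UNKNOWN
    return value is not None


_FILTERS: dict[str, Callable] = {
    "diagnostic-variant-only": _filter_diagnostic,
    "gene": _filter_gene,
    "haploinsufficiency": _filter_haplo,
    "has-field": _filter_has_field,
    "identity": lambda case: True,
}


def filter_cohort(cohort: Cohort, predicate: str, **params) -> Cohort:
    """Return the sub-cohort satisfying a registered named filter.

    Registered predicates: ``diagnostic-variant-only``, ``gene`` (gene=...),
    ``haploinsufficiency`` (group=...), ``has-field`` (field_name=...),
    ``identity``. The input cohort is untouched.
    """
    try:
        fn = _FILTERS[predicate]
    except KeyError:
        raise CohortError(
            f"unknown filter predicate {predicate!r}; known: {sorted(_FILTERS)}"
        ) from None
    kept = [case for case in cohort if fn(case, **params)]
    logger.info(
        "filter %s%s: kept %d of %d cases (removed %d)",
        predicate, params or "", len(kept), len(cohort), len(cohort) - len(kept),
    )
    return Cohort(cases=kept, label=cohort.label)
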