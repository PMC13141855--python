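# Cohort file schema, version 1

One row (CSV) or object (JSON) per subject. Enumeration spellings are
case-insensitive on read; files are UTF-8. In CSV, tri-state phenotype
columns encode present = `1`, absent = `0`, unknown = empty cell. An empty
cell in any optional column means unknown/not reported.

## Identity and demographics

| column | type | notes |
| --- | --- | --- |
| `subject_id` | string | required; unique within `source_ref` |
| `source_ref` | string | citation tag of the source report; `(source_ref, subject_id)` is the uniqueness key |
| `diagnosis` | `EA1` \| `EA2` \| empty | empty = genotype unknown (classifier input only) |
| `sex` | `female` \| `male` \| empty | |
| `age_onset` | years, fraction allowed, >= 0 | |
| `age_at_report` | years | must be >= `age_onset` when both present |

## Attack metrics

| column | type | notes |
| --- | --- | --- |
| `attack_duration_minutes` | positive number | already range-collapsed (largest value of a range, or the reported mean) |
| `attack_frequency_per_month` | positive number | attacks per 30-day month; weeks are 7 days |

Ordinal categories are derived, not stored: duration brief (<=10 min),
intermediate (>10 to <=60 min), prolonged (>1 h to <1 day), protracted
(>=1 day); frequency daily (>=30/month), weekly (>=30/7), monthly (>=1),
rare/sporadic (<1).

## Triggers

`trigger_data_available`: `1`/`0`. When `0`, every trigger column must be
empty. Tri-state columns, one per taxon:
`trigger_kinesigenic`, `trigger_exercise_induced`, `trigger_non_kinesigenic`,
and the non-kinesigenic subtypes `trigger_alcohol`, `trigger_tobacco`,
`trigger_sleep_deprivation`, `trigger_physiological_stress`
(fever/illness/infection), `trigger_fatigue`, `trigger_fasting`,
`trigger_caffeine`, `trigger_startle`, `trigger_heat`, `trigger_anxiety`,
`trigger_menstruation`, `trigger_excitement`, `trigger_emotional_stress`,
`trigger_other`. Free-text labels are normalized upstream with the shipped
synonym dictionary (`trigger_synonyms.yaml`).

## Signs

Tri-state columns. During attacks: `ictal_limb_ataxia`, `ictal_axial_ataxia`,
`ictal_rigidity`, `ictal_myokymia`, `ictal_vertigo`, `ictal_headache`,
`ictal_gi_symptoms`, `ictal_autonomic`, `ictal_aura` (collected, not
analysed). Between attacks: `interictal_ataxia`, `interictal_nystagmus`,
`interictal_clinical_myokymia`, `interictal_neuromyotonia`,
`interictal_emg_myokymia`, `interictal_peripheral_other` (any other stated
peripheral muscular sign), `interictal_headache`, `interictal_tremor`.
Course/imaging: `progressive_ataxia`, `cerebellar_atrophy`.

## Drug responses

`drug_<name>` for `acetazolamide`, `four_ap` (4-aminopyridine), `phenytoin`,
`carbamazepine`, `pyridostigmine`, `flunarizine`, `valproic_acid`,
`topiramate`. Values `complete` | `partial` | `none` | empty (unknown).
"Response" in analyses means complete or partial.

## Variant

| column | type |
| --- | --- |
| `variant_gene` | `KCNA1` \| `CACNA1A`; empty = no variant on record |
| `variant_transcript` | verbatim accession string (annotation only) |
| `variant_hgvs_c`, `variant_hgvs_p` | verbatim HGVS strings |
| `variant_effect` | `missense` \| `nonsense` \| `frameshift` \| `splice` \| `inframe_deletion` \| `outofframe_deletion` \| `other` \| `repeat_expansion` |
| `variant_acmg` | `pathogenic` \| `likely_pathogenic` \| `vus` \| `likely_benign` \| `benign` \| `unmappable` |
| `variant_nmd` | tri-state: nonsense-mediated decay predicted (curator flag) |
| `variant_functional_study` | `decreased_function` \| `increased_function` \| empty (none) |
| `variant_dominant_negative` | `1`/`0` |

JSON files carry the same fields nested: a top-level
`{"label": ..., "cases": [...]}` with `triggers`, `ictal_signs`,
`interictal_signs`, `drug_responses` as maps and `variant` as an object.
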