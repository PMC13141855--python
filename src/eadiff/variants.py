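"""Variant inclusion gating and functional grouping.

Implements the genetic curation rules: only pathogenic / likely-pathogenic
variants (ACMG 5-tier) are diagnostic, trinucleotide repeat expansions are
excluded outright, and diagnostic variants are grouped into loss-of-function
(LoF), gain-of-function (GoF) or unknown effect. Within LoF, truncating
variants predicted to undergo nonsense-mediated decay (NMD) form the
haploinsufficient subgroup used for genotype-phenotype comparison; variants
shown functionally deleterious (including dominant-negative missense) are
LoF but not haploinsufficient unless they also truncate with NMD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .cohort import Cohort, CaseRecord, TriState, ValidationError, VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "FunctionalGroup",
    "is_diagnostic",
    "assign_functional_group",
    "haploinsufficiency_partition",
]

#: Mutational effects that truncate the reading frame outright. Splice
#: variants truncate only when curated as leading to a premature stop
#: (captured via the nmd_predicted flag).
_TRUNCATING_EFFECTS = frozenset({"nonsense", "frameshift", "outofframe_deletion"})

#: Effects producing a translated product; with no functional evidence these
#: stay in the unknown group.
_TRANSLATED_EFFECTS = frozenset(
    {"missense", "inframe_deletion", "nonsense", "frameshift", "outofframe_deletion",
     "splice", "other"}
)


@dataclass(frozen=True)
class FunctionalGroup:
    """LoF / GoF / unknown grouping; ``haploinsufficient`` is meaningful only for LoF."""

    value: str  # "LoF" | "GoF" | "unknown"
    haploinsufficient: bool = False
    dominant_negative: bool = False

    def __post_init__(self) -> None:
        if self.haploinsufficient and self.value != "LoF":
            raise ValidationError("haploinsufficient grouping requires LoF")


def is_diagnostic(variant: VariantRecord) -> bool:
    """True iff the variant supports an EA1/EA2 diagnosis.

    Pathogenic or likely-pathogenic ACMG class, and not a repeat expansion
    (the SCA6 mechanism, excluded from these cohorts).
    """
    return (
        variant.acmg_class in ("pathogenic", "likely_pathogenic")
        and variant.mutational_effect != "repeat_expansion"
    )


def assign_functional_group(variant: VariantRecord) -> FunctionalGroup:
    """Group a diagnostic variant as LoF, GoF or unknown effect.

    Rules, in order:

    a. truncating effect (nonsense / frameshift / out-of-frame deletion, or a
       splice variant curated as producing a premature stop) with NMD
       predicted -> LoF, haploinsufficient;
    b. decreased channel function shown in a functional study, or a
       dominant-negative flag -> LoF, non-haploinsufficient (unless *a* also
       holds); the dominant-negative flag is retained;
    c. increased channel function shown -> GoF; combining this with an
       NMD-predicted truncation or a dominant-negative flag is contradictory
       and raises;
    d. otherwise a translated product with no conclusive functional evidence
       -> unknown.
    """
    if not is_diagnostic(variant):
        raise ValidationError(
            f"functional grouping requires a diagnostic variant ({variant.hgvs_c or variant.gene})"
        )
    truncating_nmd = (
        variant.mutational_effect in _TRUNCATING_EFFECTS
        or variant.mutational_effect == "splice"
    ) and variant.nmd_predicted is TriState.PRESENT

    if variant.functional_study == "increased_function":
        if truncating_nmd or variant.dominant_negative:
            raise ValidationError(
                "contradictory functional evidence: increased-function study on a "
                "loss-of-function variant"
            )
        return FunctionalGroup("GoF")
    if truncating_nmd:
        return FunctionalGroup("LoF", haploinsufficient=True,
                               dominant_negative=variant.dominant_negative)
    if variant.functional_study == "decreased_function" or variant.dominant_negative:
        return FunctionalGroup("LoF", haploinsufficient=False,
                               dominant_negative=variant.dominant_negative)
    return FunctionalGroup("unknown")


def haploinsufficiency_partition(
    cohort: Cohort, gene: str
) -> tuple[list[CaseRecord], list[CaseRecord]]:
    """Split a gene's diagnostic cases into (haploinsufficient, non-haploinsufficient).

    The non-haploinsufficient side holds every other diagnostic variant of the
    gene (functionally deleterious missense, dominant-negative, GoF, unknown).
    Cases without a variant, with another gene, or with non-diagnostic
    variants are excluded with a warning.
    """
    gene = gene.upper()
    haplo: list[CaseRecord] = []
    non_haplo: list[CaseRecord] = []
    skipped = 0
    for case in cohort:
        v = case.variant
        if v is None or v.gene != gene or not is_diagnostic(v):
            skipped += 1
            continue
        group = assign_functional_group(v)
        (haplo if group.haploinsufficient else non_haplo).append(case)
    if skipped:
        logger.warning(
            "haploinsufficiency partition (%s): skipped %d cases without a diagnostic "
            "%s variant", gene, skipped, gene,
        )
    logger.info(
        "haploinsufficiency partition (%s): %d haploinsufficient vs %d other",
        gene, len(haplo), len(non_haplo),
    )
    return haplo, non_haplo
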