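"""Computational and functional-assay criteria.

PP3/BP4 from REVEL (missense) and SpliceAI (other non-null consequences)
with per-gene threshold overrides; PS3/BS3 as a pass-through of curated
assay strengths; PP5/BP6 discontinued but kept in the audit trail.
"""

from __future__ import annotations

from typing import Optional

from .model import (
    AssayDirection,
    Consequence,
    Criterion,
    CriterionCall,
    FunctionalAssayEvidence,
    GeneContext,
    InSilicoScores,
    InsilicoThresholds,
    NULL_CONSEQUENCES,
    Strength,
    VariantDescriptor,
    applied_call,
    unapplied_call,
)

DEFAULT_INSILICO = InsilicoThresholds()


def evaluate_pp3_bp4(
    v: VariantDescriptor,
    scores: InSilicoScores,
    gene: GeneContext,
    bp7_call: Optional[CriterionCall] = None,
) -> Optional[CriterionCall]:
    """PP3 / BP4 from in-silico predictors.

    Missense variants use the REVEL band (benign below, pathogenic above,
    no call in between); other non-null consequences use the SpliceAI
    delta band.  Null variants are covered by PVS1 and synonymous variants
    by BP7, which pre-empts this pair when it fires.  Per-gene threshold
    overrides stand in for gene-specific ClinGen calibrations.
    """
    thresholds = gene.insilico_overrides or DEFAULT_INSILICO
    override_note = " [THR:insilico_override]" if gene.insilico_overrides else ""
    if bp7_call is not None and bp7_call.applied:
        return unapplied_call(
            Criterion.PP3, "BP7 applies; PP3/BP4 withheld [PP34:bp7_exclusive]"
        )
    if v.consequence == Consequence.missense:
        if scores.revel is None:
            return unapplied_call(
                Criterion.PP3, "no REVEL score available [PP34:missing_scores]"
            )
        splice_note = ""
        if scores.spliceai_delta is not None and scores.spliceai_delta >= 0.8:
            # the missense (REVEL) clause is preferred; log the tension
            splice_note = " (note: SpliceAI also high; missense clause preferred)"
        if scores.revel > thresholds.revel_pathogenic:
            return applied_call(
                Criterion.PP3,
                Strength.P,
                f"REVEL {scores.revel:g} > {thresholds.revel_pathogenic:g} "
                f"[PP3:revel]{override_note}{splice_note}",
                score=scores.revel,
            )
        if scores.revel < thresholds.revel_benign:
            return applied_call(
                Criterion.BP4,
                Strength.P,
                f"REVEL {scores.revel:g} < {thresholds.revel_benign:g} "
                f"[BP4:revel]{override_note}{splice_note}",
                score=scores.revel,
            )
        return None
    if v.consequence in NULL_CONSEQUENCES:
        return None
    if scores.spliceai_delta is None:
        return unapplied_call(
            Criterion.PP3, "no SpliceAI score available [PP34:missing_scores]"
        )
    if scores.spliceai_delta >= thresholds.spliceai_pathogenic:
        return applied_call(
            Criterion.PP3,
            Strength.P,
            f"SpliceAI delta {scores.spliceai_delta:g} >= "
            f"{thresholds.spliceai_pathogenic:g} [PP3:spliceai]{override_note}",
            score=scores.spliceai_delta,
        )
    if scores.spliceai_delta <= thresholds.spliceai_benign:
        return applied_call(
            Criterion.BP4,
            Strength.P,
            f"SpliceAI delta {scores.spliceai_delta:g} <= "
            f"{thresholds.spliceai_benign:g} [BP4:spliceai]{override_note}",
            score=scores.spliceai_delta,
        )
    return None


def evaluate_ps3_bs3(func: FunctionalAssayEvidence) -> Optional[CriterionCall]:
    """Pass curated functional-assay strength through as PS3 or BS3.

    Assay validation and strength assignment happen upstream; the engine
    only enforces direction exclusivity and rejects proband-derived
    evidence in the damaging direction (patient-derived findings belong
    with the phenotype criterion PP4 instead).
    """
    if func.direction == AssayDirection.none:
        return None
    assert func.strength is not None
    if func.direction == AssayDirection.damaging:
        if func.proband_derived:
            return unapplied_call(
                Criterion.PS3,
                "proband-derived functional assay rejected for PS3; consider PP4 "
                "[PS3:proband_rejected]",
            )
        return applied_call(
            Criterion.PS3,
            func.strength,
            "curated damaging functional assay [PS3:passthrough]",
        )
    return applied_call(
        Criterion.BS3,
        func.strength,
        "curated benign functional assay [BS3:passthrough]",
    )


def discontinued_criteria() -> list[CriterionCall]:
    """PP5 and BP6 are discontinued; kept unapplied for audit completeness."""
    return [
        unapplied_call(Criterion.PP5, "criterion discontinued [PP5:discontinued]"),
        unapplied_call(Criterion.BP6, "criterion discontinued [BP6:discontinued]"),
    ]
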