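"""Case-level criteria.

Proband-counting scoring systems (PM3 for recessive in-trans
observations, PS2/PM6 for confirmed/assumed de novo events), PS4 proband
counting and case-control evidence, PP1 meiosis counting, PP4 specific
phenotype, BS2 healthy carriers, BS4 non-segregation and BP5 alternate
molecular cause.  BP2 is never asserted.

The three scoring systems share the threshold ladder
SS >= 0.5 -> supporting, >= 1 -> moderate, >= 2 -> strong,
>= 4 -> very strong, and every SS is a plain sum of per-observation
scores (additivity is the contract the property tests check).
"""

from __future__ import annotations

from typing import NamedTuple, Optional

from .model import (
    CaseLevelData,
    Criterion,
    CriterionCall,
    DeNovoObservation,
    DOMINANT_GROUP,
    GeneCategory,
    GeneContext,
    Inheritance,
    PhenotypeMatch,
    RECESSIVE_CASE_GROUP,
    RecessiveObservation,
    RecessivePhase,
    Strength,
    applied_call,
    unapplied_call,
)

#: Shared SS ladder for PM3 / PM6 / PS2.
SS_LADDER: tuple[tuple[float, Strength], ...] = (
    (4.0, Strength.VS),
    (2.0, Strength.S),
    (1.0, Strength.M),
    (0.5, Strength.P),
)

#: Per-observation PM3 scores.
PM3_SCORES = {
    "in_trans": 1.0,
    "phase_unknown": 0.5,
    "homozygous": 0.5,
    "homozygous_consanguineous": 0.25,
}

#: Per-observation de novo scores by phenotype class:
#: confirmed parentage counts toward PS2, assumed toward PM6.
PS2_SCORES = {
    PhenotypeMatch.highly_specific: 2.0,
    PhenotypeMatch.consistent: 1.0,
    PhenotypeMatch.consistent_high_heterogeneity: 0.5,
    PhenotypeMatch.inconsistent: 0.0,
}
PM6_SCORES = {
    PhenotypeMatch.highly_specific: 1.0,
    PhenotypeMatch.consistent: 0.5,
    PhenotypeMatch.consistent_high_heterogeneity: 0.25,
    PhenotypeMatch.inconsistent: 0.0,
}

#: PP1 meiosis ladders: (supporting range, moderate range, strong floor).
PP1_DOMINANT = ((3, 4), (5, 6), 7)
PP1_RECESSIVE = ((1, 1), (2, 2), 3)

#: PS4 proband-count ladders by gene category.
PS4_CANCER = ((2, 5), (6, 9), 10)
PS4_GENERAL = ((1, 2), (3, 4), 5)

PS4_MIN_ODDS_RATIO = 5.0


def ss_strength(ss: float) -> Optional[Strength]:
    for floor, strength in SS_LADDER:
        if ss >= floor:
            return strength
    return None


# ---------------------------------------------------------------------------
# PM3
# ---------------------------------------------------------------------------

def recessive_observation_score(obs: RecessiveObservation) -> float:
    if obs.phase == RecessivePhase.in_trans_with_PLP:
        return PM3_SCORES["in_trans"]
    if obs.phase == RecessivePhase.phase_unknown:
        return PM3_SCORES["phase_unknown"]
    if obs.consanguineous:
        return PM3_SCORES["homozygous_consanguineous"]
    return PM3_SCORES["homozygous"]


def _obs_tag(obs: RecessiveObservation) -> str:
    if obs.phase == RecessivePhase.in_trans_with_PLP:
        return "PM3:in_trans"
    if obs.phase == RecessivePhase.phase_unknown:
        return "PM3:phase_unknown"
    return "PM3:hom_consang" if obs.consanguineous else "PM3:hom"


def score_pm3(
    obs: list[RecessiveObservation], inheritance: Inheritance = Inheritance.AR
) -> tuple[float, Optional[CriterionCall]]:
    """In-trans scoring system for recessive conditions.

    Per unrelated affected individual: 1.0 in trans with a known P/LP
    variant, 0.5 phase unknown, 0.5 homozygous (0.25 with consanguineous
    parents).  Only genes with a recessive component qualify.
    """
    if inheritance not in RECESSIVE_CASE_GROUP:
        if obs:
            return 0.0, unapplied_call(
                Criterion.PM3,
                f"inheritance {inheritance.value} has no recessive component "
                "[PM3:not_recessive]",
            )
        return 0.0, None
    ss = sum(recessive_observation_score(o) for o in obs)
    strength = ss_strength(ss)
    if strength is None:
        return ss, None
    tags = " ".join(sorted({f"[{_obs_tag(o)}]" for o in obs}))
    return ss, applied_call(
        Criterion.PM3,
        strength,
        f"in-trans scoring system SS={ss:g} over {len(obs)} observation(s) {tags}",
        score=ss,
    )


# ---------------------------------------------------------------------------
# PS2 / PM6
# ---------------------------------------------------------------------------

class DeNovoScores(NamedTuple):
    ps2_ss: float
    ps2_call: Optional[CriterionCall]
    pm6_ss: float
    pm6_call: Optional[CriterionCall]


_PHENOTYPE_TAG = {
    PhenotypeMatch.highly_specific: "highly_specific",
    PhenotypeMatch.consistent: "consistent",
    PhenotypeMatch.consistent_high_heterogeneity: "consistent_hetero",
    PhenotypeMatch.inconsistent: "inconsistent",
}


def score_de_novo(obs: list[DeNovoObservation]) -> DeNovoScores:
    """De novo scoring: confirmed events feed PS2, assumed events PM6.

    Both calls may be emitted for mixed cohorts; the classifier's caution
    policy caps how many of the overlapping criteria count.
    """

    def pool(confirmed: bool, scores: dict, criterion: Criterion):
        sel = [o for o in obs if o.confirmed == confirmed]
        ss = sum(scores[o.phenotype_match] for o in sel)
        strength = ss_strength(ss)
        if strength is None:
            return ss, None
        prefix = criterion.value
        tags = " ".join(
            sorted({f"[{prefix}:{_PHENOTYPE_TAG[o.phenotype_match]}]" for o in sel})
        )
        label = "confirmed" if confirmed else "assumed"
        return ss, applied_call(
            criterion,
            strength,
            f"{label} de novo scoring SS={ss:g} over {len(sel)} observation(s) {tags}",
            score=ss,
        )

    ps2_ss, ps2_call = pool(True, PS2_SCORES, Criterion.PS2)
    pm6_ss, pm6_call = pool(False, PM6_SCORES, Criterion.PM6)
    return DeNovoScores(ps2_ss, ps2_call, pm6_ss, pm6_call)


# ---------------------------------------------------------------------------
# PP1
# ---------------------------------------------------------------------------

def score_pp1(meioses: int, inheritance: Inheritance) -> Optional[CriterionCall]:
    """Co-segregation meiosis counting.

    Dominant conditions (AD, AD/AR on the AD side, XLD): supporting for
    3-4 meioses, moderate 5-6, strong >= 7.  Recessive-group conditions:
    supporting 1, moderate 2, strong >= 3.
    """
    if meioses < 0:
        raise ValueError("meioses must be nonnegative")
    if inheritance in (Inheritance.AD, Inheritance.XLD):
        ladder, tag = PP1_DOMINANT, "PP1:ad_tier"
    else:
        ladder, tag = PP1_RECESSIVE, "PP1:ar_tier"
    (p_lo, p_hi), (m_lo, m_hi), s_floor = ladder
    if meioses >= s_floor:
        strength = Strength.S
    elif m_lo <= meioses <= m_hi:
        strength = Strength.M
    elif p_lo <= meioses <= p_hi:
        strength = Strength.P
    else:
        return None
    return applied_call(
        Criterion.PP1,
        strength,
        f"variant segregates with {meioses} meioses [{tag}]",
        score=float(meioses),
    )


# ---------------------------------------------------------------------------
# PS4
# ---------------------------------------------------------------------------

def evaluate_ps4(
    data: CaseLevelData,
    gene: GeneContext,
    pm2_call: Optional[CriterionCall],
) -> Optional[CriterionCall]:
    """Prevalence in affected individuals.

    Strong outright for a qualifying case-control study (OR > 5, CI
    excluding 1), a known founder variant, or a VCEP-curated pathogenic
    variant.  Otherwise probands are counted, but only for dominant
    conditions on variants rare enough to meet PM2 at either weight.
    """
    cc = data.case_control
    if cc is not None and cc.odds_ratio > PS4_MIN_ODDS_RATIO and cc.ci_low > 1:
        return applied_call(
            Criterion.PS4,
            Strength.S,
            f"case-control OR {cc.odds_ratio:g} > 5 with CI excluding 1 "
            "[PS4:case_control]",
        )
    if data.founder_variant:
        return applied_call(
            Criterion.PS4, Strength.S, "known founder variant [PS4:founder]"
        )
    if data.vcep_pathogenic:
        return applied_call(
            Criterion.PS4,
            Strength.S,
            "curated as pathogenic by a recognized expert panel [PS4:vcep]",
        )
    if data.proband_count == 0:
        return None
    pm2_met = (
        pm2_call is not None and pm2_call.applied and pm2_call.criterion == Criterion.PM2
    )
    if not pm2_met or gene.inheritance not in DOMINANT_GROUP:
        return unapplied_call(
            Criterion.PS4,
            "proband counting requires a dominant condition and PM2 at either "
            "weight [PS4:counting_blocked]",
        )
    if gene.category == GeneCategory.cancer:
        ladder, tag = PS4_CANCER, "PS4:probands_cancer"
    else:
        ladder, tag = PS4_GENERAL, "PS4:probands_general"
    (p_lo, p_hi), (m_lo, m_hi), s_floor = ladder
    n = data.proband_count
    if n >= s_floor:
        strength = Strength.S
    elif m_lo <= n <= m_hi:
        strength = Strength.M
    elif p_lo <= n <= p_hi:
        strength = Strength.P
    else:
        return None
    return applied_call(
        Criterion.PS4,
        strength,
        f"{n} previously described unrelated proband(s) [{tag}]",
        score=float(n),
    )


# ---------------------------------------------------------------------------
# BS2
# ---------------------------------------------------------------------------

def evaluate_bs2(data: CaseLevelData, gene: GeneContext) -> Optional[CriterionCall]:
    """Healthy individuals carrying the variant, by inheritance context."""
    counts = data.healthy_carrier_counts
    if data.in_house_positive_genotype_no_phenotype and gene.high_penetrance_early_onset:
        return applied_call(
            Criterion.BS2,
            Strength.S,
            "in-house positive genotype without phenotype for a high-penetrance, "
            "early-onset condition [BS2:in_house]",
        )
    if gene.category == GeneCategory.cancer and counts.hom >= 1:
        return applied_call(
            Criterion.BS2,
            Strength.S,
            "homozygote in control databases for a cancer gene [BS2:cancer_hom]",
        )
    if (
        gene.inheritance in (Inheritance.AR, Inheritance.AD_AR)
        and gene.complete_penetrance
        and counts.hom >= 1
    ):
        return applied_call(
            Criterion.BS2,
            Strength.S,
            "homozygote in controls for a complete-penetrance recessive disease "
            "[BS2:recessive_hom]",
        )
    if (
        gene.inheritance == Inheritance.AD
        and gene.pediatric_green_list
        and counts.total_alleles >= 5
    ):
        return applied_call(
            Criterion.BS2,
            Strength.S,
            f"{counts.total_alleles} control alleles for a green-list pediatric "
            "dominant gene [BS2:green_list]",
        )
    if gene.inheritance in (Inheritance.XL, Inheritance.XLR) and (
        counts.hemi >= 1 or counts.hom >= 1
    ):
        return applied_call(
            Criterion.BS2,
            Strength.S,
            "hemizygote or homozygote in controls for an X-linked recessive gene "
            "[BS2:xl_hemi]",
        )
    if gene.inheritance == Inheritance.XLD and counts.het >= 5:
        return applied_call(
            Criterion.BS2,
            Strength.S,
            f"{counts.het} heterozygous control subjects for an XLD gene [BS2:xld_het]",
        )
    return None


# ---------------------------------------------------------------------------
# BS4 / PP4 / BP5 / BP2
# ---------------------------------------------------------------------------

def evaluate_bs4(data: CaseLevelData, gene: GeneContext) -> Optional[CriterionCall]:
    """Non-segregation, restricted to high-penetrance early-onset conditions."""
    if data.nonsegregation_observed and gene.high_penetrance_early_onset:
        return applied_call(
            Criterion.BS4,
            Strength.S,
            "affected family member lacks the genotype in a high-penetrance, "
            "early-onset condition [BS4:met]",
        )
    return None


def evaluate_pp4(
    data: CaseLevelData, pm2_call: Optional[CriterionCall]
) -> Optional[CriterionCall]:
    """Phenotype highly specific for a single-etiology disease.

    Requires a comprehensive test, a rare variant (PM2 at either weight),
    a consistent family history and the specific phenotype; upgraded to
    strong with pathognomonic extra evidence.
    """
    pm2_met = (
        pm2_call is not None and pm2_call.applied and pm2_call.criterion == Criterion.PM2
    )
    if not (
        data.comprehensive_test
        and pm2_met
        and data.family_history_consistent
        and data.phenotype_specific_single_etiology
    ):
        return None
    if data.pathognomonic_extra_evidence:
        return applied_call(
            Criterion.PP4,
            Strength.S,
            "specific phenotype with pathognomonic additional evidence [PP4:upgrade]",
        )
    return applied_call(
        Criterion.PP4,
        Strength.P,
        "comprehensive test, rare variant, consistent family history and "
        "single-etiology phenotype [PP4:base]",
    )


def evaluate_bp5(data: CaseLevelData, gene: GeneContext) -> Optional[CriterionCall]:
    """Alternate molecular cause, AD highly penetrant childhood-onset only."""
    if (
        data.alternate_molecular_cause
        and data.variant_noncontributory
        and gene.ad_highly_penetrant_childhood_onset
        and gene.inheritance in (Inheritance.AD, Inheritance.AD_AR)
    ):
        return applied_call(
            Criterion.BP5,
            Strength.P,
            "clear alternate molecular cause; variant deemed non-contributory "
            "[BP5:met]",
        )
    return None


def unapplied_bp2() -> CriterionCall:
    """BP2 is never asserted; recurrent variants can have atypical phenotypes."""
    return unapplied_call(
        Criterion.BP2,
        "not applied: presence in cis/trans with a pathogenic variant is not "
        "treated as evidence of benignity [BP2:not_applied]",
    )
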