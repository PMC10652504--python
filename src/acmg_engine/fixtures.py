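"""Synthetic evidence fixtures.

``gold_fixture_set`` builds hand-written evidence records, one or more per
criterion clause and per combining rule, each with its expected applied
calls and expected tier; the suite asserts that running the engine over
the set reproduces every expectation and touches every clause tag in
``CLAUSE_TAGS``.  ``random_cohort`` generates reproducible randomized
cohorts in which configured clauses fire with given prevalences, for
property tests.

All records are synthetic: gene symbols, frequencies and case
observations are constructed to exercise rule branches, not to describe
real genes or populations.
"""

from __future__ import annotations

import json
import random
import re
from pathlib import Path
from typing import Any, Callable, Optional, Union

from pydantic import BaseModel, Field

from .classifier import RecordStatus, Tier
from .model import (
    AssayDirection,
    CaseControlStudy,
    CaseLevelData,
    ClinicalValidity,
    Consequence,
    Criterion,
    DeNovoObservation,
    EvidenceRecord,
    FrequencyRecord,
    FrequencyThresholds,
    FunctionalAssayEvidence,
    GeneCategory,
    GeneContext,
    HealthyCarrierCounts,
    Inheritance,
    InsilicoThresholds,
    InSilicoScores,
    PhenotypeMatch,
    PriorClassification,
    PriorClassifiedVariant,
    RecessiveObservation,
    RecessivePhase,
    SpecialDomain,
    Strength,
    VariantDescriptor,
)

# ---------------------------------------------------------------------------
# Clause-tag registry (branch-coverage contract)
# ---------------------------------------------------------------------------

#: Every clause tag the criterion modules can emit into a rationale.
#: The gold set must touch all of them.
CLAUSE_TAGS: frozenset[str] = frozenset(
    {
        "BA1:threshold", "BS1:threshold", "PM2:absent", "PM2:below_m",
        "PM2:below_p", "PM2:insufficient_data", "THR:gene_override",
        "PVS1:nmd_null", "PVS1:last_exon_critical", "PVS1:last_exon",
        "PVS1:splice_inframe_critical", "PVS1:splice_inframe",
        "PVS1:splice_nmd", "PVS1:splice_no_nmd_critical", "PVS1:splice_no_nmd",
        "PVS1:initiation", "PVS1:exon_del_nmd", "PVS1:exon_del_critical",
        "PVS1:exon_del", "PVS1:lof_not_established",
        "PS1:pathogenic", "PS1:lp_multi", "PS1:lp_single",
        "PM5:pathogenic", "PM5:lp_multi", "PM5:lp_single",
        "PS1PM5:splice_suppressed",
        "PM1:notch3", "PM1:collagen", "PM1:zinc_finger", "PM1:decipher",
        "PM1:hotspot",
        "PM4:stop_loss", "PM4:small_indel", "PM4:large_indel",
        "PM4:repeat_blocked", "PM4:rarity_blocked",
        "PP2:met", "BP7:met", "BP7:missing_scores",
        "BP1:not_applied", "BP3:not_applied", "BP2:not_applied",
        "PM3:in_trans", "PM3:phase_unknown", "PM3:hom", "PM3:hom_consang",
        "PM3:not_recessive",
        "PS2:highly_specific", "PS2:consistent", "PS2:consistent_hetero",
        "PM6:highly_specific", "PM6:consistent", "PM6:consistent_hetero",
        "PP1:ad_tier", "PP1:ar_tier",
        "PS4:case_control", "PS4:founder", "PS4:vcep",
        "PS4:probands_cancer", "PS4:probands_general", "PS4:counting_blocked",
        "BS2:in_house", "BS2:cancer_hom", "BS2:recessive_hom",
        "BS2:green_list", "BS2:xl_hemi", "BS2:xld_het",
        "BS4:met", "PP4:base", "PP4:upgrade", "BP5:met",
        "PS3:passthrough", "PS3:proband_rejected", "BS3:passthrough",
        "PP3:revel", "PP3:spliceai", "BP4:revel", "BP4:spliceai",
        "PP34:bp7_exclusive", "PP34:missing_scores", "THR:insilico_override",
        "PP5:discontinued", "BP6:discontinued",
    }
)

_TAG_RE = re.compile(r"\[([A-Za-z0-9]+:[a-z_0-9]+)\]")


def extract_clause_tags(rationales: list[str]) -> set[str]:
    tags: set[str] = set()
    for text in rationales:
        tags.update(_TAG_RE.findall(text))
    return tags


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def make_gene(symbol: str = "GENE1", **kw: Any) -> GeneContext:
    defaults: dict[str, Any] = {
        "symbol": symbol,
        "inheritance": Inheritance.AD,
        "category": GeneCategory.general,
        "clinical_validity": ClinicalValidity.definitive,
    }
    defaults.update(kw)
    return GeneContext.model_validate(defaults)


def lof_gene(symbol: str = "LOFGENE", **kw: Any) -> GeneContext:
    kw.setdefault("pli", 0.99)
    return make_gene(symbol, **kw)


def freqs_at(frequency: float, an: int = 100_000) -> list[FrequencyRecord]:
    ac = round(frequency * an)
    return [FrequencyRecord(population="overall", allele_count=ac, allele_number=an)]


def absent_freqs(an: int = 100_000) -> list[FrequencyRecord]:
    return [FrequencyRecord(population="overall", allele_count=0, allele_number=an)]


#: Frequency high enough to clear PM2 in every built-in row yet far below
#: BS1 in every row (5e-4 with AC >= 5: no call anywhere).
def neutral_freqs() -> list[FrequencyRecord]:
    return [FrequencyRecord(population="overall", allele_count=50, allele_number=100_000)]


def missense(codon: int = 100, ref: str = "A", alt: str = "V", **kw: Any) -> VariantDescriptor:
    return VariantDescriptor(
        consequence=Consequence.missense, codon_index=codon, ref_aa=ref, alt_aa=alt, **kw
    )


def null_variant(consequence: Consequence, **kw: Any) -> VariantDescriptor:
    return VariantDescriptor(consequence=consequence, **kw)


def prior(
    codon: int = 100,
    alt: str = "V",
    equivalent: bool = True,
    classification: PriorClassification = PriorClassification.pathogenic,
    reports: int = 1,
) -> PriorClassifiedVariant:
    return PriorClassifiedVariant(
        codon_index=codon,
        alt_aa=alt,
        protein_change_equivalent=equivalent,
        classification=classification,
        independent_report_count=reports,
    )


class GoldFixture(BaseModel):
    """One synthetic record with its expected engine behavior."""

    name: str
    record: EvidenceRecord
    expected_status: RecordStatus = RecordStatus.classified
    #: labels of the applied calls after conflict resolution, e.g. PVS1_VS
    expected_applied: list[str] = Field(default_factory=list)
    expected_tier: Optional[Tier] = None
    expected_rule: Optional[str] = None


def _fx(
    name: str,
    expected_applied: list[str],
    expected_tier: Optional[Tier],
    expected_rule: Optional[str] = None,
    expected_status: RecordStatus = RecordStatus.classified,
    **record_kw: Any,
) -> GoldFixture:
    record_kw.setdefault("id", name)
    record_kw.setdefault("variant", missense())
    record_kw.setdefault("gene", make_gene())
    record_kw.setdefault("frequencies", neutral_freqs())
    return GoldFixture(
        name=name,
        record=EvidenceRecord.model_validate(record_kw),
        expected_status=expected_status,
        expected_applied=sorted(expected_applied),
        expected_tier=expected_tier,
        expected_rule=expected_rule,
    )


# ---------------------------------------------------------------------------
# Gold fixture set
# ---------------------------------------------------------------------------

def gold_fixture_set() -> list[GoldFixture]:  # noqa: C901 (deliberately linear)
    """Hand-built records exercising every clause and combining rule."""
    LP, P, B, LB, VUS = (
        Tier.likely_pathogenic,
        Tier.pathogenic,
        Tier.benign,
        Tier.likely_benign,
        Tier.VUS,
    )
    fx: list[GoldFixture] = []
    add = fx.append

    # -- population frequency -------------------------------------------
    add(_fx("pop_ba1_standalone", ["BA1_A"], B, "1A", frequencies=freqs_at(0.06)))
    add(
        _fx(
            "pop_bs1_with_bp4", ["BS1_S", "BP4_P"], LB, "2A",
            frequencies=freqs_at(0.002),
            insilico=InSilicoScores(revel=0.35),
        )
    )
    add(_fx("pop_pm2_absent_dominant", ["PM2_M"], VUS, frequencies=absent_freqs()))
    add(
        _fx(
            "pop_pm2_low_freq_recessive", ["PM2_M"], VUS,
            gene=make_gene("ARGENE", inheritance=Inheritance.AR),
            frequencies=[
                FrequencyRecord(population="overall", allele_count=1, allele_number=300_000)
            ],
        )
    )
    add(
        _fx(
            "pop_pm2_supporting_cancer", ["PM2_P"], VUS,
            gene=make_gene("CANAR", category=GeneCategory.cancer, inheritance=Inheritance.AR),
            frequencies=freqs_at(0.0003),
        )
    )
    add(
        _fx(
            "pop_insufficient_data", [], VUS,
            frequencies=[
                FrequencyRecord(population="AFR", allele_count=1, allele_number=1500)
            ],
        )
    )
    add(
        _fx(
            "pop_exception_gene_override", ["BS1_S"], VUS,
            gene=make_gene(
                "EXCGENE",
                ba1_exception=True,
                frequency_overrides=FrequencyThresholds(
                    ba1=0.10, bs1_s=0.01, pm2_p=0.0001, pm2_m=0.00001
                ),
            ),
            frequencies=freqs_at(0.06),
        )
    )

    # -- PVS1 decision table ---------------------------------------------
    def pvs1(name: str, variant: VariantDescriptor, applied: list[str],
             tier: Tier, rule: Optional[str] = None, **kw: Any) -> None:
        kw.setdefault("gene", lof_gene())
        add(_fx(name, applied, tier, rule, variant=variant, **kw))

    add(
        _fx(
            "pvs1_nmd_nonsense_absent", ["PVS1_VS", "PM2_M"], LP, "3A",
            gene=lof_gene(),
            variant=null_variant(Consequence.nonsense, nmd_predicted=True),
            frequencies=absent_freqs(),
        )
    )
    add(
        _fx(
            "pvs1_with_pm2_supporting", ["PVS1_VS", "PM2_P"], LP, "3B",
            gene=lof_gene("CANLOF", category=GeneCategory.cancer, inheritance=Inheritance.AR),
            variant=null_variant(Consequence.nonsense, nmd_predicted=True),
            frequencies=freqs_at(0.0003),
        )
    )
    pvs1(
        "pvs1_last_exon_critical",
        null_variant(Consequence.nonsense, nmd_predicted=False, affected_region_critical=True),
        ["PVS1_S", "PM2_M"], LP, "3C", frequencies=absent_freqs(),
    )
    pvs1(
        "pvs1_last_exon_noncritical",
        null_variant(Consequence.frameshift, nmd_predicted=False),
        ["PVS1_M", "PM2_M"], VUS, frequencies=absent_freqs(),
    )
    pvs1(
        "pvs1_splice_nmd",
        null_variant(Consequence.canonical_splice, nmd_predicted=True),
        ["PVS1_VS"], VUS,
    )
    pvs1(
        "pvs1_splice_no_nmd_critical",
        null_variant(
            Consequence.canonical_splice, nmd_predicted=False, affected_region_critical=True
        ),
        ["PVS1_S"], VUS,
    )
    pvs1(
        "pvs1_splice_no_nmd",
        null_variant(Consequence.canonical_splice, nmd_predicted=False),
        ["PVS1_M"], VUS,
    )
    pvs1(
        "pvs1_splice_inframe_critical",
        null_variant(
            Consequence.canonical_splice,
            nmd_predicted=False,
            exon_skip_inframe=True,
            affected_region_critical=True,
        ),
        ["PVS1_S"], VUS,
    )
    pvs1(
        "pvs1_splice_inframe",
        null_variant(
            Consequence.canonical_splice, nmd_predicted=False, exon_skip_inframe=True
        ),
        ["PVS1_P"], VUS,
    )
    pvs1(
        "pvs1_initiation_codon",
        null_variant(Consequence.initiation_codon),
        ["PVS1_M"], VUS,
    )
    pvs1(
        "pvs1_exon_deletion_nmd",
        null_variant(Consequence.single_multi_exon_deletion, nmd_predicted=True),
        ["PVS1_VS"], VUS,
    )
    pvs1(
        "pvs1_exon_deletion_critical",
        null_variant(
            Consequence.single_multi_exon_deletion,
            nmd_predicted=False,
            affected_region_critical=True,
        ),
        ["PVS1_S"], VUS,
    )
    pvs1(
        "pvs1_exon_deletion",
        null_variant(Consequence.single_multi_exon_deletion, nmd_predicted=False),
        ["PVS1_M"], VUS,
    )
    add(
        _fx(
            "pvs1_lof_not_established", ["PM2_M"], VUS,
            gene=make_gene("NOLOF", pli=0.2, o_e=0.8),
            variant=null_variant(Consequence.nonsense, nmd_predicted=True),
            frequencies=absent_freqs(),
        )
    )

    # -- PS1 / PM5 --------------------------------------------------------
    add(_fx("ps1_pathogenic_prior", ["PS1_S"], VUS, prior_variants=[prior()]))
    add(
        _fx(
            "ps1_lp_two_reports", ["PS1_S"], VUS,
            prior_variants=[
                prior(classification=PriorClassification.likely_pathogenic, reports=2)
            ],
        )
    )
    add(
        _fx(
            "ps1_lp_single_report", ["PS1_M"], VUS,
            prior_variants=[
                prior(classification=PriorClassification.likely_pathogenic, reports=1)
            ],
        )
    )
    add(
        _fx(
            "pm5_pathogenic_prior", ["PM5_M"], VUS,
            prior_variants=[prior(alt="W", equivalent=False)],
        )
    )
    add(
        _fx(
            "pm5_lp_two_reports", ["PM5_M"], VUS,
            prior_variants=[
                prior(
                    alt="W",
                    equivalent=False,
                    classification=PriorClassification.likely_pathogenic,
                    reports=2,
                )
            ],
        )
    )
    add(
        _fx(
            "pm5_lp_single_report", ["PM5_P"], VUS,
            prior_variants=[
                prior(
                    alt="W",
                    equivalent=False,
                    classification=PriorClassification.likely_pathogenic,
                    reports=1,
                )
            ],
        )
    )
    add(
        _fx(
            "ps1_splice_suppressed", [], VUS,
            prior_variants=[prior()],
            insilico=InSilicoScores(spliceai_delta=0.9),
        )
    )

    # -- PM1 --------------------------------------------------------------
    add(
        _fx(
            "pm1_collagen_glycine", ["PM1_S"], VUS,
            gene=make_gene("COLGENE", special_domain_class=SpecialDomain.collagen_glycine),
            variant=missense(ref="G", alt="S"),
        )
    )
    add(
        _fx(
            "pm1_notch3_cysteine", ["PM1_S"], VUS,
            gene=make_gene("EGFGENE", special_domain_class=SpecialDomain.notch3_egf),
            variant=missense(ref="C", alt="R", cysteine_parity_change=True),
        )
    )
    add(
        _fx(
            "pm1_zinc_finger", ["PM1_S"], VUS,
            gene=make_gene("ZNFGENE", special_domain_class=SpecialDomain.c2h4_zinc_finger),
            variant=missense(ref="H", alt="Y"),
        )
    )
    add(
        _fx(
            "pm1_decipher_constraint", ["PM1_M"], VUS,
            gene=make_gene("CONGENE", decipher_missense_constraint=0.3),
        )
    )
    add(
        _fx(
            "pm1_literature_hotspot", ["PM1_M"], VUS,
            gene=make_gene("HOTGENE", hotspot_codon_ranges=[(90, 110)]),
        )
    )

    # -- PM4 --------------------------------------------------------------
    add(
        _fx(
            "pm4_small_indel", ["PM4_P", "PM2_M"], VUS,
            variant=VariantDescriptor(consequence=Consequence.inframe_indel, indel_aa_length=2),
            frequencies=absent_freqs(),
        )
    )
    add(
        _fx(
            "pm4_large_indel", ["PM4_M", "PM2_P"], VUS,
            gene=make_gene("ARGENE", inheritance=Inheritance.AR),
            variant=VariantDescriptor(consequence=Consequence.inframe_indel, indel_aa_length=5),
            frequencies=freqs_at(0.00005),
        )
    )
    add(
        _fx(
            "pm4_stop_loss", ["PM4_M", "PM2_M"], VUS,
            variant=VariantDescriptor(consequence=Consequence.stop_loss),
            frequencies=absent_freqs(),
        )
    )
    add(
        _fx(
            "pm4_repeat_region_blocked", ["PM2_M"], VUS,
            variant=VariantDescriptor(
                consequence=Consequence.inframe_indel, indel_aa_length=5, in_repeat_region=True
            ),
            frequencies=absent_freqs(),
        )
    )
    add(
        _fx(
            "pm4_rarity_blocked", [], VUS,
            variant=VariantDescriptor(consequence=Consequence.inframe_indel, indel_aa_length=2),
        )
    )

    # -- PP2 / BP7 --------------------------------------------------------
    add(
        _fx(
            "pp2_constrained_gene", ["PP2_P"], VUS,
            gene=make_gene("MISGENE", pathogenic_missense_count=5, missense_constraint_z=3.5),
        )
    )
    add(
        _fx(
            "bp7_silent_with_bs1", ["BP7_P", "BS1_S"], LB, "2A",
            variant=VariantDescriptor(consequence=Consequence.synonymous),
            insilico=InSilicoScores(spliceai_delta=0.05, gerp=-1.2),
            frequencies=freqs_at(0.002),
        )
    )
    add(
        _fx(
            "bp7_missing_gerp", ["BP4_P"], VUS,
            variant=VariantDescriptor(consequence=Consequence.synonymous),
            insilico=InSilicoScores(spliceai_delta=0.05),
        )
    )

    # -- PM3 --------------------------------------------------------------
    ar_gene = make_gene("ARGENE", inheritance=Inheritance.AR)
    add(
        _fx(
            "pm3_one_in_trans", ["PM3_M"], VUS,
            gene=ar_gene,
            case_data=CaseLevelData(
                recessive_obs=[RecessiveObservation(phase=RecessivePhase.in_trans_with_PLP)]
            ),
        )
    )
    add(
        _fx(
            "pm3_very_strong", ["PM3_VS"], VUS,
            gene=ar_gene,
            case_data=CaseLevelData(
                recessive_obs=[RecessiveObservation(phase=RecessivePhase.in_trans_with_PLP)] * 3
                + [RecessiveObservation(phase=RecessivePhase.homozygous)] * 2
            ),
        )
    )
    add(
        _fx(
            "pm3_supporting_mix", ["PM3_P"], VUS,
            gene=ar_gene,
            case_data=CaseLevelData(
                recessive_obs=[
                    RecessiveObservation(phase=RecessivePhase.phase_unknown),
                    RecessiveObservation(
                        phase=RecessivePhase.homozygous, consanguineous=True
                    ),
                ]
            ),
        )
    )
    add(
        _fx(
            "pm3_dominant_blocked", [], VUS,
            case_data=CaseLevelData(
                recessive_obs=[RecessiveObservation(phase=RecessivePhase.in_trans_with_PLP)] * 2
            ),
        )
    )

    # -- PS2 / PM6 --------------------------------------------------------
    add(
        _fx(
            "ps2_confirmed_specific", ["PS2_S"], VUS,
            case_data=CaseLevelData(
                denovo_obs=[
                    DeNovoObservation(
                        confirmed=True, phenotype_match=PhenotypeMatch.highly_specific
                    )
                ]
            ),
        )
    )
    add(
        _fx(
            "ps2_confirmed_mixed", ["PS2_M"], VUS,
            case_data=CaseLevelData(
                denovo_obs=[
                    DeNovoObservation(
                        confirmed=True, phenotype_match=PhenotypeMatch.consistent
                    ),
                    DeNovoObservation(
                        confirmed=True,
                        phenotype_match=PhenotypeMatch.consistent_high_heterogeneity,
                    ),
                ]
            ),
        )
    )
    add(
        _fx(
            "pm6_assumed_consistent", ["PM6_P"], VUS,
            case_data=CaseLevelData(
                denovo_obs=[
                    DeNovoObservation(
                        confirmed=False, phenotype_match=PhenotypeMatch.consistent
                    )
                ]
            ),
        )
    )
    add(
        _fx(
            "pm6_assumed_mixed", ["PM6_M"], VUS,
            case_data=CaseLevelData(
                denovo_obs=[
                    DeNovoObservation(
                        confirmed=False, phenotype_match=PhenotypeMatch.highly_specific
                    ),
                    DeNovoObservation(
                        confirmed=False,
                        phenotype_match=PhenotypeMatch.consistent_high_heterogeneity,
                    ),
                ]
            ),
        )
    )

    # -- PP1 --------------------------------------------------------------
    add(
        _fx(
            "pp1_dominant_strong", ["PP1_S"], VUS,
            case_data=CaseLevelData(segregating_meioses=7),
        )
    )
    add(
        _fx(
            "pp1_recessive_moderate", ["PP1_M"], VUS,
            gene=ar_gene,
            case_data=CaseLevelData(segregating_meioses=2),
        )
    )

    # -- PS4 --------------------------------------------------------------
    add(
        _fx(
            "ps4_case_control", ["PS4_S"], VUS,
            case_data=CaseLevelData(
                case_control=CaseControlStudy(odds_ratio=8.0, ci_low=1.4)
            ),
        )
    )
    add(
        _fx(
            "ps4_founder_variant", ["PS4_S"], VUS,
            case_data=CaseLevelData(founder_variant=True),
        )
    )
    add(
        _fx(
            "ps4_vcep_pathogenic", ["PS4_S"], VUS,
            case_data=CaseLevelData(vcep_pathogenic=True),
        )
    )
    add(
        _fx(
            "ps4_probands_cancer", ["PS4_M", "PM2_M"], VUS,
            gene=make_gene("CANAD", category=GeneCategory.cancer),
            case_data=CaseLevelData(proband_count=7),
            frequencies=absent_freqs(),
        )
    )
    add(
        _fx(
            "ps4_probands_general", ["PS4_S", "PM2_M"], LP, "3C",
            case_data=CaseLevelData(proband_count=5),
            frequencies=absent_freqs(),
        )
    )
    add(
        _fx(
            "ps4_counting_blocked", [], VUS,
            case_data=CaseLevelData(proband_count=6),
        )
    )

    # -- BS2 --------------------------------------------------------------
    add(
        _fx(
            "bs2_in_house_genotype", ["BS2_S"], VUS,
            gene=make_gene("PENGENE", high_penetrance_early_onset=True),
            case_data=CaseLevelData(in_house_positive_genotype_no_phenotype=True),
        )
    )
    add(
        _fx(
            "bs2_cancer_homozygote", ["BS2_S"], VUS,
            gene=make_gene("CANAD", category=GeneCategory.cancer),
            case_data=CaseLevelData(healthy_carrier_counts=HealthyCarrierCounts(hom=1)),
        )
    )
    add(
        _fx(
            "bs2_recessive_homozygote", ["BS2_S"], VUS,
            gene=make_gene("ARGENE", inheritance=Inheritance.AR, complete_penetrance=True),
            case_data=CaseLevelData(healthy_carrier_counts=HealthyCarrierCounts(hom=1)),
        )
    )
    add(
        _fx(
            "bs2_green_list_alleles", ["BS2_S"], VUS,
            gene=make_gene("GREEN", pediatric_green_list=True),
            case_data=CaseLevelData(healthy_carrier_counts=HealthyCarrierCounts(het=5)),
        )
    )
    add(
        _fx(
            "bs2_xl_hemizygote", ["BS2_S"], VUS,
            gene=make_gene("XLGENE", inheritance=Inheritance.XLR),
            case_data=CaseLevelData(healthy_carrier_counts=HealthyCarrierCounts(hemi=1)),
        )
    )
    add(
        _fx(
            "bs2_xld_heterozygotes", ["BS2_S"], VUS,
            gene=make_gene("XLDGENE", inheritance=Inheritance.XLD),
            case_data=CaseLevelData(healthy_carrier_counts=HealthyCarrierCounts(het=5)),
        )
    )

    # -- BS4 / PP4 / BP5 --------------------------------------------------
    add(
        _fx(
            "bs4_nonsegregation", ["BS4_S"], VUS,
            gene=make_gene("PENGENE", high_penetrance_early_onset=True),
            case_data=CaseLevelData(nonsegregation_observed=True),
        )
    )
    pp4_flags = dict(
        comprehensive_test=True,
        family_history_consistent=True,
        phenotype_specific_single_etiology=True,
    )
    add(
        _fx(
            "pp4_base", ["PP4_P", "PM2_M"], VUS,
            case_data=CaseLevelData(**pp4_flags),
            frequencies=absent_freqs(),
        )
    )
    add(
        _fx(
            "pp4_pathognomonic_upgrade", ["PP4_S", "PM2_M"], LP, "3C",
            case_data=CaseLevelData(**pp4_flags, pathognomonic_extra_evidence=True),
            frequencies=absent_freqs(),
        )
    )
    add(
        _fx(
            "bp5_alternate_cause", ["BP5_P"], VUS,
            gene=make_gene("CHILDAD", ad_highly_penetrant_childhood_onset=True),
            case_data=CaseLevelData(
                alternate_molecular_cause=True, variant_noncontributory=True
            ),
        )
    )

    # -- PS3 / BS3 --------------------------------------------------------
    add(
        _fx(
            "ps3_curated_strong", ["PS3_S"], VUS,
            functional=FunctionalAssayEvidence(
                direction=AssayDirection.damaging, strength=Strength.S
            ),
        )
    )
    add(
        _fx(
            "ps3_proband_rejected", [], VUS,
            functional=FunctionalAssayEvidence(
                direction=AssayDirection.damaging, strength=Strength.S, proband_derived=True
            ),
        )
    )
    add(
        _fx(
            "bs3_curated_moderate", ["BS3_M"], VUS,
            functional=FunctionalAssayEvidence(
                direction=AssayDirection.benign, strength=Strength.M
            ),
        )
    )

    # -- PP3 / BP4 --------------------------------------------------------
    add(_fx("pp3_revel_high", ["PP3_P"], VUS, insilico=InSilicoScores(revel=0.75)))
    add(
        _fx(
            "pp3_spliceai_noncoding", ["PP3_P"], VUS,
            variant=VariantDescriptor(consequence=Consequence.other),
            insilico=InSilicoScores(spliceai_delta=0.85),
        )
    )
    add(_fx("bp4_revel_low", ["BP4_P"], VUS, insilico=InSilicoScores(revel=0.35)))
    add(
        _fx(
            "bp4_spliceai_noncoding", ["BP4_P"], VUS,
            variant=VariantDescriptor(consequence=Consequence.other),
            insilico=InSilicoScores(spliceai_delta=0.1),
        )
    )
    add(
        _fx(
            "pp3_gene_specific_threshold", ["PP3_P"], VUS,
            gene=make_gene(
                "OVRGENE",
                insilico_overrides=InsilicoThresholds(revel_pathogenic=0.9),
            ),
            insilico=InSilicoScores(revel=0.95),
        )
    )

    # -- combining-rule demonstrations -----------------------------------
    add(
        _fx(
            "rule_1b_two_benign_strong", ["BS1_S", "BS2_S"], B, "1B",
            gene=make_gene("CANAD", category=GeneCategory.cancer),
            frequencies=freqs_at(0.002),
            case_data=CaseLevelData(healthy_carrier_counts=HealthyCarrierCounts(hom=1)),
        )
    )
    add(
        _fx(
            "rule_2b_two_benign_supporting", ["BP4_P", "BP5_P"], LB, "2B",
            gene=make_gene("CHILDAD", ad_highly_penetrant_childhood_onset=True),
            insilico=InSilicoScores(revel=0.35),
            case_data=CaseLevelData(
                alternate_molecular_cause=True, variant_noncontributory=True
            ),
        )
    )
    pp2_gene_kw = dict(pathogenic_missense_count=5, missense_constraint_z=3.5)
    add(
        _fx(
            "rule_3d_strong_two_supporting", ["PS3_S", "PP3_P", "PP2_P"], LP, "3D",
            gene=make_gene("MISGENE", **pp2_gene_kw),
            insilico=InSilicoScores(revel=0.75),
            functional=FunctionalAssayEvidence(
                direction=AssayDirection.damaging, strength=Strength.S
            ),
        )
    )
    add(
        _fx(
            "rule_3e_three_moderate", ["PM2_M", "PM1_M", "PM5_M"], LP, "3E",
            gene=make_gene("CONGENE", decipher_missense_constraint=0.3),
            prior_variants=[prior(alt="W", equivalent=False)],
            frequencies=absent_freqs(),
        )
    )
    add(
        _fx(
            "rule_3f_two_moderate_two_supporting",
            ["PM2_M", "PM5_M", "PP3_P", "PP2_P"], LP, "3F",
            gene=make_gene("MISGENE", **pp2_gene_kw),
            prior_variants=[prior(alt="W", equivalent=False)],
            insilico=InSilicoScores(revel=0.75),
            frequencies=absent_freqs(),
        )
    )
    add(
        _fx(
            "rule_3g_moderate_four_supporting",
            ["PM2_M", "PP3_P", "PP2_P", "PP4_P", "PP1_P"], LP, "3G",
            gene=make_gene("MISGENE", **pp2_gene_kw),
            insilico=InSilicoScores(revel=0.75),
            case_data=CaseLevelData(segregating_meioses=3, **pp4_flags),
            frequencies=absent_freqs(),
        )
    )
    add(
        _fx(
            "rule_4a_vs_strong", ["PVS1_VS", "PM2_M", "PS3_S"], P, "4A",
            gene=lof_gene(),
            variant=null_variant(Consequence.nonsense, nmd_predicted=True),
            functional=FunctionalAssayEvidence(
                direction=AssayDirection.damaging, strength=Strength.S
            ),
            frequencies=absent_freqs(),
        )
    )
    add(
        _fx(
            "rule_4b_vs_two_moderate", ["PVS1_VS", "PM2_M", "PM6_M"], P, "4B",
            gene=lof_gene(),
            variant=null_variant(Consequence.nonsense, nmd_predicted=True),
            case_data=CaseLevelData(
                denovo_obs=[
                    DeNovoObservation(
                        confirmed=False, phenotype_match=PhenotypeMatch.highly_specific
                    )
                ]
            ),
            frequencies=absent_freqs(),
        )
    )
    add(
        _fx(
            "rule_4c_vs_moderate_supporting", ["PVS1_VS", "PM2_M", "PP1_P"], P, "4C",
            gene=lof_gene(),
            variant=null_variant(Consequence.nonsense, nmd_predicted=True),
            case_data=CaseLevelData(segregating_meioses=3),
            frequencies=absent_freqs(),
        )
    )
    add(
        _fx(
            "rule_4d_vs_two_supporting", ["PVS1_VS", "PP1_P", "PM6_P"], P, "4D",
            gene=lof_gene(),
            variant=null_variant(Consequence.nonsense, nmd_predicted=True),
            case_data=CaseLevelData(
                segregating_meioses=3,
                denovo_obs=[
                    DeNovoObservation(
                        confirmed=False, phenotype_match=PhenotypeMatch.consistent
                    )
                ],
            ),
        )
    )
    add(
        _fx(
            "rule_4e_two_strong", ["PS3_S", "PS4_S"], P, "4E",
            functional=FunctionalAssayEvidence(
                direction=AssayDirection.damaging, strength=Strength.S
            ),
            case_data=CaseLevelData(
                case_control=CaseControlStudy(odds_ratio=8.0, ci_low=1.4)
            ),
        )
    )
    add(
        _fx(
            "rule_4f_strong_three_moderate",
            ["PS3_S", "PM2_M", "PM1_M", "PM5_M"], P, "4F",
            gene=make_gene("CONGENE", decipher_missense_constraint=0.3),
            prior_variants=[prior(alt="W", equivalent=False)],
            functional=FunctionalAssayEvidence(
                direction=AssayDirection.damaging, strength=Strength.S
            ),
            frequencies=absent_freqs(),
        )
    )
    add(
        _fx(
            "rule_4g_strong_two_moderate_two_supporting",
            ["PS3_S", "PM2_M", "PM1_M", "PP3_P", "PP2_P"], P, "4G",
            gene=make_gene(
                "MIXGENE", decipher_missense_constraint=0.3, **pp2_gene_kw
            ),
            insilico=InSilicoScores(revel=0.75),
            functional=FunctionalAssayEvidence(
                direction=AssayDirection.damaging, strength=Strength.S
            ),
            frequencies=absent_freqs(),
        )
    )
    add(
        _fx(
            "rule_4h_strong_moderate_four_supporting",
            ["PS3_S", "PM2_M", "PP3_P", "PP2_P", "PP1_P", "PP4_P"], P, "4H",
            gene=make_gene("MISGENE", **pp2_gene_kw),
            insilico=InSilicoScores(revel=0.75),
            functional=FunctionalAssayEvidence(
                direction=AssayDirection.damaging, strength=Strength.S
            ),
            case_data=CaseLevelData(segregating_meioses=3, **pp4_flags),
            frequencies=absent_freqs(),
        )
    )

    # -- gene gate --------------------------------------------------------
    add(
        _fx(
            "gate_vcep_delegate", [], None,
            expected_status=RecordStatus.vcep_delegate,
            gene=make_gene("VCEPGENE", vcep_curated=True),
        )
    )
    add(
        _fx(
            "gate_disputed_validity", [], None,
            expected_status=RecordStatus.not_classifiable,
            gene=make_gene("BADGENE", clinical_validity=ClinicalValidity.disputed),
        )
    )

    return fx


def dump_gold_fixtures(path: Union[str, Path]) -> None:
    """Export the gold set as JSON (records plus expectations)."""
    payload = [f.model_dump(mode="json") for f in gold_fixture_set()]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Randomized cohorts
# ---------------------------------------------------------------------------

#: Evidence injectors: each makes the named criterion fire on the base
#: record.  Injectors compose only when their evidence is compatible
#: (e.g. BA1 and PM2 are contradictory by construction); prevalences are
#: guaranteed per clause only for compatible clause sets.
_INJECTORS: dict[str, Callable[[dict[str, Any]], None]] = {}


def _injector(name: str) -> Callable:
    def deco(fn: Callable[[dict[str, Any]], None]) -> Callable:
        _INJECTORS[name] = fn
        return fn

    return deco


@_injector("BA1")
def _inj_ba1(kw: dict[str, Any]) -> None:
    kw["frequencies"] = freqs_at(0.06)


@_injector("BS1")
def _inj_bs1(kw: dict[str, Any]) -> None:
    kw["frequencies"] = freqs_at(0.002)


@_injector("PM2")
def _inj_pm2(kw: dict[str, Any]) -> None:
    kw["frequencies"] = absent_freqs()


@_injector("PVS1")
def _inj_pvs1(kw: dict[str, Any]) -> None:
    kw["gene"] = lof_gene(kw["gene"].symbol)
    kw["variant"] = null_variant(Consequence.nonsense, nmd_predicted=True)


@_injector("PS1")
def _inj_ps1(kw: dict[str, Any]) -> None:
    kw["prior_variants"] = [prior()]


@_injector("PM1")
def _inj_pm1(kw: dict[str, Any]) -> None:
    kw["gene"] = kw["gene"].model_copy(update={"decipher_missense_constraint": 0.3})


@_injector("PP2")
def _inj_pp2(kw: dict[str, Any]) -> None:
    kw["gene"] = kw["gene"].model_copy(
        update={"pathogenic_missense_count": 5, "missense_constraint_z": 3.5}
    )


@_injector("PP3")
def _inj_pp3(kw: dict[str, Any]) -> None:
    kw["insilico"] = InSilicoScores(revel=0.75)


@_injector("BP4")
def _inj_bp4(kw: dict[str, Any]) -> None:
    kw["insilico"] = InSilicoScores(revel=0.35)


@_injector("BP7")
def _inj_bp7(kw: dict[str, Any]) -> None:
    kw["variant"] = VariantDescriptor(consequence=Consequence.synonymous)
    kw["insilico"] = InSilicoScores(spliceai_delta=0.05, gerp=-1.2)


@_injector("PM3")
def _inj_pm3(kw: dict[str, Any]) -> None:
    kw["gene"] = kw["gene"].model_copy(update={"inheritance": Inheritance.AR})
    kw["case"]["recessive_obs"] = [
        RecessiveObservation(phase=RecessivePhase.in_trans_with_PLP)
    ]


@_injector("PS2")
def _inj_ps2(kw: dict[str, Any]) -> None:
    kw["case"].setdefault("denovo_obs", []).append(
        DeNovoObservation(confirmed=True, phenotype_match=PhenotypeMatch.highly_specific)
    )


@_injector("PM6")
def _inj_pm6(kw: dict[str, Any]) -> None:
    kw["case"].setdefault("denovo_obs", []).append(
        DeNovoObservation(confirmed=False, phenotype_match=PhenotypeMatch.consistent)
    )


@_injector("PP1")
def _inj_pp1(kw: dict[str, Any]) -> None:
    kw["case"]["segregating_meioses"] = 7


@_injector("PS4")
def _inj_ps4(kw: dict[str, Any]) -> None:
    kw["frequencies"] = absent_freqs()
    kw["case"]["proband_count"] = 5


@_injector("BS2")
def _inj_bs2(kw: dict[str, Any]) -> None:
    kw["gene"] = kw["gene"].model_copy(update={"category": GeneCategory.cancer})
    kw["case"]["healthy_carrier_counts"] = HealthyCarrierCounts(hom=1)


@_injector("BS4")
def _inj_bs4(kw: dict[str, Any]) -> None:
    kw["gene"] = kw["gene"].model_copy(update={"high_penetrance_early_onset": True})
    kw["case"]["nonsegregation_observed"] = True


@_injector("PP4")
def _inj_pp4(kw: dict[str, Any]) -> None:
    kw["frequencies"] = absent_freqs()
    kw["case"].update(
        comprehensive_test=True,
        family_history_consistent=True,
        phenotype_specific_single_etiology=True,
    )


@_injector("BP5")
def _inj_bp5(kw: dict[str, Any]) -> None:
    kw["gene"] = kw["gene"].model_copy(
        update={"ad_highly_penetrant_childhood_onset": True}
    )
    kw["case"].update(alternate_molecular_cause=True, variant_noncontributory=True)


@_injector("PS3")
def _inj_ps3(kw: dict[str, Any]) -> None:
    kw["functional"] = FunctionalAssayEvidence(
        direction=AssayDirection.damaging, strength=Strength.S
    )


@_injector("BS3")
def _inj_bs3(kw: dict[str, Any]) -> None:
    kw["functional"] = FunctionalAssayEvidence(
        direction=AssayDirection.benign, strength=Strength.M
    )


SUPPORTED_CLAUSES = frozenset(_INJECTORS)


def random_cohort(
    n: int, seed: int, clause_prevalence: dict[str, float]
) -> list[EvidenceRecord]:
    """Generate ``n`` synthetic records with clause-level prevalences.

    Each configured clause fires independently with its probability; the
    base record carries no applied evidence.  Reproducible for a fixed
    seed.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    for clause, p in clause_prevalence.items():
        if clause not in SUPPORTED_CLAUSES:
            raise ValueError(
                f"unsupported clause {clause!r}; choose from "
                f"{sorted(SUPPORTED_CLAUSES)}"
            )
        if not 0 <= p <= 1:
            raise ValueError(f"prevalence for {clause} outside [0, 1]")
    rng = random.Random(seed)
    records = []
    for i in range(n):
        kw: dict[str, Any] = {
            "id": f"cohort{i}",
            "gene": make_gene(f"G{i}"),
            "variant": missense(),
            "frequencies": neutral_freqs(),
            "case": {},
        }
        for clause in sorted(clause_prevalence):
            if rng.random() < clause_prevalence[clause]:
                _INJECTORS[clause](kw)
        case = kw.pop("case")
        kw["case_data"] = CaseLevelData.model_validate(case) if case else CaseLevelData()
        records.append(EvidenceRecord.model_validate(kw))
    return records
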