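"""Domain model for constitutional sequence-variant classification.

Defines the evidence record schema consumed by the rules engine: gene
context (inheritance, category, constraint metrics, list memberships),
per-population allele frequencies, the molecular description of the
variant, case-level observations, in-silico scores and curated functional
assay evidence.  Also implements the two gating operations that run before
any criterion is evaluated: the gene clinical-validity gate and primary
transcript selection.

Validation is handled by pydantic; invariant violations surface as
``pydantic.ValidationError`` naming the offending field.
"""

from __future__ import annotations

import logging
from enum import Enum
from typing import Optional

from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    field_validator,
    model_validator,
)

logger = logging.getLogger("acmg_engine")


class EngineError(Exception):
    """Base class for engine errors."""


class ConfigurationError(EngineError):
    """A configuration table is missing or inconsistent."""


# ---------------------------------------------------------------------------
# Enumerations
# ---------------------------------------------------------------------------

class Inheritance(str, Enum):
    AD = "AD"
    AR = "AR"
    AD_AR = "AD_AR"
    XL = "XL"
    XLR = "XLR"
    XLD = "XLD"


#: Inheritance modes grouped with AR for the frequency-threshold table
#: ("AR, AD/AR or XL" row).  XLR/XLD are refinements of XL and follow the
#: XL grouping for frequency purposes.
RECESSIVE_FREQUENCY_GROUP = frozenset(
    {Inheritance.AR, Inheritance.AD_AR, Inheritance.XL, Inheritance.XLR, Inheritance.XLD}
)

#: Modes treated as dominant for proband counting (PS4) and the dominant
#: co-segregation ladder (PP1).  AD/AR genes qualify on their AD side.
DOMINANT_GROUP = frozenset({Inheritance.AD, Inheritance.AD_AR, Inheritance.XLD})

#: Modes treated as recessive for the in-trans scoring system (PM3).
RECESSIVE_CASE_GROUP = frozenset({Inheritance.AR, Inheritance.AD_AR})


class GeneCategory(str, Enum):
    cancer = "cancer"
    general = "general"


class ClinicalValidity(str, Enum):
    definitive = "definitive"
    strong = "strong"
    moderate = "moderate"
    limited = "limited"
    disputed = "disputed"
    refuted = "refuted"
    none = "none"


#: Validities for which general-rule classification may proceed
#: ("at least limited").
CLASSIFIABLE_VALIDITIES = frozenset(
    {
        ClinicalValidity.limited,
        ClinicalValidity.moderate,
        ClinicalValidity.strong,
        ClinicalValidity.definitive,
    }
)


class LofMechanism(str, Enum):
    """Curated loss-of-function disease-mechanism status for a gene."""

    established = "established"
    not_established = "not_established"
    unknown = "unknown"


class SpecialDomain(str, Enum):
    """Gene classes with dedicated PM1_S residue rules."""

    notch3_egf = "notch3_egf"
    collagen_glycine = "collagen_glycine"
    c2h4_zinc_finger = "c2h4_zinc_finger"
    none = "none"


class Consequence(str, Enum):
    nonsense = "nonsense"
    frameshift = "frameshift"
    canonical_splice = "canonical_splice"
    initiation_codon = "initiation_codon"
    single_multi_exon_deletion = "single_multi_exon_deletion"
    missense = "missense"
    synonymous = "synonymous"
    inframe_indel = "inframe_indel"
    stop_loss = "stop_loss"
    other = "other"


#: Null-variant consequences in scope for PVS1.
NULL_CONSEQUENCES = frozenset(
    {
        Consequence.nonsense,
        Consequence.frameshift,
        Consequence.canonical_splice,
        Consequence.initiation_codon,
        Consequence.single_multi_exon_deletion,
    }
)


class Strength(str, Enum):
    A = "A"    # stand-alone
    VS = "VS"  # very strong
    S = "S"    # strong
    M = "M"    # moderate
    P = "P"    # supporting


STRENGTH_RANK = {
    Strength.P: 1,
    Strength.M: 2,
    Strength.S: 3,
    Strength.VS: 4,
    Strength.A: 5,
}

#: Evidence points per strength level in the naturally scaled point system
#: (supporting 1, moderate 2, strong 4, very strong 8; stand-alone treated
#: as 8 for the posterior, configurable at call sites).
STRENGTH_POINTS = {
    Strength.P: 1,
    Strength.M: 2,
    Strength.S: 4,
    Strength.VS: 8,
    Strength.A: 8,
}


class Direction(str, Enum):
    benign = "benign"
    pathogenic = "pathogenic"


class Criterion(str, Enum):
    PVS1 = "PVS1"
    PS1 = "PS1"
    PS2 = "PS2"
    PS3 = "PS3"
    PS4 = "PS4"
    PM1 = "PM1"
    PM2 = "PM2"
    PM3 = "PM3"
    PM4 = "PM4"
    PM5 = "PM5"
    PM6 = "PM6"
    PP1 = "PP1"
    PP2 = "PP2"
    PP3 = "PP3"
    PP4 = "PP4"
    PP5 = "PP5"
    BA1 = "BA1"
    BS1 = "BS1"
    BS2 = "BS2"
    BS3 = "BS3"
    BS4 = "BS4"
    BP1 = "BP1"
    BP2 = "BP2"
    BP3 = "BP3"
    BP4 = "BP4"
    BP5 = "BP5"
    BP6 = "BP6"
    BP7 = "BP7"


ALL_CRITERIA: tuple[Criterion, ...] = tuple(Criterion)
assert len(ALL_CRITERIA) == 28


def criterion_direction(criterion: Criterion) -> Direction:
    return Direction.benign if criterion.value.startswith("B") else Direction.pathogenic


#: Strength levels at which each criterion may be applied (weight
#: modulations).  Criteria that are never routinely applied (BP1, BP2,
#: BP3) keep a supporting weight for the curated-override hook; PP5/BP6
#: are discontinued and carry no weight.
ALLOWED_STRENGTHS: dict[Criterion, frozenset[Strength]] = {
    Criterion.PVS1: frozenset({Strength.P, Strength.M, Strength.S, Strength.VS}),
    Criterion.PS1: frozenset({Strength.M, Strength.S}),
    Criterion.PS2: frozenset({Strength.P, Strength.M, Strength.S, Strength.VS}),
    Criterion.PS3: frozenset({Strength.P, Strength.M, Strength.S, Strength.VS}),
    Criterion.PS4: frozenset({Strength.P, Strength.M, Strength.S}),
    Criterion.PM1: frozenset({Strength.M, Strength.S}),
    Criterion.PM2: frozenset({Strength.P, Strength.M}),
    Criterion.PM3: frozenset({Strength.P, Strength.M, Strength.S, Strength.VS}),
    Criterion.PM4: frozenset({Strength.P, Strength.M}),
    Criterion.PM5: frozenset({Strength.P, Strength.M}),
    Criterion.PM6: frozenset({Strength.P, Strength.M, Strength.S, Strength.VS}),
    Criterion.PP1: frozenset({Strength.P, Strength.M, Strength.S}),
    Criterion.PP2: frozenset({Strength.P}),
    Criterion.PP3: frozenset({Strength.P}),
    Criterion.PP4: frozenset({Strength.P, Strength.S}),
    Criterion.PP5: frozenset(),
    Criterion.BA1: frozenset({Strength.A}),
    Criterion.BS1: frozenset({Strength.S}),
    Criterion.BS2: frozenset({Strength.S}),
    Criterion.BS3: frozenset({Strength.P, Strength.M, Strength.S}),
    Criterion.BS4: frozenset({Strength.S}),
    Criterion.BP1: frozenset({Strength.P}),
    Criterion.BP2: frozenset({Strength.P}),
    Criterion.BP3: frozenset({Strength.P}),
    Criterion.BP4: frozenset({Strength.P}),
    Criterion.BP5: frozenset({Strength.P}),
    Criterion.BP6: frozenset(),
    Criterion.BP7: frozenset({Strength.P}),
}


# ---------------------------------------------------------------------------
# Criterion call
# ---------------------------------------------------------------------------

class CriterionCall(BaseModel):
    """One evaluated criterion: direction, modulated strength, rationale.

    The rationale carries machine-readable clause tags in square brackets
    (e.g. ``[PM3:in_trans]``) that the fixtures module uses to measure
    branch coverage.
    """

    model_config = ConfigDict(validate_assignment=True)

    criterion: Criterion
    direction: Direction
    strength: Optional[Strength] = None
    applied: bool = False
    rationale: str = ""
    score: Optional[float] = None

    @model_validator(mode="after")
    def _check_consistency(self) -> "CriterionCall":
        expected = criterion_direction(self.criterion)
        if self.direction != expected:
            raise ValueError(
                f"direction {self.direction.value!r} inconsistent with "
                f"criterion family of {self.criterion.value}"
            )
        if self.applied:
            if self.strength is None:
                raise ValueError(f"{self.criterion.value}: applied call requires a strength")
            if self.strength not in ALLOWED_STRENGTHS[self.criterion]:
                raise ValueError(
                    f"{self.criterion.value}: strength {self.strength.value} is not an "
                    f"allowed weight modulation"
                )
        return self

    @property
    def points(self) -> int:
        """Signed evidence points (pathogenic positive, benign negative)."""
        if not self.applied or self.strength is None:
            return 0
        pts = STRENGTH_POINTS[self.strength]
        return pts if self.direction == Direction.pathogenic else -pts

    def label(self) -> str:
        if self.strength is None:
            return self.criterion.value
        return f"{self.criterion.value}_{self.strength.value}"


def applied_call(
    criterion: Criterion,
    strength: Strength,
    rationale: str = "",
    score: Optional[float] = None,
) -> CriterionCall:
    return CriterionCall(
        criterion=criterion,
        direction=criterion_direction(criterion),
        strength=strength,
        applied=True,
        rationale=rationale,
        score=score,
    )


def unapplied_call(
    criterion: Criterion, rationale: str = "", score: Optional[float] = None
) -> CriterionCall:
    return CriterionCall(
        criterion=criterion,
        direction=criterion_direction(criterion),
        strength=None,
        applied=False,
        rationale=rationale,
        score=score,
    )


# ---------------------------------------------------------------------------
# Thresholds (frequency + in-silico overrides)
# ---------------------------------------------------------------------------

class FrequencyThresholds(BaseModel):
    """Allele-frequency thresholds for BA1 / BS1_S / PM2_P / PM2_M.

    ``pm2_m = None`` encodes the "absent from controls" rule for PM2_M
    (the dominant rows of the built-in table); ``ba1 = None`` disables the
    stand-alone benign rule (used for exception-list genes whose override
    does not provide one).
    """

    ba1: Optional[float] = Field(default=None, gt=0, le=1)
    bs1_s: float = Field(gt=0, lt=1)
    pm2_p: float = Field(gt=0, lt=1)
    pm2_m: Optional[float] = Field(default=None, ge=0, lt=1)

    @model_validator(mode="after")
    def _check_ordering(self) -> "FrequencyThresholds":
        if self.ba1 is not None and not self.ba1 > self.bs1_s:
            raise ValueError("threshold ordering violated: ba1 must exceed bs1_s")
        if not self.bs1_s > self.pm2_p:
            raise ValueError("threshold ordering violated: bs1_s must exceed pm2_p")
        if self.pm2_m is not None and not self.pm2_p >= self.pm2_m:
            raise ValueError("threshold ordering violated: pm2_p must be >= pm2_m")
        return self


class InsilicoThresholds(BaseModel):
    """Per-gene REVEL / SpliceAI cut-offs for PP3 and BP4."""

    revel_pathogenic: float = Field(default=0.7, ge=0, le=1)
    revel_benign: float = Field(default=0.4, ge=0, le=1)
    spliceai_pathogenic: float = Field(default=0.8, ge=0, le=1)
    spliceai_benign: float = Field(default=0.2, ge=0, le=1)

    @model_validator(mode="after")
    def _check_bands(self) -> "InsilicoThresholds":
        if self.revel_benign > self.revel_pathogenic:
            raise ValueError("revel_benign must not exceed revel_pathogenic")
        if self.spliceai_benign > self.spliceai_pathogenic:
            raise ValueError("spliceai_benign must not exceed spliceai_pathogenic")
        return self


# ---------------------------------------------------------------------------
# Gene context
# ---------------------------------------------------------------------------

class GeneContext(BaseModel):
    """Per-gene facts that parameterize every criterion.

    Curation-derived flags (penetrance class, green-list membership,
    special domain class, hotspot intervals) are configuration inputs;
    the engine never infers them.
    """

    symbol: str
    inheritance: Inheritance
    category: GeneCategory = GeneCategory.general
    vcep_curated: bool = False
    clinical_validity: ClinicalValidity
    ba1_exception: bool = False

    # loss-of-function mechanism: curated status plus fallback metrics
    lof_mechanism: LofMechanism = LofMechanism.unknown
    pli: Optional[float] = Field(default=None, ge=0, le=1)
    o_e: Optional[float] = Field(default=None, ge=0)

    missense_constraint_z: Optional[float] = None
    pathogenic_missense_count: int = Field(default=0, ge=0)
    decipher_missense_constraint: Optional[float] = Field(default=None, ge=0)
    special_domain_class: SpecialDomain = SpecialDomain.none
    hotspot_codon_ranges: list[tuple[int, int]] = Field(default_factory=list)

    pediatric_green_list: bool = False
    high_penetrance_early_onset: bool = False
    complete_penetrance: bool = False
    ad_highly_penetrant_childhood_onset: bool = False

    frequency_overrides: Optional[FrequencyThresholds] = None
    insilico_overrides: Optional[InsilicoThresholds] = None

    def lof_established(self) -> bool:
        """Whether loss of function is a known disease mechanism.

        Curated haploinsufficiency status wins; when unknown, fall back
        to constraint metrics (pLI > 0.9 or o/e < 0.35).
        """
        if self.lof_mechanism == LofMechanism.established:
            return True
        if self.lof_mechanism == LofMechanism.not_established:
            return False
        if self.pli is not None and self.pli > 0.9:
            return True
        if self.o_e is not None and self.o_e < 0.35:
            return True
        return False


class GateOutcome(str, Enum):
    classifiable = "classifiable"
    not_classifiable = "not_classifiable"
    vcep_delegate = "vcep_delegate"


def gate_gene(gene: GeneContext) -> GateOutcome:
    """Gate a gene by clinical validity and VCEP curation.

    VCEP-curated genes are delegated to their expert-panel workflow (the
    general rules must not be applied); genes whose gene-disease validity
    is below "limited" are refused.
    """
    if gene.vcep_curated:
        return GateOutcome.vcep_delegate
    if gene.clinical_validity in CLASSIFIABLE_VALIDITIES:
        return GateOutcome.classifiable
    logger.info(
        "gene %s refused: clinical validity %s is below 'limited'",
        gene.symbol,
        gene.clinical_validity.value,
    )
    return GateOutcome.not_classifiable


# ---------------------------------------------------------------------------
# Transcripts
# ---------------------------------------------------------------------------

class TranscriptFlag(str, Enum):
    mane_select = "mane_select"
    refseq_select = "refseq_select"
    mane_clinical_plus = "mane_clinical_plus"
    refseq = "refseq"


TRANSCRIPT_PRIORITY = (
    TranscriptFlag.mane_select,
    TranscriptFlag.refseq_select,
    TranscriptFlag.mane_clinical_plus,
    TranscriptFlag.refseq,
)


class TranscriptRecord(BaseModel):
    id: str
    flags: set[TranscriptFlag]
    length: int = Field(gt=0)

    @field_validator("flags")
    @classmethod
    def _non_empty(cls, v: set[TranscriptFlag]) -> set[TranscriptFlag]:
        if not v:
            raise ValueError("at least one transcript flag is required")
        return v


def select_primary_transcript(transcripts: list[TranscriptRecord]) -> TranscriptRecord:
    """Pick the primary transcript by reference-set priority.

    MANE Select > RefSeq Select > MANE Clinical Plus > RefSeq; when only
    plain RefSeq transcripts are available the longest wins, ties broken
    toward the lexicographically smallest identifier for determinism.
    """
    if not transcripts:
        raise ValueError("cannot select a primary transcript from an empty list")
    for flag in TRANSCRIPT_PRIORITY:
        candidates = [t for t in transcripts if flag in t.flags]
        if not candidates:
            continue
        if flag == TranscriptFlag.refseq:
            return min(candidates, key=lambda t: (-t.length, t.id))
        return min(candidates, key=lambda t: t.id)
    raise AssertionError("unreachable: flags validated non-empty")


# ---------------------------------------------------------------------------
# Frequencies
# ---------------------------------------------------------------------------

class FrequencyRecord(BaseModel):
    """Allele count / number for one (sub)population."""

    population: str
    allele_count: int = Field(ge=0)
    allele_number: int = Field(ge=0)
    founder_effect: bool = False

    @model_validator(mode="after")
    def _ac_le_an(self) -> "FrequencyRecord":
        if self.allele_count > self.allele_number:
            raise ValueError("allele_count exceeds allele_number")
        return self

    @property
    def frequency(self) -> float:
        if self.allele_number == 0:
            return 0.0
        return self.allele_count / self.allele_number


# ---------------------------------------------------------------------------
# Molecular descriptors
# ---------------------------------------------------------------------------

class VariantDescriptor(BaseModel):
    """Molecular consequence and location context on the primary transcript."""

    consequence: Consequence
    codon_index: Optional[int] = Field(default=None, gt=0)
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None
    indel_aa_length: int = Field(default=0, ge=0)
    #: region with more than 3 identical sequence units (bases or sets of bases)
    in_repeat_region: bool = False
    nmd_predicted: Optional[bool] = None
    last_exon_or_50nt_rule: Optional[bool] = None
    affected_region_critical: bool = False
    exon_skip_inframe: bool = False
    #: NOTCH3 EGF-like repeat: substitution changes cysteine parity
    cysteine_parity_change: bool = False
    #: functional studies indicate aberrant splicing (PS1/PM5 caution)
    functional_splicing_aberrant: bool = False

    @model_validator(mode="after")
    def _field_scoping(self) -> "VariantDescriptor":
        if self.indel_aa_length > 0 and self.consequence not in (
            Consequence.inframe_indel,
            Consequence.stop_loss,
        ):
            raise ValueError("indel_aa_length is only meaningful for in-frame indels")
        if self.consequence != Consequence.missense and (
            self.ref_aa is not None or self.alt_aa is not None
        ):
            raise ValueError("ref_aa/alt_aa are only meaningful for missense variants")
        return self


class PriorClassification(str, Enum):
    pathogenic = "pathogenic"
    likely_pathogenic = "likely_pathogenic"


class PriorClassifiedVariant(BaseModel):
    """A previously classified missense variant at some codon of the gene."""

    codon_index: int = Field(gt=0)
    alt_aa: str
    #: same protein change as the assessed variant (equivalent missense)
    protein_change_equivalent: bool = False
    classification: PriorClassification
    independent_report_count: int = Field(ge=1)


class InSilicoScores(BaseModel):
    revel: Optional[float] = Field(default=None, ge=0, le=1)
    spliceai_delta: Optional[float] = Field(default=None, ge=0, le=1)
    gerp: Optional[float] = None


# ---------------------------------------------------------------------------
# Case-level data
# ---------------------------------------------------------------------------

class RecessivePhase(str, Enum):
    in_trans_with_PLP = "in_trans_with_PLP"
    phase_unknown = "phase_unknown"
    homozygous = "homozygous"


class RecessiveObservation(BaseModel):
    """One unrelated affected individual for the in-trans scoring system."""

    phase: RecessivePhase
    consanguineous: bool = False

    @model_validator(mode="after")
    def _consanguinity_scope(self) -> "RecessiveObservation":
        if self.consanguineous and self.phase != RecessivePhase.homozygous:
            raise ValueError("consanguineous is only meaningful for homozygous observations")
        return self


class PhenotypeMatch(str, Enum):
    highly_specific = "highly_specific"
    consistent = "consistent"
    consistent_high_heterogeneity = "consistent_high_heterogeneity"
    inconsistent = "inconsistent"


class DeNovoObservation(BaseModel):
    """One de novo event; confirmed means maternity and paternity confirmed."""

    confirmed: bool
    phenotype_match: PhenotypeMatch


class CaseControlStudy(BaseModel):
    odds_ratio: float = Field(gt=0)
    ci_low: float = Field(gt=0)


class HealthyCarrierCounts(BaseModel):
    het: int = Field(default=0, ge=0)
    hom: int = Field(default=0, ge=0)
    hemi: int = Field(default=0, ge=0)

    @property
    def total_alleles(self) -> int:
        return self.het + 2 * self.hom + self.hemi


class CaseLevelData(BaseModel):
    recessive_obs: list[RecessiveObservation] = Field(default_factory=list)
    denovo_obs: list[DeNovoObservation] = Field(default_factory=list)
    segregating_meioses: int = Field(default=0, ge=0)
    nonsegregation_observed: bool = False
    #: unrelated, previously described probands with a confirmed phenotype
    proband_count: int = Field(default=0, ge=0)
    case_control: Optional[CaseControlStudy] = None
    founder_variant: bool = False
    vcep_pathogenic: bool = False
    healthy_carrier_counts: HealthyCarrierCounts = Field(default_factory=HealthyCarrierCounts)
    phenotype_specific_single_etiology: bool = False
    comprehensive_test: bool = False
    family_history_consistent: bool = False
    pathognomonic_extra_evidence: bool = False
    alternate_molecular_cause: bool = False
    variant_noncontributory: bool = False
    in_house_positive_genotype_no_phenotype: bool = False


# ---------------------------------------------------------------------------
# Functional assay evidence
# ---------------------------------------------------------------------------

class AssayDirection(str, Enum):
    damaging = "damaging"
    benign = "benign"
    none = "none"


class FunctionalAssayEvidence(BaseModel):
    """Curated functional-assay outcome with a pre-assessed strength."""

    direction: AssayDirection = AssayDirection.none
    strength: Optional[Strength] = None
    proband_derived: bool = False

    @model_validator(mode="after")
    def _strength_scope(self) -> "FunctionalAssayEvidence":
        if self.direction == AssayDirection.none:
            if self.strength is not None:
                raise ValueError("strength must be absent when direction is 'none'")
            return self
        if self.strength is None:
            raise ValueError("strength is required when a direction is asserted")
        if self.strength == Strength.A:
            raise ValueError("stand-alone is not a functional-assay strength")
        if self.direction == AssayDirection.benign and self.strength == Strength.VS:
            raise ValueError("benign functional evidence is capped at strong")
        return self


# ---------------------------------------------------------------------------
# Evidence record
# ---------------------------------------------------------------------------

class EvidenceRecord(BaseModel):
    """Everything known about one variant, pre-annotated by upstream tools."""

    id: str = "variant"
    variant: VariantDescriptor
    gene: GeneContext
    transcripts: list[TranscriptRecord] = Field(default_factory=list)
    frequencies: list[FrequencyRecord] = Field(default_factory=list)
    prior_variants: list[PriorClassifiedVariant] = Field(default_factory=list)
    case_data: CaseLevelData = Field(default_factory=CaseLevelData)
    insilico: InSilicoScores = Field(default_factory=InSilicoScores)
    functional: FunctionalAssayEvidence = Field(default_factory=FunctionalAssayEvidence)
    #: curated per-variant criterion overrides (e.g. the exceptional-case
    #: hook for BP3); passed through the conflict resolver unchanged.
    curated_overrides: list[CriterionCall] = Field(default_factory=list)
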