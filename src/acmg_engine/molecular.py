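"""Variant-type and location criteria.

PVS1 (config-driven decision-table modulation for null variants in
loss-of-function genes), PS1/PM5 (prior classified missense changes),
PM1 (domain / hotspot), PM4 (protein-length change), PP2 (missense
constraint) and BP7 (silent variants without splice impact).  BP1 and BP3
are deliberately never applied routinely; they stay in the audit trail as
unapplied entries with a curated-override hook for exceptional cases.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources
from typing import Optional

from pydantic import BaseModel, Field

from .model import (
    Consequence,
    Criterion,
    CriterionCall,
    GeneContext,
    InSilicoScores,
    NULL_CONSEQUENCES,
    PriorClassification,
    PriorClassifiedVariant,
    SpecialDomain,
    Strength,
    VariantDescriptor,
    applied_call,
    unapplied_call,
)

#: SpliceAI delta at or above which a deleterious splice mechanism is
#: suspected and PS1/PM5 are withheld.
SPLICE_CAUTION_DELTA = 0.8
#: gnomAD regional missense-constraint Z cut-off for PP2 (strict >).
PP2_CONSTRAINT_Z = 3.09
#: Minimum previously reported pathogenic missense variants for PP2.
PP2_MIN_PATHOGENIC_MISSENSE = 3
#: DECIPHER missense-constraint cut-off for PM1_M (strict <).
PM1_DECIPHER_CONSTRAINT = 0.4
#: BP7 requires SpliceAI <= 0.2 and GERP < 0.
BP7_SPLICEAI_MAX = 0.2


# ---------------------------------------------------------------------------
# PVS1
# ---------------------------------------------------------------------------

class Pvs1Row(BaseModel):
    """One decision-table row; unspecified fields match anything."""

    tag: str
    consequence: list[Consequence]
    nmd_predicted: Optional[bool] = None
    last_exon_or_50nt_rule: Optional[bool] = None
    affected_region_critical: Optional[bool] = None
    exon_skip_inframe: Optional[bool] = None
    strength: Strength

    def matches(self, v: VariantDescriptor) -> bool:
        if v.consequence not in self.consequence:
            return False
        for field in (
            "nmd_predicted",
            "last_exon_or_50nt_rule",
            "affected_region_critical",
            "exon_skip_inframe",
        ):
            want = getattr(self, field)
            if want is not None and getattr(v, field) != want:
                return False
        return True


class Pvs1Table(BaseModel):
    description: str = ""
    rows: list[Pvs1Row] = Field(min_length=1)

    def match(self, v: VariantDescriptor) -> Optional[Pvs1Row]:
        for row in self.rows:
            if row.matches(v):
                return row
        return None


@lru_cache(maxsize=1)
def default_pvs1_table() -> Pvs1Table:
    text = resources.files("acmg_engine.data").joinpath("pvs1_decision_table.json").read_text()
    return Pvs1Table.model_validate(json.loads(text))


def load_pvs1_table(path: str) -> Pvs1Table:
    with open(path) as fh:
        return Pvs1Table.model_validate(json.load(fh))


#: Null consequences for which an NMD prediction is meaningful (and
#: therefore required).  Initiation-codon variants carry no NMD concept.
_NMD_RELEVANT = NULL_CONSEQUENCES - {Consequence.initiation_codon}


def evaluate_pvs1(
    v: VariantDescriptor,
    gene: GeneContext,
    table: Optional[Pvs1Table] = None,
) -> Optional[CriterionCall]:
    """PVS1 for null variants in genes where LoF is an established mechanism.

    Strength comes from the decision table keyed on consequence, NMD
    prediction, last-exon status, criticality of the affected region and
    in-frame exon skipping.
    """
    if v.consequence not in NULL_CONSEQUENCES:
        return None
    if v.consequence in _NMD_RELEVANT and v.nmd_predicted is None:
        raise ValueError(
            f"null variant ({v.consequence.value}) requires an nmd_predicted value"
        )
    if not gene.lof_established():
        return unapplied_call(
            Criterion.PVS1,
            "loss of function is not an established mechanism for "
            f"{gene.symbol} [PVS1:lof_not_established]",
        )
    if table is None:
        table = default_pvs1_table()
    row = table.match(v)
    if row is None:
        return unapplied_call(
            Criterion.PVS1, "no decision-table row matches [PVS1:no_table_row]"
        )
    return applied_call(
        Criterion.PVS1,
        row.strength,
        f"decision-table row '{row.tag}' [PVS1:{row.tag}]",
    )


# ---------------------------------------------------------------------------
# PS1 / PM5
# ---------------------------------------------------------------------------

def _is_equivalent(v: VariantDescriptor, prior: PriorClassifiedVariant) -> bool:
    if prior.codon_index != v.codon_index:
        return False
    return prior.protein_change_equivalent or (
        v.alt_aa is not None and prior.alt_aa == v.alt_aa
    )


def evaluate_ps1_pm5(
    v: VariantDescriptor,
    known: list[PriorClassifiedVariant],
    scores: InSilicoScores,
) -> Optional[CriterionCall]:
    """PS1 (equivalent missense) / PM5 (same-codon different missense).

    Both require the pathogenic mechanism to be the missense effect
    itself, so any suspicion of a splice mechanism (SpliceAI delta >= 0.8
    or functional evidence of aberrant splicing) withholds the pair.  PS1,
    when applicable, pre-empts PM5; the two are mutually exclusive.
    """
    if v.consequence != Consequence.missense:
        return None
    if (
        scores.spliceai_delta is not None
        and scores.spliceai_delta >= SPLICE_CAUTION_DELTA
    ) or v.functional_splicing_aberrant:
        return unapplied_call(
            Criterion.PS1,
            "possible splice mechanism (SpliceAI >= 0.8 or aberrant-splicing "
            "assay); PS1/PM5 withheld [PS1PM5:splice_suppressed]",
        )
    if v.codon_index is None:
        return None

    same_codon = [p for p in known if p.codon_index == v.codon_index]
    equivalent = [p for p in same_codon if _is_equivalent(v, p)]
    different = [p for p in same_codon if not _is_equivalent(v, p)]

    def counts(priors: list[PriorClassifiedVariant]) -> tuple[int, int]:
        path = sum(
            p.independent_report_count
            for p in priors
            if p.classification == PriorClassification.pathogenic
        )
        lp = sum(
            p.independent_report_count
            for p in priors
            if p.classification == PriorClassification.likely_pathogenic
        )
        return path, lp

    eq_path, eq_lp = counts(equivalent)
    if eq_path >= 1 or eq_lp >= 2:
        tag = "PS1:pathogenic" if eq_path >= 1 else "PS1:lp_multi"
        return applied_call(
            Criterion.PS1,
            Strength.S,
            f"equivalent missense previously classified ({eq_path} pathogenic, "
            f"{eq_lp} likely pathogenic reports) [{tag}]",
        )
    if eq_lp == 1:
        return applied_call(
            Criterion.PS1,
            Strength.M,
            "equivalent missense likely pathogenic in one previous case [PS1:lp_single]",
        )

    diff_path, diff_lp = counts(different)
    if diff_path >= 1 or diff_lp >= 2:
        tag = "PM5:pathogenic" if diff_path >= 1 else "PM5:lp_multi"
        return applied_call(
            Criterion.PM5,
            Strength.M,
            f"different missense at same codon ({diff_path} pathogenic, "
            f"{diff_lp} likely pathogenic reports) [{tag}]",
        )
    if diff_lp == 1:
        return applied_call(
            Criterion.PM5,
            Strength.P,
            "different missense at same codon likely pathogenic in one report "
            "[PM5:lp_single]",
        )
    return None


# ---------------------------------------------------------------------------
# PM1
# ---------------------------------------------------------------------------

def evaluate_pm1(v: VariantDescriptor, gene: GeneContext) -> Optional[CriterionCall]:
    """Mutational hotspot / critical functional domain.

    Strong for the three special residue classes (NOTCH3 EGF cysteine
    parity, collagen glycine, C2H4 zinc-finger Cys/His); moderate for
    regions under DECIPHER missense constraint < 0.4 or configured
    literature hotspots.
    """
    if v.consequence != Consequence.missense:
        return None
    cls = gene.special_domain_class
    if cls == SpecialDomain.notch3_egf and v.cysteine_parity_change:
        return applied_call(
            Criterion.PM1,
            Strength.S,
            "cysteine-parity-changing substitution in an EGF-like repeat [PM1:notch3]",
        )
    if cls == SpecialDomain.collagen_glycine and v.ref_aa == "G":
        return applied_call(
            Criterion.PM1, Strength.S, "glycine substitution in a collagen gene [PM1:collagen]"
        )
    if cls == SpecialDomain.c2h4_zinc_finger and v.ref_aa in ("C", "H"):
        return applied_call(
            Criterion.PM1,
            Strength.S,
            "Cys/His substitution in a C2H4 zinc finger [PM1:zinc_finger]",
        )
    if (
        gene.decipher_missense_constraint is not None
        and gene.decipher_missense_constraint < PM1_DECIPHER_CONSTRAINT
    ):
        return applied_call(
            Criterion.PM1,
            Strength.M,
            f"DECIPHER missense constraint {gene.decipher_missense_constraint:g} < "
            f"{PM1_DECIPHER_CONSTRAINT} [PM1:decipher]",
        )
    if v.codon_index is not None and any(
        lo <= v.codon_index <= hi for lo, hi in gene.hotspot_codon_ranges
    ):
        return applied_call(
            Criterion.PM1, Strength.M, "codon inside a configured literature hotspot [PM1:hotspot]"
        )
    return None


# ---------------------------------------------------------------------------
# PM4
# ---------------------------------------------------------------------------

def evaluate_pm4(
    v: VariantDescriptor, pm2_call: Optional[CriterionCall]
) -> Optional[CriterionCall]:
    """Protein-length change (in-frame indels outside repeats, stop loss).

    Only applies to variants rare enough to meet PM2 at either weight.
    Indels of 1-2 residues are supporting, 3 or more moderate; stop-loss
    variants are moderate (they extend the protein by well over two
    residues in virtually all transcripts).
    """
    if v.consequence not in (Consequence.inframe_indel, Consequence.stop_loss):
        return None
    if v.in_repeat_region:
        return unapplied_call(
            Criterion.PM4,
            "repetitive region (> 3 identical sequence units) [PM4:repeat_blocked]",
        )
    pm2_met = (
        pm2_call is not None
        and pm2_call.applied
        and pm2_call.criterion == Criterion.PM2
    )
    if not pm2_met:
        return unapplied_call(
            Criterion.PM4, "variant does not meet PM2 at any weight [PM4:rarity_blocked]"
        )
    if v.consequence == Consequence.stop_loss:
        return applied_call(Criterion.PM4, Strength.M, "stop-loss variant [PM4:stop_loss]")
    if v.indel_aa_length <= 2:
        return applied_call(
            Criterion.PM4,
            Strength.P,
            f"in-frame indel of {v.indel_aa_length} aa [PM4:small_indel]",
        )
    return applied_call(
        Criterion.PM4,
        Strength.M,
        f"in-frame indel of {v.indel_aa_length} aa [PM4:large_indel]",
    )


# ---------------------------------------------------------------------------
# PP2
# ---------------------------------------------------------------------------

def evaluate_pp2(v: VariantDescriptor, gene: GeneContext) -> Optional[CriterionCall]:
    """Missense in a constrained region of a missense-mechanism gene."""
    if v.consequence != Consequence.missense:
        return None
    if (
        gene.pathogenic_missense_count >= PP2_MIN_PATHOGENIC_MISSENSE
        and gene.missense_constraint_z is not None
        and gene.missense_constraint_z > PP2_CONSTRAINT_Z
    ):
        return applied_call(
            Criterion.PP2,
            Strength.P,
            f"{gene.pathogenic_missense_count} pathogenic missense variants and "
            f"regional constraint Z {gene.missense_constraint_z:g} > {PP2_CONSTRAINT_Z} "
            "[PP2:met]",
        )
    return None


# ---------------------------------------------------------------------------
# BP7
# ---------------------------------------------------------------------------

def evaluate_bp7(v: VariantDescriptor, scores: InSilicoScores) -> Optional[CriterionCall]:
    """Synonymous variant with no predicted splice impact and no conservation."""
    if v.consequence != Consequence.synonymous:
        return None
    if scores.spliceai_delta is None or scores.gerp is None:
        return unapplied_call(
            Criterion.BP7,
            "SpliceAI and GERP scores are both required [BP7:missing_scores]",
        )
    if scores.spliceai_delta <= BP7_SPLICEAI_MAX and scores.gerp < 0:
        return applied_call(
            Criterion.BP7,
            Strength.P,
            f"synonymous, SpliceAI {scores.spliceai_delta:g} <= {BP7_SPLICEAI_MAX} and "
            f"GERP {scores.gerp:g} < 0 [BP7:met]",
        )
    return None


# ---------------------------------------------------------------------------
# BP1 / BP3 (not routinely applied)
# ---------------------------------------------------------------------------

def unapplied_bp1_bp3() -> list[CriterionCall]:
    """BP1 and BP3 audit entries; overridable per variant in curated cases."""
    return [
        unapplied_call(
            Criterion.BP1,
            "not routinely applied (rare-missense deleteriousness is hard to "
            "exclude without functional data) [BP1:not_applied]",
        ),
        unapplied_call(
            Criterion.BP3,
            "not routinely applied (repetitive regions and dispensable domains "
            "are hard to define); curated override available [BP3:not_applied]",
        ),
    ]
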