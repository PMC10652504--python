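"""Population-frequency criteria: BA1, BS1 and PM2.

The three criteria are mutually exclusive and evaluated from per-population
allele counts under gene-category- and inheritance-specific thresholds.
Two built-in threshold rows exist (cancer genes and remaining genes, each
split by dominant vs. recessive-group inheritance); per-gene overrides take
precedence and are the hook for gene-specific ClinGen recommendations.

Eligibility of a population: no founder effect and more than 2,000 alleles
tested; for the benign-direction criteria (BA1/BS1) the variant must
additionally be present in at least 5 alleles.  Frequencies are compared as
exact rationals AC/AN, never as pre-rounded percentages.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Optional

from .model import (
    ConfigurationError,
    Criterion,
    CriterionCall,
    FrequencyRecord,
    FrequencyThresholds,
    GeneCategory,
    GeneContext,
    Inheritance,
    RECESSIVE_FREQUENCY_GROUP,
    Strength,
    applied_call,
    unapplied_call,
)

#: Minimum alleles tested for a population to be evaluable (strict >).
MIN_ALLELES_TESTED = 2000
#: Minimum allele count for benign-direction eligibility.
MIN_BENIGN_ALLELE_COUNT = 5

#: Built-in threshold table keyed by (category, recessive-group?).
#: Percent values as printed: cancer AD (BS1 >0.1%, PM2_P <0.004%, PM2_M
#: absent); cancer recessive group (>1%, <0.04%, <0.004%); remaining AD
#: (>0.1%, <0.001%, absent); remaining recessive group (>1%, <0.01%,
#: <0.001%).  BA1 is 0.05 for all non-exception genes.
DEFAULT_BA1 = 0.05
_TABLE: dict[tuple[GeneCategory, bool], FrequencyThresholds] = {
    (GeneCategory.cancer, False): FrequencyThresholds(
        ba1=DEFAULT_BA1, bs1_s=0.001, pm2_p=0.00004, pm2_m=None
    ),
    (GeneCategory.cancer, True): FrequencyThresholds(
        ba1=DEFAULT_BA1, bs1_s=0.01, pm2_p=0.0004, pm2_m=0.00004
    ),
    (GeneCategory.general, False): FrequencyThresholds(
        ba1=DEFAULT_BA1, bs1_s=0.001, pm2_p=0.00001, pm2_m=None
    ),
    (GeneCategory.general, True): FrequencyThresholds(
        ba1=DEFAULT_BA1, bs1_s=0.01, pm2_p=0.0001, pm2_m=0.00001
    ),
}


def eligible_populations(
    records: list[FrequencyRecord], for_benign: bool
) -> list[FrequencyRecord]:
    """Filter populations evaluable for frequency criteria.

    ``for_benign=True`` applies the 5-allele presence requirement used for
    BA1/BS1; pathogenic-direction evaluation (PM2) drops it, since
    requiring observed alleles would make absence from controls unusable.
    """
    out = []
    for rec in records:
        if rec.founder_effect or rec.allele_number <= MIN_ALLELES_TESTED:
            continue
        if for_benign and rec.allele_count < MIN_BENIGN_ALLELE_COUNT:
            continue
        out.append(rec)
    return out


def resolve_thresholds(gene: GeneContext) -> FrequencyThresholds:
    """Return the frequency thresholds in force for a gene.

    Per-gene overrides win; otherwise the built-in table row selected by
    gene category and inheritance grouping.  Exception-list genes have no
    default stand-alone threshold and must be configured explicitly.
    """
    if gene.frequency_overrides is not None:
        return gene.frequency_overrides
    if gene.ba1_exception:
        raise ConfigurationError(
            f"gene {gene.symbol} is on the BA1 exception list and needs "
            "explicit per-gene frequency thresholds"
        )
    recessive = gene.inheritance in RECESSIVE_FREQUENCY_GROUP
    return _TABLE[(gene.category, recessive)]


def _exact(threshold: float) -> Fraction:
    """Interpret a threshold as the exact decimal it was written as.

    Thresholds are printed decimals (0.05, 0.001, ...); comparing the
    exact rational AC/AN against the nearest binary float would misplace
    boundary frequencies such as exactly 5%.
    """
    return Fraction(str(threshold))


def _max_frequency(records: list[FrequencyRecord]) -> Optional[Fraction]:
    freqs = [
        Fraction(r.allele_count, r.allele_number) for r in records if r.allele_number > 0
    ]
    return max(freqs) if freqs else None


def evaluate_frequency(
    records: list[FrequencyRecord],
    gene: GeneContext,
    thresholds: Optional[FrequencyThresholds] = None,
) -> Optional[CriterionCall]:
    """Evaluate BA1 / BS1 / PM2; at most one call is ever returned.

    Ordering implements the mutual-exclusivity contract (strongest rule
    first): BA1_A, then BS1_S on the benign-eligible maximum frequency,
    then PM2_M / PM2_P on the pathogenic-eligible maximum.  With no
    evaluable population at all, no call is made (absence cannot be
    asserted without evaluable controls).
    """
    if thresholds is None:
        thresholds = resolve_thresholds(gene)
    override_note = " [THR:gene_override]" if gene.frequency_overrides is not None else ""

    benign_pool = eligible_populations(records, for_benign=True)
    pathogenic_pool = eligible_populations(records, for_benign=False)

    if not pathogenic_pool:
        return unapplied_call(
            Criterion.PM2,
            "insufficient population data: no population passes eligibility "
            "[PM2:insufficient_data]",
        )

    f_max = _max_frequency(benign_pool)
    f_chk = _max_frequency(pathogenic_pool)
    assert f_chk is not None

    if f_max is not None:
        if thresholds.ba1 is not None and f_max >= _exact(thresholds.ba1):
            return applied_call(
                Criterion.BA1,
                Strength.A,
                f"allele frequency {float(f_max):.6g} >= {thresholds.ba1:g} "
                f"[BA1:threshold]{override_note}",
                score=float(f_max),
            )
        if f_max > _exact(thresholds.bs1_s):
            return applied_call(
                Criterion.BS1,
                Strength.S,
                f"allele frequency {float(f_max):.6g} > {thresholds.bs1_s:g} "
                f"[BS1:threshold]{override_note}",
                score=float(f_max),
            )

    absent = all(r.allele_count == 0 for r in pathogenic_pool)
    if thresholds.pm2_m is None:
        if absent:
            return applied_call(
                Criterion.PM2,
                Strength.M,
                f"absent from all eligible control populations [PM2:absent]{override_note}",
                score=0.0,
            )
    elif f_chk < _exact(thresholds.pm2_m):
        tag = "PM2:absent" if absent else "PM2:below_m"
        return applied_call(
            Criterion.PM2,
            Strength.M,
            f"allele frequency {float(f_chk):.6g} < {thresholds.pm2_m:g} "
            f"[{tag}]{override_note}",
            score=float(f_chk),
        )
    if f_chk < _exact(thresholds.pm2_p):
        return applied_call(
            Criterion.PM2,
            Strength.P,
            f"allele frequency {float(f_chk):.6g} < {thresholds.pm2_p:g} "
            f"[PM2:below_p]{override_note}",
            score=float(f_chk),
        )
    return None
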