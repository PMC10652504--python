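"""Variant-type criteria: PVS1 table, PS1/PM5 exclusivity, PM1, PM4, PP2, BP7."""

import itertools

import pytest

from acmg_engine import (
    Consequence,
    Criterion,
    InSilicoScores,
    PriorClassification,
    PriorClassifiedVariant,
    Strength,
    applied_call,
    evaluate_bp7,
    evaluate_pm1,
    evaluate_pm4,
    evaluate_pp2,
    evaluate_ps1_pm5,
    evaluate_pvs1,
)
from acmg_engine.fixtures import lof_gene, make_gene, missense, null_variant, prior


def applied(call):
    return call is not None and call.applied


PM2_M = applied_call(Criterion.PM2, Strength.M, "test")
PM2_P = applied_call(Criterion.PM2, Strength.P, "test")


class TestPvs1:
    def test_nmd_nonsense_in_constrained_gene_is_very_strong(self):
        call = evaluate_pvs1(
            null_variant(Consequence.nonsense, nmd_predicted=True), lof_gene()
        )
        assert call.label() == "PVS1_VS"

    def test_unconstrained_gene_gets_no_call(self):
        gene = make_gene(pli=0.2, o_e=0.8)
        call = evaluate_pvs1(
            null_variant(Consequence.nonsense, nmd_predicted=True), gene
        )
        assert not applied(call)

    def test_curated_mechanism_overrides_metrics(self):
        gene = make_gene(lof_mechanism="established", pli=0.1)
        call = evaluate_pvs1(
            null_variant(Consequence.nonsense, nmd_predicted=True), gene
        )
        assert call.label() == "PVS1_VS"
        gene2 = make_gene(lof_mechanism="not_established", pli=0.99)
        assert not applied(
            evaluate_pvs1(null_variant(Consequence.nonsense, nmd_predicted=True), gene2)
        )

    def test_oe_metric_alone_establishes_mechanism(self):
        gene = make_gene(o_e=0.1)
        call = evaluate_pvs1(
            null_variant(Consequence.frameshift, nmd_predicted=True), gene
        )
        assert call.label() == "PVS1_VS"

    def test_missense_is_out_of_scope(self):
        assert evaluate_pvs1(missense(), lof_gene()) is None

    def test_missing_nmd_field_is_validation_error(self):
        with pytest.raises(ValueError, match="nmd_predicted"):
            evaluate_pvs1(null_variant(Consequence.nonsense), lof_gene())

    @pytest.mark.parametrize(
        "variant, expected",
        [
            (null_variant(Consequence.nonsense, nmd_predicted=False), "PVS1_M"),
            (
                null_variant(
                    Consequence.nonsense,
                    nmd_predicted=False,
                    affected_region_critical=True,
                ),
                "PVS1_S",
            ),
            (
                null_variant(
                    Consequence.canonical_splice,
                    nmd_predicted=False,
                    exon_skip_inframe=True,
                ),
                "PVS1_P",
            ),
            (null_variant(Consequence.initiation_codon), "PVS1_M"),
            (
                null_variant(Consequence.single_multi_exon_deletion, nmd_predicted=True),
                "PVS1_VS",
            ),
        ],
    )
    def test_decision_table_downgrades(self, variant, expected):
        assert evaluate_pvs1(variant, lof_gene()).label() == expected


def _ps1_pm5_oracle(eq_path, eq_lp, diff_path, diff_lp):
    """Clause list transcribed independently of the implementation."""
    if eq_path >= 1 or eq_lp >= 2:
        return "PS1_S"
    if eq_lp == 1:
        return "PS1_M"
    if diff_path >= 1 or diff_lp >= 2:
        return "PM5_M"
    if diff_lp == 1:
        return "PM5_P"
    return None


class TestPs1Pm5:
    def test_exhaustive_report_count_enumeration(self):
        """PS1/PM5 mutual exclusion over all report-count combinations 0-3."""
        scores = InSilicoScores()
        for eq_path, eq_lp, diff_path, diff_lp in itertools.product(range(4), repeat=4):
            priors = []
            if eq_path:
                priors.append(prior(reports=eq_path))
            if eq_lp:
                priors.append(
                    prior(
                        classification=PriorClassification.likely_pathogenic,
                        reports=eq_lp,
                    )
                )
            if diff_path:
                priors.append(prior(alt="W", equivalent=False, reports=diff_path))
            if diff_lp:
                priors.append(
                    prior(
                        alt="W",
                        equivalent=False,
                        classification=PriorClassification.likely_pathogenic,
                        reports=diff_lp,
                    )
                )
            call = evaluate_ps1_pm5(missense(), priors, scores)
            expected = _ps1_pm5_oracle(eq_path, eq_lp, diff_path, diff_lp)
            got = call.label() if applied(call) else None
            assert got == expected, (eq_path, eq_lp, diff_path, diff_lp)

    def test_high_spliceai_suppresses_both(self):
        call = evaluate_ps1_pm5(
            missense(), [prior()], InSilicoScores(spliceai_delta=0.9)
        )
        assert not applied(call)

    def test_aberrant_splicing_assay_suppresses_both(self):
        v = missense(functional_splicing_aberrant=True)
        call = evaluate_ps1_pm5(v, [prior()], InSilicoScores())
        assert not applied(call)

    def test_other_codon_priors_are_ignored(self):
        call = evaluate_ps1_pm5(
            missense(codon=100), [prior(codon=200)], InSilicoScores()
        )
        assert call is None


class TestPm1:
    def test_collagen_glycine_is_strong(self):
        gene = make_gene(special_domain_class="collagen_glycine")
        assert evaluate_pm1(missense(ref="G", alt="S"), gene).label() == "PM1_S"

    def test_collagen_non_glycine_falls_through(self):
        gene = make_gene(special_domain_class="collagen_glycine")
        assert evaluate_pm1(missense(ref="A", alt="S"), gene) is None

    def test_decipher_constraint_boundary_is_strict(self):
        assert evaluate_pm1(
            missense(), make_gene(decipher_missense_constraint=0.4)
        ) is None
        assert (
            evaluate_pm1(missense(), make_gene(decipher_missense_constraint=0.39)).label()
            == "PM1_M"
        )

    def test_hotspot_interval_containment(self):
        gene = make_gene(hotspot_codon_ranges=[(90, 110)])
        assert evaluate_pm1(missense(codon=110), gene).label() == "PM1_M"
        assert evaluate_pm1(missense(codon=111), gene) is None


class TestPm4:
    def test_small_indel_supporting(self):
        v = null_variant(Consequence.inframe_indel, indel_aa_length=2)
        assert evaluate_pm4(v, PM2_M).label() == "PM4_P"

    def test_large_indel_moderate(self):
        v = null_variant(Consequence.inframe_indel, indel_aa_length=5)
        assert evaluate_pm4(v, PM2_P).label() == "PM4_M"

    def test_stop_loss_moderate(self):
        assert evaluate_pm4(null_variant(Consequence.stop_loss), PM2_M).label() == "PM4_M"

    def test_repeat_region_blocks(self):
        v = null_variant(
            Consequence.inframe_indel, indel_aa_length=5, in_repeat_region=True
        )
        assert not applied(evaluate_pm4(v, PM2_P))

    def test_requires_pm2(self):
        v = null_variant(Consequence.inframe_indel, indel_aa_length=2)
        assert not applied(evaluate_pm4(v, None))


class TestPp2:
    @pytest.mark.parametrize(
        "count, z, expected",
        [(5, 3.5, True), (2, 4.0, False), (5, 3.09, False), (3, 3.1, True)],
    )
    def test_both_requirements(self, count, z, expected):
        gene = make_gene(pathogenic_missense_count=count, missense_constraint_z=z)
        assert applied(evaluate_pp2(missense(), gene)) == expected


class TestBp7:
    def test_silent_low_impact(self):
        v = null_variant(Consequence.synonymous)
        call = evaluate_bp7(v, InSilicoScores(spliceai_delta=0.05, gerp=-1.2))
        assert call.label() == "BP7_P"

    @pytest.mark.parametrize(
        "spliceai, gerp", [(0.5, -1.2), (0.05, 0.5), (0.21, -1.0), (0.05, 0.0)]
    )
    def test_threshold_failures(self, spliceai, gerp):
        v = null_variant(Consequence.synonymous)
        assert evaluate_bp7(v, InSilicoScores(spliceai_delta=spliceai, gerp=gerp)) is None

    def test_missense_out_of_scope(self):
        assert evaluate_bp7(missense(), InSilicoScores(spliceai_delta=0.05, gerp=-1)) is None

    def test_missing_score_withholds_with_rationale(self):
        v = null_variant(Consequence.synonymous)
        call = evaluate_bp7(v, InSilicoScores(spliceai_delta=0.05))
        assert not applied(call) and "required" in call.rationale
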