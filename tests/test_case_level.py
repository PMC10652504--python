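"""Case-level scoring systems, proband and meiosis ladders, BS2/BS4/PP4/BP5."""

import itertools

import pytest

from acmg_engine import (
    CaseControlStudy,
    CaseLevelData,
    Criterion,
    DeNovoObservation,
    GeneCategory,
    HealthyCarrierCounts,
    Inheritance,
    PhenotypeMatch,
    RecessiveObservation,
    RecessivePhase,
    Strength,
    applied_call,
    evaluate_bp5,
    evaluate_bs2,
    evaluate_bs4,
    evaluate_pp4,
    evaluate_ps4,
    score_de_novo,
    score_pm3,
    score_pp1,
    ss_strength,
)
from acmg_engine.case_level import recessive_observation_score
from acmg_engine.fixtures import make_gene

PM2_M = applied_call(Criterion.PM2, Strength.M, "test")


def applied(call):
    return call is not None and call.applied


_OBS_KINDS = {
    "in_trans": (RecessivePhase.in_trans_with_PLP, False, 1.0),
    "phase_unknown": (RecessivePhase.phase_unknown, False, 0.5),
    "hom": (RecessivePhase.homozygous, False, 0.5),
    "hom_consang": (RecessivePhase.homozygous, True, 0.25),
}


class TestPm3:
    @pytest.mark.parametrize("kind, score", [(k, v[2]) for k, v in _OBS_KINDS.items()])
    def test_per_observation_scores(self, kind, score):
        phase, consang, _ = _OBS_KINDS[kind]
        obs = RecessiveObservation(phase=phase, consanguineous=consang)
        assert recessive_observation_score(obs) == score

    def test_single_in_trans_reaches_moderate(self):
        ss, call = score_pm3(
            [RecessiveObservation(phase=RecessivePhase.in_trans_with_PLP)]
        )
        assert ss == 1.0 and call.label() == "PM3_M"

    def test_consanguineous_homozygote_alone_below_ladder(self):
        ss, call = score_pm3(
            [RecessiveObservation(phase=RecessivePhase.homozygous, consanguineous=True)]
        )
        assert ss == 0.25 and call is None

    def test_mixed_multiset_sums_to_strong(self):
        obs = (
            [RecessiveObservation(phase=RecessivePhase.in_trans_with_PLP)] * 2
            + [RecessiveObservation(phase=RecessivePhase.phase_unknown)]
            + [RecessiveObservation(phase=RecessivePhase.homozygous)] * 2
        )
        ss, call = score_pm3(obs)
        assert ss == 3.5 and call.label() == "PM3_S"

    def test_dominant_only_gene_gets_no_call(self):
        _, call = score_pm3(
            [RecessiveObservation(phase=RecessivePhase.in_trans_with_PLP)],
            Inheritance.AD,
        )
        assert not applied(call)

    def test_additivity_and_monotone_ladder_brute_force(self):
        """SS is additive over observation multisets and the call is a
        monotone nondecreasing function of SS (all multisets up to size 5)."""
        kinds = list(_OBS_KINDS.values())
        results = []
        for size in range(6):
            for combo in itertools.combinations_with_replacement(kinds, size):
                obs = [
                    RecessiveObservation(phase=phase, consanguineous=consang)
                    for phase, consang, _ in combo
                ]
                expected_ss = sum(score for _, _, score in combo)
                ss, call = score_pm3(obs)
                assert ss == pytest.approx(expected_ss)
                assert (call.strength if call else None) == ss_strength(ss)
                results.append((ss, call.strength if call else None))
        rank = {None: 0, Strength.P: 1, Strength.M: 2, Strength.S: 3, Strength.VS: 4}
        results.sort(key=lambda x: x[0])
        best = 0
        for _, strength in results:
            assert rank[strength] >= best or rank[strength] == best
            best = max(best, rank[strength])


class TestDeNovo:
    def test_confirmed_specific_is_strong(self):
        dn = score_de_novo(
            [DeNovoObservation(confirmed=True, phenotype_match=PhenotypeMatch.highly_specific)]
        )
        assert dn.ps2_ss == 2.0 and dn.ps2_call.label() == "PS2_S"
        assert dn.pm6_call is None

    def test_assumed_consistent_is_supporting(self):
        dn = score_de_novo(
            [DeNovoObservation(confirmed=False, phenotype_match=PhenotypeMatch.consistent)]
        )
        assert dn.pm6_ss == 0.5 and dn.pm6_call.label() == "PM6_P"

    def test_assumed_high_heterogeneity_scores_quarter_point(self):
        dn = score_de_novo(
            [
                DeNovoObservation(
                    confirmed=False,
                    phenotype_match=PhenotypeMatch.consistent_high_heterogeneity,
                )
            ]
        )
        assert dn.pm6_ss == 0.25 and dn.pm6_call is None

    def test_inconsistent_phenotype_scores_zero(self):
        dn = score_de_novo(
            [DeNovoObservation(confirmed=False, phenotype_match=PhenotypeMatch.inconsistent)] * 3
        )
        assert dn.pm6_ss == 0.0 and dn.pm6_call is None and dn.ps2_call is None

    def test_mixed_cohort_feeds_both_pools(self):
        dn = score_de_novo(
            [
                DeNovoObservation(
                    confirmed=True, phenotype_match=PhenotypeMatch.highly_specific
                ),
                DeNovoObservation(
                    confirmed=False, phenotype_match=PhenotypeMatch.consistent
                ),
            ]
        )
        assert dn.ps2_call.label() == "PS2_S" and dn.pm6_call.label() == "PM6_P"

    def test_threshold_ladder_shared_with_pm3(self):
        """PM3/PM6/PS2 share the {0.5,1,2,4} -> {P,M,S,VS} ladder."""
        for ss, expected in [
            (0.0, None), (0.25, None), (0.5, Strength.P), (0.75, Strength.P),
            (1.0, Strength.M), (1.9, Strength.M), (2.0, Strength.S),
            (3.9, Strength.S), (4.0, Strength.VS), (10.0, Strength.VS),
        ]:
            assert ss_strength(ss) == expected


class TestPp1:
    @pytest.mark.parametrize(
        "meioses, expected",
        [(0, None), (2, None), (3, "PP1_P"), (4, "PP1_P"), (5, "PP1_M"),
         (6, "PP1_M"), (7, "PP1_S"), (12, "PP1_S")],
    )
    def test_dominant_ladder(self, meioses, expected):
        call = score_pp1(meioses, Inheritance.AD)
        assert (call.label() if call else None) == expected

    @pytest.mark.parametrize(
        "meioses, expected",
        [(0, None), (1, "PP1_P"), (2, "PP1_M"), (3, "PP1_S"), (8, "PP1_S")],
    )
    def test_recessive_ladder(self, meioses, expected):
        call = score_pp1(meioses, Inheritance.AR)
        assert (call.label() if call else None) == expected


class TestPs4:
    def test_case_control_overrides_proband_counting(self):
        data = CaseLevelData(case_control=CaseControlStudy(odds_ratio=8, ci_low=1.4))
        assert evaluate_ps4(data, make_gene(), None).label() == "PS4_S"

    def test_weak_case_control_falls_through(self):
        data = CaseLevelData(case_control=CaseControlStudy(odds_ratio=8, ci_low=0.9))
        assert evaluate_ps4(data, make_gene(), None) is None

    @pytest.mark.parametrize(
        "count, expected",
        [(0, None), (1, "PS4_P"), (2, "PS4_P"), (3, "PS4_M"), (4, "PS4_M"),
         (5, "PS4_S"), (9, "PS4_S")],
    )
    def test_general_gene_ladder(self, count, expected):
        data = CaseLevelData(proband_count=count)
        call = evaluate_ps4(data, make_gene(), PM2_M)
        assert (call.label() if applied(call) else None) == expected

    @pytest.mark.parametrize(
        "count, expected",
        [(1, None), (2, "PS4_P"), (5, "PS4_P"), (6, "PS4_M"), (9, "PS4_M"),
         (10, "PS4_S")],
    )
    def test_cancer_gene_ladder(self, count, expected):
        data = CaseLevelData(proband_count=count)
        gene = make_gene(category=GeneCategory.cancer)
        call = evaluate_ps4(data, gene, PM2_M)
        assert (call.label() if applied(call) else None) == expected

    def test_counting_requires_pm2(self):
        data = CaseLevelData(proband_count=6)
        assert not applied(evaluate_ps4(data, make_gene(), None))

    def test_counting_requires_dominant_inheritance(self):
        data = CaseLevelData(proband_count=6)
        gene = make_gene(inheritance=Inheritance.AR)
        assert not applied(evaluate_ps4(data, gene, PM2_M))


class TestBs2:
    def test_cancer_homozygote(self):
        gene = make_gene(category=GeneCategory.cancer)
        data = CaseLevelData(healthy_carrier_counts=HealthyCarrierCounts(hom=1))
        assert evaluate_bs2(data, gene).label() == "BS2_S"

    def test_green_list_five_alleles(self):
        gene = make_gene(pediatric_green_list=True)
        data = CaseLevelData(healthy_carrier_counts=HealthyCarrierCounts(het=3, hom=1))
        assert evaluate_bs2(data, gene).label() == "BS2_S"  # 3 + 2 = 5 alleles

    def test_xld_below_five_heterozygotes(self):
        gene = make_gene(inheritance=Inheritance.XLD)
        data = CaseLevelData(healthy_carrier_counts=HealthyCarrierCounts(het=3))
        assert evaluate_bs2(data, gene) is None

    def test_recessive_needs_complete_penetrance(self):
        data = CaseLevelData(healthy_carrier_counts=HealthyCarrierCounts(hom=1))
        gene = make_gene(inheritance=Inheritance.AR)
        assert evaluate_bs2(data, gene) is None
        gene2 = make_gene(inheritance=Inheritance.AR, complete_penetrance=True)
        assert evaluate_bs2(data, gene2).label() == "BS2_S"


class TestBs4Pp4Bp5:
    def test_bs4_restricted_to_early_onset(self):
        data = CaseLevelData(nonsegregation_observed=True)
        assert evaluate_bs4(data, make_gene()) is None
        gene = make_gene(high_penetrance_early_onset=True)
        assert evaluate_bs4(data, gene).label() == "BS4_S"

    def test_pp4_requires_all_four_conditions(self):
        base = dict(
            comprehensive_test=True,
            family_history_consistent=True,
            phenotype_specific_single_etiology=True,
        )
        assert evaluate_pp4(CaseLevelData(**base), PM2_M).label() == "PP4_P"
        for dropped in base:
            data = CaseLevelData(**{k: v for k, v in base.items() if k != dropped})
            assert evaluate_pp4(data, PM2_M) is None
        assert evaluate_pp4(CaseLevelData(**base), None) is None

    def test_pp4_pathognomonic_upgrade(self):
        data = CaseLevelData(
            comprehensive_test=True,
            family_history_consistent=True,
            phenotype_specific_single_etiology=True,
            pathognomonic_extra_evidence=True,
        )
        assert evaluate_pp4(data, PM2_M).label() == "PP4_S"

    def test_bp5_dominant_childhood_onset_only(self):
        data = CaseLevelData(alternate_molecular_cause=True, variant_noncontributory=True)
        assert evaluate_bp5(data, make_gene()) is None
        gene = make_gene(ad_highly_penetrant_childhood_onset=True)
        assert evaluate_bp5(data, gene).label() == "BP5_P"
        gene_ar = make_gene(
            inheritance=Inheritance.AR, ad_highly_penetrant_childhood_onset=True
        )
        assert evaluate_bp5(data, gene_ar) is None
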