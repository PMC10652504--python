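"""Frequency criteria: thresholds, eligibility, exclusivity, monotonicity."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acmg_engine import (
    ConfigurationError,
    Criterion,
    FrequencyRecord,
    FrequencyThresholds,
    GeneCategory,
    Inheritance,
    Strength,
    eligible_populations,
    evaluate_frequency,
    resolve_thresholds,
)
from acmg_engine.fixtures import make_gene


def rec(ac, an=100_000, pop="overall", founder=False):
    return FrequencyRecord(
        population=pop, allele_count=ac, allele_number=an, founder_effect=founder
    )


class TestEligibility:
    def test_benign_keeps_well_sampled_population(self):
        kept = eligible_populations([rec(10, 5000, "AFR")], for_benign=True)
        assert len(kept) == 1

    def test_small_population_dropped(self):
        assert eligible_populations([rec(10, 1500, "EAS")], for_benign=True) == []
        assert eligible_populations([rec(10, 1500, "EAS")], for_benign=False) == []

    def test_five_allele_floor_applies_only_to_benign_direction(self):
        r = [rec(3, 100_000, "NFE")]
        assert eligible_populations(r, for_benign=True) == []
        assert len(eligible_populations(r, for_benign=False)) == 1

    def test_founder_effect_always_excluded(self):
        assert eligible_populations([rec(10, founder=True)], for_benign=False) == []

    def test_exactly_2000_alleles_is_not_enough(self):
        assert eligible_populations([rec(10, 2000)], for_benign=False) == []


class TestResolveThresholds:
    def test_cancer_recessive_row(self):
        thr = resolve_thresholds(
            make_gene(category=GeneCategory.cancer, inheritance=Inheritance.AR)
        )
        assert (thr.ba1, thr.bs1_s, thr.pm2_p, thr.pm2_m) == (
            0.05, 0.01, 0.0004, 0.00004
        )

    def test_general_dominant_row_has_absent_pm2m(self):
        thr = resolve_thresholds(make_gene(inheritance=Inheritance.AD))
        assert (thr.ba1, thr.bs1_s, thr.pm2_p) == (0.05, 0.001, 0.00001)
        assert thr.pm2_m is None

    @pytest.mark.parametrize(
        "inh", [Inheritance.AR, Inheritance.AD_AR, Inheritance.XL, Inheritance.XLR,
                Inheritance.XLD]
    )
    def test_recessive_group_shares_the_ar_row(self, inh):
        thr = resolve_thresholds(make_gene(inheritance=inh))
        assert thr.bs1_s == 0.01

    def test_override_returned_verbatim(self):
        ovr = FrequencyThresholds(ba1=0.02, bs1_s=0.005, pm2_p=0.0001, pm2_m=0.00001)
        gene = make_gene(frequency_overrides=ovr)
        assert resolve_thresholds(gene) is ovr

    def test_exception_gene_without_override_is_config_error(self):
        with pytest.raises(ConfigurationError, match="exception"):
            resolve_thresholds(make_gene(ba1_exception=True))

    @pytest.mark.parametrize("category", list(GeneCategory))
    @pytest.mark.parametrize("inh", [Inheritance.AD, Inheritance.AR])
    def test_builtin_rows_satisfy_ordering_invariant(self, category, inh):
        thr = resolve_thresholds(make_gene(category=category, inheritance=inh))
        assert thr.ba1 > thr.bs1_s > thr.pm2_p
        if thr.pm2_m is not None:
            assert thr.pm2_p >= thr.pm2_m


class TestEvaluateFrequency:
    def test_ba1_at_five_percent(self):
        call = evaluate_frequency([rec(6000)], make_gene())
        assert call.label() == "BA1_A"

    def test_bs1_above_dominant_threshold(self):
        call = evaluate_frequency([rec(200)], make_gene())
        assert call.label() == "BS1_S"

    def test_pm2_supporting_band_cancer_recessive(self):
        gene = make_gene(category=GeneCategory.cancer, inheritance=Inheritance.AR)
        call = evaluate_frequency([rec(30)], gene)  # 3e-4 in [4e-5, 4e-4)
        assert call.label() == "PM2_P"

    def test_pm2_moderate_when_absent_recessive(self):
        gene = make_gene(inheritance=Inheritance.AR)
        call = evaluate_frequency([rec(0)], gene)
        assert call.label() == "PM2_M"

    def test_no_eligible_population_withholds_pm2(self):
        call = evaluate_frequency([rec(0, an=1500)], make_gene())
        assert call is not None and not call.applied
        assert "insufficient" in call.rationale

    def test_exception_gene_ba1_disabled_without_threshold(self):
        ovr = FrequencyThresholds(ba1=None, bs1_s=0.01, pm2_p=0.0001, pm2_m=0.00001)
        gene = make_gene(ba1_exception=True, frequency_overrides=ovr)
        call = evaluate_frequency([rec(6000)], gene)  # 6% but BA1 disabled
        assert call.label() == "BS1_S"

    def test_boundary_bs1_is_strict(self):
        # exactly 0.1% for a general AD gene: printed symbol is ">"
        call = evaluate_frequency([rec(100)], make_gene())
        assert call is None

    def test_boundary_ba1_is_inclusive(self):
        call = evaluate_frequency([rec(5000)], make_gene())
        assert call.label() == "BA1_A"


#: pathogenic-direction scale for the monotonicity check
_SCALE = {"PM2_M": 4, "PM2_P": 3, None: 2, "BS1_S": 1, "BA1_A": 0}


def _scale(call):
    if call is None or not call.applied:
        return _SCALE[None]
    return _SCALE[call.label()]


class TestFrequencyProperties:
    @pytest.mark.parametrize("category", list(GeneCategory))
    @pytest.mark.parametrize("inh", [Inheritance.AD, Inheritance.AR])
    def test_mutual_exclusivity_on_ac_grid(self, category, inh):
        """At most one of BA1/BS1/PM2 for every allele count."""
        gene = make_gene(category=category, inheritance=inh)
        an = 100_000
        grid = [0, 1, 3, 4, 5, 10, 30, 50, 99, 100, 101, 500, 999, 1000,
                1001, 4999, 5000, 5001, 60_000]
        for ac in grid:
            call = evaluate_frequency([rec(ac, an)], gene)
            calls = [call] if call is not None and call.applied else []
            assert len(calls) <= 1
            if calls:
                assert calls[0].criterion in (Criterion.BA1, Criterion.BS1, Criterion.PM2)

    @settings(derandomize=True, max_examples=200)
    @given(
        ac=st.integers(min_value=0, max_value=90_000),
        bump=st.integers(min_value=1, max_value=10_000),
        category=st.sampled_from(list(GeneCategory)),
        inh=st.sampled_from([Inheritance.AD, Inheritance.AR]),
    )
    def test_increasing_allele_count_never_moves_pathogenic(
        self, ac, bump, category, inh
    ):
        gene = make_gene(category=category, inheritance=inh)
        before = evaluate_frequency([rec(ac)], gene)
        after = evaluate_frequency([rec(ac + bump)], gene)
        assert _scale(after) <= _scale(before)

    def test_populations_failing_eligibility_are_ignored_not_absent(self):
        """A founder population with carriers does not defeat PM2 absence."""
        gene = make_gene()
        call = evaluate_frequency([rec(0), rec(500, founder=True)], gene)
        assert call.label() == "PM2_M"
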