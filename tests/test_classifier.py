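"""Conflict resolution, combining rules vs. brute force, Bayesian posterior."""

import itertools
import math
import random

import pytest

from acmg_engine import (
    Criterion,
    Strength,
    StrengthCount,
    Tier,
    applied_call,
    audit_consistency,
    classify_calls,
    classify_counts,
    classify_rule_based,
    compute_posterior,
    evidence_odds,
    posterior_category,
    resolve_conflicts,
)
from acmg_engine.classifier import net_points, posterior_from_points


def call(code, strength):
    return applied_call(Criterion(code), Strength(strength), "test")


class TestResolveConflicts:
    def test_ba1_beats_pm2(self):
        resolved = resolve_conflicts([call("BA1", "A"), call("PM2", "M")])
        labels = [c.label() for c in resolved if c.applied]
        assert labels == ["BA1_A"]

    def test_ps1_beats_pm5(self):
        resolved = resolve_conflicts([call("PS1", "S"), call("PM5", "M")])
        labels = [c.label() for c in resolved if c.applied]
        assert labels == ["PS1_S"]

    def test_single_call_unchanged(self):
        resolved = resolve_conflicts([call("PM2", "M")])
        assert [c.label() for c in resolved if c.applied] == ["PM2_M"]

    def test_equal_strength_tie_breaks_pathogenic(self):
        resolved = resolve_conflicts([call("BS4", "S"), call("PP1", "S")])
        labels = [c.label() for c in resolved if c.applied]
        assert labels == ["PP1_S"]

    def test_caution_group_caps_at_two(self):
        resolved = resolve_conflicts(
            [call("PM3", "S"), call("PS4", "M"), call("PP1", "P")]
        )
        labels = sorted(c.label() for c in resolved if c.applied)
        assert labels == ["PM3_S", "PS4_M"]

    def test_caution_cap_configurable(self):
        resolved = resolve_conflicts(
            [call("PM3", "S"), call("PS4", "M"), call("PP1", "P")], caution_cap=3
        )
        assert sum(c.applied for c in resolved) == 3

    def test_demoted_calls_stay_in_audit(self):
        resolved = resolve_conflicts([call("BA1", "A"), call("PM2", "M")])
        pm2 = next(c for c in resolved if c.criterion == Criterion.PM2)
        assert not pm2.applied and "demoted" in pm2.rationale


def _oracle_tier(vs, s, m, p, bs, bp, ba1):
    """Independent transcription of the 19 combining rules."""
    pathogenic = (
        (vs >= 1 and s >= 1)
        or (vs >= 1 and m >= 2)
        or (vs >= 1 and m >= 1 and p >= 1)
        or (vs >= 1 and p >= 2)
        or s >= 2
        or (s >= 1 and m >= 3)
        or (s >= 1 and m == 2 and p >= 2)
        or (s >= 1 and m == 1 and p >= 4)
    )
    likely_pathogenic = (
        (vs >= 1 and m >= 1)
        or (s >= 1 and 1 <= m <= 2)
        or (s >= 1 and p >= 2)
        or m >= 3
        or (m >= 2 and p >= 2)
        or (m >= 1 and p >= 4)
    )
    benign = ba1 or bs >= 2
    likely_benign = (bs >= 1 and bp >= 1) or bp >= 2
    path_side = "P" if pathogenic else ("LP" if likely_pathogenic else None)
    ben_side = "B" if benign else ("LB" if likely_benign else None)
    if path_side and ben_side:
        return Tier.VUS
    if path_side:
        return Tier.pathogenic if path_side == "P" else Tier.likely_pathogenic
    if ben_side:
        return Tier.benign if ben_side == "B" else Tier.likely_benign
    return Tier.VUS


class TestCombiningRules:
    def test_rule_matcher_equals_brute_force_up_to_six_calls(self):
        """classify_counts agrees with an independently written matcher on
        every strength-count vector with at most 6 calls."""
        checked = 0
        for vs, s, m, p, bs, bp in itertools.product(range(7), repeat=6):
            if vs + s + m + p + bs + bp > 6:
                continue
            for ba1 in (False, True):
                sc = StrengthCount(
                    path_vs=vs, path_s=s, path_m=m, path_p=p,
                    ben_s=bs, ben_p=bp, ba1_present=ba1,
                )
                assert classify_counts(sc).tier == _oracle_tier(vs, s, m, p, bs, bp, ba1)
                checked += 1
        assert checked > 1500

    @pytest.mark.parametrize(
        "calls, tier, rule",
        [
            ([call("PVS1", "VS"), call("PM2", "P")], Tier.likely_pathogenic, "3B"),
            ([call("PS4", "S"), call("PS3", "S")], Tier.pathogenic, "4E"),
            ([call("PM2", "M")], Tier.VUS, None),
            ([call("BA1", "A")], Tier.benign, "1A"),
            ([call("PVS1", "VS"), call("PM2", "M")], Tier.likely_pathogenic, "3A"),
        ],
    )
    def test_enumerated_examples(self, calls, tier, rule):
        match = classify_rule_based(calls)
        assert match.tier == tier and match.matched_rule == rule

    def test_conflicting_directions_yield_vus_with_both_rules(self):
        match = classify_rule_based(
            [call("PS3", "S"), call("PS4", "S"), call("BS1", "S"), call("BS2", "S")]
        )
        assert match.tier == Tier.VUS
        assert match.conflicting_directions and len(match.matched_rules) == 2


class TestEvidenceOdds:
    def test_printed_ladder_to_three_significant_figures(self):
        assert round(evidence_odds(Strength.P), 2) == 2.08
        assert round(evidence_odds(Strength.M), 2) == 4.33
        assert round(evidence_odds(Strength.S), 1) == 18.7
        assert evidence_odds(Strength.VS) == 350.0

    def test_exponent_additivity(self):
        assert evidence_odds(Strength.M) ** 2 == pytest.approx(
            evidence_odds(Strength.S)
        )
        assert evidence_odds(Strength.P) ** 8 == pytest.approx(350.0)


#: palette of valid applied calls for randomized multisets
_PALETTE = (
    [("PVS1", s) for s in ("P", "M", "S", "VS")]
    + [("PS3", s) for s in ("P", "M", "S", "VS")]
    + [("PM3", s) for s in ("P", "M", "S", "VS")]
    + [("PP1", s) for s in ("P", "M", "S")]
    + [("BS3", s) for s in ("P", "M", "S")]
    + [("BS1", "S"), ("BP4", "P"), ("BP7", "P"), ("BA1", "A")]
)


class TestPosterior:
    def test_two_strong_reproduce_printed_value(self):
        assert round(compute_posterior([call("PS3", "S"), call("PS4", "S")]), 3) == 0.975

    def test_very_strong_plus_moderate_reproduce_printed_value(self):
        assert round(compute_posterior([call("PVS1", "VS"), call("PM2", "M")]), 3) == 0.994

    def test_no_calls_returns_prior(self):
        assert compute_posterior([], prior=0.1) == pytest.approx(0.1)

    def test_invalid_prior_rejected(self):
        with pytest.raises(ValueError):
            compute_posterior([call("PS3", "S")], prior=1.5)

    def test_ba1_scores_as_eight_benign_points(self):
        assert compute_posterior([call("BA1", "A")]) == pytest.approx(
            posterior_from_points(-8)
        )

    def test_monotone_under_added_evidence(self):
        """Adding pathogenic evidence never lowers the posterior; adding
        benign evidence never raises it (1,000 random call multisets)."""
        rng = random.Random(20231116)
        for _ in range(1000):
            base = [
                call(c, s) for c, s in rng.choices(_PALETTE, k=rng.randint(0, 6))
            ]
            before = compute_posterior(base)
            extra_code, extra_strength = rng.choice(_PALETTE)
            extra = call(extra_code, extra_strength)
            after = compute_posterior(base + [extra])
            if extra.criterion.value.startswith("B"):
                assert after <= before + 1e-12
            else:
                assert after >= before - 1e-12

    def test_depends_only_on_net_points(self):
        """Equal net point totals give identical posteriors (additivity)."""
        rng = random.Random(7)
        for _ in range(200):
            calls = [call(c, s) for c, s in rng.choices(_PALETTE, k=rng.randint(1, 6))]
            pts = net_points(calls)
            assert compute_posterior(calls) == pytest.approx(posterior_from_points(pts))
        # an explicit substitution: one Strong == two Moderate
        a = compute_posterior([call("PS3", "S")])
        b = compute_posterior([call("PM3", "M"), call("PM2", "M")])
        assert a == pytest.approx(b)


class TestPosteriorCategory:
    @pytest.mark.parametrize(
        "post_p, tier",
        [
            (0.994, Tier.pathogenic),
            (0.975, Tier.likely_pathogenic),
            (0.90, Tier.likely_pathogenic),
            (0.50, Tier.VUS),
            (0.05, Tier.likely_benign),
            (0.0005, Tier.benign),
        ],
    )
    def test_boundaries(self, post_p, tier):
        assert posterior_category(post_p) == tier


class TestAuditConsistency:
    def test_flags_exactly_the_two_printed_inconsistencies(self):
        report = audit_consistency()
        flagged = sorted(e.rule_id for e in report if not e.consistent)
        assert flagged == ["3A", "4E"]

    def test_rule_3b_minimal_set_inside_likely_pathogenic_range(self):
        report = {e.rule_id: e for e in audit_consistency()}
        assert 0.90 <= round(report["3B"].post_p, 3) <= 0.99
        assert report["3B"].consistent

    def test_all_pathogenic_rules_except_4e_exceed_099(self):
        for entry in audit_consistency():
            if entry.rule_id.startswith("4") and entry.rule_id != "4E":
                assert entry.post_p > 0.99

    def test_report_covers_all_nineteen_rules(self):
        assert len(audit_consistency()) == 19


class TestClassifyCalls:
    def test_both_paths_reported_side_by_side(self):
        result = classify_calls("v1", [call("PS3", "S"), call("PS4", "S")])
        assert result.tier == Tier.pathogenic  # rule 4E
        assert result.posterior_tier == Tier.likely_pathogenic  # post_p 0.975
        assert round(result.post_p, 3) == 0.975
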