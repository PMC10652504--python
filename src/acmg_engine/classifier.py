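"""Conflict resolution, combining rules and the Bayesian posterior.

The rule-based path applies the 19 enumerated combining rules to the
resolved criterion calls and yields one of the five classification tiers.
The Bayesian path maps strengths to exponentially scaled odds of
pathogenicity (supporting 2.08, moderate 4.33, strong 18.7, very strong
350 — i.e. 350**(pts/8) with points 1/2/4/8), combines them additively in
point space and converts the combined odds to a posterior probability of
pathogenicity under a configurable prior.  Both outputs are reported side
by side; in particular BA1 is honored as stand-alone benign by the
rule-based path but scored as 8 benign points by the posterior path,
since an absolute criterion has no Bayesian analogue.
"""

from __future__ import annotations

import itertools
import logging
from enum import Enum
from typing import Optional, Sequence

from pydantic import BaseModel, Field

from .model import (
    Criterion,
    CriterionCall,
    Direction,
    STRENGTH_POINTS,
    STRENGTH_RANK,
    Strength,
)

logger = logging.getLogger("acmg_engine")

#: Odds of pathogenicity for very strong evidence; the anchor of the
#: exponential scaling.
ODDS_VERY_STRONG = 350.0
#: Default prior probability of pathogenicity.
DEFAULT_PRIOR = 0.10
#: Benign points contributed by stand-alone BA1 on the posterior path.
DEFAULT_BA1_POINTS = 8

#: Mutually exclusive criterion sets: only the strongest call survives.
EXCLUSIVITY_SETS: tuple[frozenset[Criterion], ...] = (
    frozenset({Criterion.BA1, Criterion.BS1, Criterion.PM2}),
    frozenset({Criterion.PP3, Criterion.BP4, Criterion.BP7}),
    frozenset({Criterion.BP3, Criterion.PM4, Criterion.PVS1}),
    frozenset({Criterion.PS1, Criterion.PM5}),
    frozenset({Criterion.PS3, Criterion.BS3}),
    frozenset({Criterion.BS4, Criterion.PP1}),
)

#: Overlapping criteria whose simultaneous use requires caution: at most
#: ``caution_cap`` (default 2) of each group count toward classification.
CAUTION_GROUPS: tuple[frozenset[Criterion], ...] = (
    frozenset({Criterion.PM1, Criterion.PP2}),
    frozenset({Criterion.PM1, Criterion.PM5}),
    frozenset({Criterion.PS2, Criterion.PM6}),
    frozenset({Criterion.PM3, Criterion.PS4, Criterion.PP1}),
)


class Tier(str, Enum):
    pathogenic = "pathogenic"
    likely_pathogenic = "likely_pathogenic"
    VUS = "VUS"
    likely_benign = "likely_benign"
    benign = "benign"


# ---------------------------------------------------------------------------
# Conflict resolution
# ---------------------------------------------------------------------------

def _call_rank(call: CriterionCall) -> tuple[int, int]:
    """Sort key: strength first, pathogenic direction breaks ties."""
    assert call.strength is not None
    return (STRENGTH_RANK[call.strength], 1 if call.direction == Direction.pathogenic else 0)


def resolve_conflicts(
    calls: Sequence[CriterionCall], caution_cap: int = 2
) -> list[CriterionCall]:
    """Enforce exclusivity sets and caution caps over evaluated calls.

    Within each mutually exclusive set the strongest applied call is kept
    (stand-alone > very strong > strong > moderate > supporting); an
    equal-strength tie is broken toward the pathogenic direction with a
    logged warning.  Within each caution group at most ``caution_cap``
    calls remain applied.  Demoted calls stay in the audit trail with
    ``applied=False`` and an annotated rationale.
    """
    out = [c.model_copy(deep=True) for c in calls]
    by_criterion: dict[Criterion, CriterionCall] = {}
    for c in out:
        if c.applied:
            by_criterion[c.criterion] = c

    def demote(call: CriterionCall, reason: str) -> None:
        call.applied = False
        call.strength = None
        call.rationale = (call.rationale + f" | demoted: {reason}").strip(" |")

    for group in EXCLUSIVITY_SETS:
        members = [by_criterion[c] for c in group if c in by_criterion and by_criterion[c].applied]
        if len(members) <= 1:
            continue
        members.sort(key=_call_rank, reverse=True)
        winner = members[0]
        if _call_rank(members[1])[0] == _call_rank(winner)[0]:
            logger.warning(
                "equal-strength conflict between %s and %s resolved toward the "
                "pathogenic direction",
                winner.label(),
                members[1].label(),
            )
        for loser in members[1:]:
            demote(loser, f"mutually exclusive with {winner.criterion.value}")

    for group in CAUTION_GROUPS:
        members = [by_criterion[c] for c in group if c in by_criterion and by_criterion[c].applied]
        if len(members) <= caution_cap:
            continue
        members.sort(key=_call_rank, reverse=True)
        for loser in members[caution_cap:]:
            demote(
                loser,
                "caution cap: overlapping criteria "
                f"({', '.join(sorted(c.value for c in group))}) limited to "
                f"{caution_cap}",
            )
    return out


# ---------------------------------------------------------------------------
# Combining rules
# ---------------------------------------------------------------------------

class StrengthCount(BaseModel):
    """Applied-call tallies per direction, the input to the rule matcher."""

    path_vs: int = Field(default=0, ge=0)
    path_s: int = Field(default=0, ge=0)
    path_m: int = Field(default=0, ge=0)
    path_p: int = Field(default=0, ge=0)
    ben_s: int = Field(default=0, ge=0)
    ben_p: int = Field(default=0, ge=0)
    ba1_present: bool = False
    #: rule 3B is criterion-specific: PVS1 at VS together with PM2 at P
    pvs1_vs_and_pm2_p: bool = False


def count_strengths(calls: Sequence[CriterionCall]) -> StrengthCount:
    sc = StrengthCount()
    labels = {c.label() for c in calls if c.applied}
    sc.pvs1_vs_and_pm2_p = "PVS1_VS" in labels and "PM2_P" in labels
    for c in calls:
        if not c.applied or c.strength is None:
            continue
        if c.strength == Strength.A:
            sc.ba1_present = True
            continue
        key = {
            (Direction.pathogenic, Strength.VS): "path_vs",
            (Direction.pathogenic, Strength.S): "path_s",
            (Direction.pathogenic, Strength.M): "path_m",
            (Direction.pathogenic, Strength.P): "path_p",
            (Direction.benign, Strength.S): "ben_s",
            (Direction.benign, Strength.P): "ben_p",
        }.get((c.direction, c.strength))
        if key is None:
            # benign VS/M have no combining-rule slot; they still count
            # toward the posterior but not the rule matcher
            logger.debug("no combining-rule slot for %s", c.label())
            continue
        setattr(sc, key, getattr(sc, key) + 1)
    return sc


#: The 19 combining rules, in evaluation order within each tier.
PATHOGENIC_RULES: tuple[tuple[str, str], ...] = (
    ("4A", "1 Very Strong AND >=1 Strong"),
    ("4B", "1 Very Strong AND >=2 Moderate"),
    ("4C", "1 Very Strong AND 1 Moderate AND 1 Supporting"),
    ("4D", "1 Very Strong AND >=2 Supporting"),
    ("4E", ">=2 Strong"),
    ("4F", "1 Strong AND >=3 Moderate"),
    ("4G", "1 Strong AND 2 Moderate AND >=2 Supporting"),
    ("4H", "1 Strong AND 1 Moderate AND >=4 Supporting"),
)
LIKELY_PATHOGENIC_RULES: tuple[tuple[str, str], ...] = (
    ("3A", "1 Very Strong AND 1 Moderate"),
    ("3B", "PVS1_VS AND PM2_P"),
    ("3C", "1 Strong AND 1-2 Moderate"),
    ("3D", "1 Strong AND >=2 Supporting"),
    ("3E", ">=3 Moderate"),
    ("3F", "2 Moderate AND >=2 Supporting"),
    ("3G", "1 Moderate AND >=4 Supporting"),
)
BENIGN_RULES: tuple[tuple[str, str], ...] = (
    ("1A", "Stand-alone BA1"),
    ("1B", ">=2 Strong benign"),
)
LIKELY_BENIGN_RULES: tuple[tuple[str, str], ...] = (
    ("2A", "1 Strong benign AND 1 Supporting benign"),
    ("2B", ">=2 Supporting benign"),
)

ALL_RULE_IDS = tuple(
    rid
    for rid, _ in BENIGN_RULES + LIKELY_BENIGN_RULES + LIKELY_PATHOGENIC_RULES + PATHOGENIC_RULES
)
assert len(ALL_RULE_IDS) == 19


def _rule_matches(rule_id: str, sc: StrengthCount) -> bool:
    vs, s, m, p = sc.path_vs, sc.path_s, sc.path_m, sc.path_p
    bs, bp = sc.ben_s, sc.ben_p
    return {
        "4A": vs >= 1 and s >= 1,
        "4B": vs >= 1 and m >= 2,
        "4C": vs >= 1 and m >= 1 and p >= 1,
        "4D": vs >= 1 and p >= 2,
        "4E": s >= 2,
        "4F": s >= 1 and m >= 3,
        "4G": s >= 1 and m == 2 and p >= 2,
        "4H": s >= 1 and m == 1 and p >= 4,
        "3A": vs >= 1 and m >= 1,
        "3B": sc.pvs1_vs_and_pm2_p,
        "3C": s >= 1 and 1 <= m <= 2,
        "3D": s >= 1 and p >= 2,
        "3E": m >= 3,
        "3F": m >= 2 and p >= 2,
        "3G": m >= 1 and p >= 4,
        "1A": sc.ba1_present,
        "1B": bs >= 2,
        "2A": bs >= 1 and bp >= 1,
        "2B": bp >= 2,
    }[rule_id]


class RuleMatch(BaseModel):
    tier: Tier
    matched_rule: Optional[str] = None
    matched_rules: list[str] = Field(default_factory=list)
    conflicting_directions: bool = False


def classify_counts(sc: StrengthCount) -> RuleMatch:
    """Match the strength-count vector against the 19 combining rules."""
    path_rule = next((rid for rid, _ in PATHOGENIC_RULES if _rule_matches(rid, sc)), None)
    lp_rule = next(
        (rid for rid, _ in LIKELY_PATHOGENIC_RULES if _rule_matches(rid, sc)), None
    )
    ben_rule = next((rid for rid, _ in BENIGN_RULES if _rule_matches(rid, sc)), None)
    lb_rule = next((rid for rid, _ in LIKELY_BENIGN_RULES if _rule_matches(rid, sc)), None)

    path_best = path_rule or lp_rule
    ben_best = ben_rule or lb_rule
    if path_best and ben_best:
        logger.warning(
            "combining rules match in both directions (%s vs %s); tier is VUS",
            path_best,
            ben_best,
        )
        return RuleMatch(
            tier=Tier.VUS,
            matched_rules=[path_best, ben_best],
            conflicting_directions=True,
        )
    if path_best:
        tier = Tier.pathogenic if path_rule else Tier.likely_pathogenic
        return RuleMatch(tier=tier, matched_rule=path_best, matched_rules=[path_best])
    if ben_best:
        tier = Tier.benign if ben_rule else Tier.likely_benign
        return RuleMatch(tier=tier, matched_rule=ben_best, matched_rules=[ben_best])
    return RuleMatch(tier=Tier.VUS)


def classify_rule_based(calls: Sequence[CriterionCall]) -> RuleMatch:
    """Rule-based five-tier classification of resolved criterion calls."""
    return classify_counts(count_strengths(calls))


# ---------------------------------------------------------------------------
# Bayesian posterior
# ---------------------------------------------------------------------------

def evidence_odds(strength: Strength) -> float:
    """Odds of pathogenicity for one piece of evidence at ``strength``.

    The exponential scaling anchored at 350 for very strong:
    350**(1/8) ~= 2.08 (supporting), 350**(1/4) ~= 4.33 (moderate),
    350**(1/2) ~= 18.7 (strong), 350 (very strong).
    """
    pts = STRENGTH_POINTS[strength]
    return ODDS_VERY_STRONG ** (pts / 8.0)


def net_points(
    calls: Sequence[CriterionCall], ba1_points: int = DEFAULT_BA1_POINTS
) -> int:
    """Net evidence points: pathogenic minus benign, BA1 as benign points."""
    total = 0
    for c in calls:
        if not c.applied or c.strength is None:
            continue
        if c.strength == Strength.A:
            total -= ba1_points
        else:
            total += c.points
    return total


def posterior_from_points(pts: float, prior: float = DEFAULT_PRIOR) -> float:
    if not 0 < prior < 1:
        raise ValueError("prior must lie strictly between 0 and 1")
    odds_path = ODDS_VERY_STRONG ** (pts / 8.0)
    return odds_path * prior / ((odds_path - 1.0) * prior + 1.0)


def compute_posterior(
    calls: Sequence[CriterionCall],
    prior: float = DEFAULT_PRIOR,
    ba1_points: int = DEFAULT_BA1_POINTS,
) -> float:
    """Posterior probability of pathogenicity for resolved calls.

    Points are summed across applied calls (supporting 1, moderate 2,
    strong 4, very strong 8; benign negative; BA1 as ``ba1_points``
    benign), combined odds are 350**(points/8), and Bayes' rule converts
    odds to a probability under ``prior``.
    """
    return posterior_from_points(net_points(calls, ba1_points=ba1_points), prior=prior)


class PosteriorBoundaries(BaseModel):
    """Tier boundaries on the posterior scale.

    The pathogenic-side boundaries (likely pathogenic 0.90-0.99,
    pathogenic > 0.99) follow the adopted Bayesian framework; the
    benign-side defaults (benign < 0.001, likely benign < 0.10) come from
    the same framework and are configurable because different services
    print different benign cut-offs.
    """

    pathogenic_gt: float = 0.99
    likely_pathogenic_min: float = 0.90
    likely_benign_lt: float = 0.10
    benign_lt: float = 0.001


DEFAULT_BOUNDARIES = PosteriorBoundaries()


def posterior_category(
    post_p: float, boundaries: PosteriorBoundaries = DEFAULT_BOUNDARIES
) -> Tier:
    """Map a posterior probability to the five-tier scale."""
    if post_p > boundaries.pathogenic_gt:
        return Tier.pathogenic
    if post_p >= boundaries.likely_pathogenic_min:
        return Tier.likely_pathogenic
    if post_p < boundaries.benign_lt:
        return Tier.benign
    if post_p < boundaries.likely_benign_lt:
        return Tier.likely_benign
    return Tier.VUS


# ---------------------------------------------------------------------------
# Rule-consistency audit
# ---------------------------------------------------------------------------

#: Minimal satisfying strength multiset per combining rule (signed points:
#: pathogenic positive, benign negative).
RULE_MINIMAL_SETS: dict[str, tuple[str, ...]] = {
    "1A": ("A-",),
    "1B": ("S-", "S-"),
    "2A": ("S-", "P-"),
    "2B": ("P-", "P-"),
    "3A": ("VS", "M"),
    "3B": ("VS", "P"),
    "3C": ("S", "M"),
    "3D": ("S", "P", "P"),
    "3E": ("M", "M", "M"),
    "3F": ("M", "M", "P", "P"),
    "3G": ("M", "P", "P", "P", "P"),
    "4A": ("VS", "S"),
    "4B": ("VS", "M", "M"),
    "4C": ("VS", "M", "P"),
    "4D": ("VS", "P", "P"),
    "4E": ("S", "S"),
    "4F": ("S", "M", "M", "M"),
    "4G": ("S", "M", "M", "P", "P"),
    "4H": ("S", "M", "P", "P", "P", "P"),
}

_RULE_TIER = {
    "1": Tier.benign,
    "2": Tier.likely_benign,
    "3": Tier.likely_pathogenic,
    "4": Tier.pathogenic,
}

_TOKEN_POINTS = {
    "P": 1, "M": 2, "S": 4, "VS": 8,
    "P-": -1, "M-": -2, "S-": -4, "A-": -8,
}


class RuleAudit(BaseModel):
    rule_id: str
    description: str
    minimal_set: tuple[str, ...]
    points: int
    post_p: float
    expected_tier: Tier
    posterior_tier: Tier
    consistent: bool


def audit_consistency(
    prior: float = DEFAULT_PRIOR,
    boundaries: PosteriorBoundaries = DEFAULT_BOUNDARIES,
) -> list[RuleAudit]:
    """Check every combining rule's minimal call set against its tier.

    For each rule the minimal satisfying strength multiset is scored on
    the posterior path and the resulting probability (rounded to the
    3-decimal reporting precision) is mapped back to a tier; rules whose
    posterior tier differs from their rule-based tier are flagged as
    mathematically inconsistent with the Bayesian framework.
    """
    descriptions = dict(
        BENIGN_RULES + LIKELY_BENIGN_RULES + LIKELY_PATHOGENIC_RULES + PATHOGENIC_RULES
    )
    report = []
    for rule_id in ALL_RULE_IDS:
        minimal = RULE_MINIMAL_SETS[rule_id]
        pts = sum(_TOKEN_POINTS[t] for t in minimal)
        post_p = posterior_from_points(pts, prior=prior)
        expected = _RULE_TIER[rule_id[0]]
        observed = posterior_category(round(post_p, 3), boundaries)
        report.append(
            RuleAudit(
                rule_id=rule_id,
                description=descriptions[rule_id],
                minimal_set=minimal,
                points=pts,
                post_p=post_p,
                expected_tier=expected,
                posterior_tier=observed,
                consistent=observed == expected,
            )
        )
    return report


# ---------------------------------------------------------------------------
# Classification result
# ---------------------------------------------------------------------------

class RecordStatus(str, Enum):
    classified = "classified"
    vcep_delegate = "vcep_delegate"
    not_classifiable = "not_classifiable"
    error = "error"


class Classification(BaseModel):
    """Final result for one variant: tier, matched rule, posterior, audit."""

    record_id: str
    status: RecordStatus
    tier: Optional[Tier] = None
    matched_rule: Optional[str] = None
    matched_rules: list[str] = Field(default_factory=list)
    post_p: Optional[float] = None
    posterior_tier: Optional[Tier] = None
    prior: float = DEFAULT_PRIOR
    points: Optional[int] = None
    audit: list[CriterionCall] = Field(default_factory=list)
    message: str = ""

    def applied_labels(self) -> list[str]:
        return sorted(c.label() for c in self.audit if c.applied)


def classify_calls(
    record_id: str,
    calls: Sequence[CriterionCall],
    prior: float = DEFAULT_PRIOR,
    caution_cap: int = 2,
    ba1_points: int = DEFAULT_BA1_POINTS,
    boundaries: PosteriorBoundaries = DEFAULT_BOUNDARIES,
) -> Classification:
    """Resolve conflicts, then run both classification paths."""
    resolved = resolve_conflicts(calls, caution_cap=caution_cap)
    match = classify_rule_based(resolved)
    pts = net_points(resolved, ba1_points=ba1_points)
    post_p = posterior_from_points(pts, prior=prior)
    return Classification(
        record_id=record_id,
        status=RecordStatus.classified,
        tier=match.tier,
        matched_rule=match.matched_rule,
        matched_rules=match.matched_rules,
        post_p=post_p,
        posterior_tier=posterior_category(round(post_p, 3), boundaries),
        prior=prior,
        points=pts,
        audit=list(resolved),
    )
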