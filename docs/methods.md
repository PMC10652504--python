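# Methods

## Scope and design

The engine implements rule-based interpretation of constitutional
single-nucleotide variants and small indels in Mendelian disease genes.
It deliberately separates three concerns:

1. **Evidence acquisition** is out of scope. Population frequencies,
   in-silico scores, functional-assay strengths and case-level
   observations arrive pre-annotated in the evidence record. The engine
   never queries gnomAD/ClinVar-like resources and never touches a
   reference genome.
2. **Per-criterion evaluation** turns evidence into at most one call per
   ACMG/AMP criterion, each with a modulated strength and a rationale
   string carrying machine-readable clause tags (used for branch-coverage
   accounting in the test suite).
3. **Combination** resolves inter-criterion conflicts, applies the 19
   combining rules, and computes a Bayesian posterior probability of
   pathogenicity. Both the rule-based tier and the posterior are
   reported; they are allowed to disagree and their disagreement is
   diagnostic (see the rule-consistency audit below).

Two gates run before any criterion: genes curated by a Variant Curation
Expert Panel are delegated (the general rules must not override
gene-specific workflows), and genes whose gene–disease validity is below
"limited" are refused rather than classified. The primary transcript is
fixed by reference-set priority (MANE Select > RefSeq Select > MANE
Clinical Plus > RefSeq; among plain RefSeq the longest wins, ties broken
lexicographically for determinism).

## Population-frequency criteria

A population is evaluable when it shows no founder effect and more than
2,000 tested alleles; benign-direction evaluation (BA1/BS1) additionally
requires the variant in at least 5 alleles. The 5-allele floor is *not*
applied to PM2: requiring observed alleles would make "absent from
controls" unsatisfiable. Frequencies are compared as exact rationals
AC/AN against thresholds parsed as exact decimals — comparing against
the nearest binary float misplaces boundary frequencies such as exactly
5 % (this is a real failure mode, caught by the boundary tests).

Built-in thresholds by gene category and inheritance grouping (AD row
vs. the AR / AD-AR / X-linked row):

| Category  | Inheritance     | BS1_S    | PM2_P     | PM2_M     |
|-----------|-----------------|----------|-----------|-----------|
| cancer    | AD              | > 0.1 %  | < 0.004 % | absent    |
| cancer    | AR, AD/AR or XL | > 1 %    | < 0.04 %  | < 0.004 % |
| remaining | AD              | > 0.1 %  | < 0.001 % | absent    |
| remaining | AR, AD/AR or XL | > 1 %    | < 0.01 %  | < 0.001 % |

BA1 fires at ≥ 5 % for genes not on the stand-alone exception list;
exception-list genes carry no default and must supply per-gene
thresholds (an override may also disable BA1 entirely). Comparison
symbols follow the table verbatim: BA1 inclusive (≥), BS1 strict (>),
PM2 strict (<). "Absent" under the dominant rows means AC = 0 in every
evaluable population; populations failing eligibility are ignored, not
treated as absent. With no evaluable population at all, PM2 is withheld
with an explicit rationale — absence cannot be asserted without
evaluable controls.

XLR and XLD are accepted as refinements of XL: frequency rules use the
XL grouping; BS2 uses the refined mode; PP1 and PS4 treat XLD as
dominant and XL/XLR as recessive (the source ladders are printed only
for AD and AR/AD-AR, so the X-linked assignment follows the same
grouping logic).

## Variant-type criteria

**PVS1** applies to null variants (nonsense, frameshift, canonical
splice, initiation codon, single/multi-exon deletion) only when loss of
function is an established mechanism: curated haploinsufficiency status
wins; with unknown curation, pLI > 0.9 or o/e < 0.35 establishes it.
Strength modulation is a first-match decision table shipped as editable
JSON (`data/pvs1_decision_table.json`): NMD-predicted nonsense/
frameshift/splice/exon-deletion variants are very strong; NMD-escaping
variants downgrade to strong (critical region affected) or moderate;
in-frame exon skips to strong/supporting; initiation-codon variants are
moderate. NMD prediction is a required input for NMD-relevant null
consequences (a missing value is a validation error); initiation-codon
variants have no NMD concept and are exempt.

**PS1/PM5** require the pathogenic mechanism to be the missense change
itself, so a SpliceAI delta ≥ 0.8 or a functional finding of aberrant
splicing withholds the pair entirely (suppression, not downgrade, was
chosen: once a splice mechanism is plausible, a same-residue precedent
is no longer informative). PS1 (equivalent missense) pre-empts PM5
(different missense, same codon); within each, one pathogenic report or
two independent likely-pathogenic reports give the full weight, a single
likely-pathogenic report one notch less. "Independently classified" is
taken from the report counts on the supplied prior-variant records; the
engine does not deduplicate literature.

**PM1** is strong for three special residue classes (cysteine-parity
changes in NOTCH3-type EGF repeats — supplied as a boolean, since
repeat annotation is out of scope —, glycine substitutions in collagen
genes, Cys/His substitutions in C2H4 zinc fingers) and moderate for
regions under DECIPHER missense constraint < 0.4 or configured
literature hotspots. **PM4** requires rarity (PM2 at either weight) and
a non-repetitive region; indels of 1–2 residues are supporting, ≥ 3
moderate; stop-loss variants are mapped to moderate because they extend
the protein by well over two residues in virtually all transcripts (the
source tiers cover indels only; the mapping is overridable via a curated
per-variant call). **PP2** needs ≥ 3 reported pathogenic missense
variants *and* regional missense-constraint Z > 3.09. **BP1, BP2 and
BP3** are never asserted routinely; they remain in the audit trail
unapplied, with a curated per-variant override hook for the exceptional
BP3 case. **PP5/BP6** are discontinued and always unapplied.

## Case-level criteria

PM3 (recessive in-trans), PS2 (confirmed de novo) and PM6 (assumed de
novo) are additive scoring systems over unrelated affected individuals,
sharing the ladder SS ≥ 0.5/1/2/4 → P/M/S/VS. Per-observation scores:
PM3 — 1.0 in trans with a known P/LP variant, 0.5 phase unknown, 0.5
homozygous (0.25 with consanguineous parents); PS2 — 2.0/1.0/0.5/0 and
PM6 — 1.0/0.5/0.25/0 by phenotype class (highly specific / consistent /
consistent with high genetic heterogeneity / inconsistent). Mixed
cohorts feed both de novo pools; the classifier's caution cap bounds
their joint contribution. Observation lists arrive pre-merged; the
engine does not deduplicate families.

PS4 is strong outright for a qualifying case-control study (OR > 5 with
the confidence interval excluding 1), a known founder variant, or an
expert-panel-curated pathogenic variant; otherwise probands are counted
only for dominant conditions on variants meeting PM2 at either weight
(cancer genes 2–5/6–9/≥ 10 → P/M/S; other genes 1–2/3–4/≥ 5). PP1
counts meioses (dominant 3–4/5–6/≥ 7; recessive 1/2/≥ 3). BS2, BS4 and
BP5 are restricted by penetrance/onset gene flags that are configuration
inputs, never inferred; the green-list BS2 clause counts carrier alleles
as het + 2·hom + hemi. PP4 requires all four of: comprehensive testing,
rarity (PM2), consistent family history, and a single-etiology
phenotype; pathognomonic extra evidence upgrades it to strong.

## Conflict resolution and combination

Mutual-exclusivity sets — {BA1, BS1, PM2}, {PP3, BP4, BP7}, {BP3, PM4,
PVS1}, {PS1, PM5}, {PS3, BS3}, {BS4, PP1} — keep the strongest applied
call (A > VS > S > M > P); an equal-strength tie is broken toward the
pathogenic direction with a logged warning (conservative for a
diagnostic screen: a pathogenic-leaning VUS is reviewed, a benign call
is filed). Caution groups — {PM1, PP2}, {PM1, PM5}, {PS2, PM6},
{PM3, PS4, PP1} — are co-applicable but capped so that at most the two
strongest count (configurable). Demoted calls stay in the 28-entry audit
trail with `applied=False` and an annotated rationale.

The rule-based tier checks pathogenic rules before likely-pathogenic and
benign before likely-benign; "1 Strong AND 1–2 Moderate" style counts
are at-least constraints except where an upper bound is printed, which
is safe because the stronger tier is matched first. Matches in both
directions yield VUS with both rule identifiers logged (standard
practice for conflicting evidence). Rule 3B is criterion-specific
(PVS1_VS together with PM2_P) and checked on labels, not counts.

## Bayesian posterior

Strengths map to points 1/2/4/8 (P/M/S/VS); benign calls count negative;
BA1 is scored as 8 benign points on the posterior path while remaining
stand-alone on the rule path — an absolute criterion has no Bayesian
analogue, so both readings are reported side by side. Combined odds are
OddsPath = 350^(points/8) and

    Post_P = OddsPath · prior / ((OddsPath − 1) · prior + 1)

with prior 0.10 by default (the value required to reproduce the
canonical posteriors 0.975 for two Strong and 0.994 for Very Strong +
Moderate; exposed as `--prior`). Tier boundaries on the posterior scale:
pathogenic > 0.99, likely pathogenic 0.90–0.99; the benign side
(benign < 0.001, likely benign < 0.10) follows the Tavtigian
Bayesian-framework calibration and is configurable, since benign
cut-offs are printed differently across services.

The rule-consistency audit evaluates each combining rule's minimal
satisfying multiset and maps its posterior back to a tier. The posterior
is rounded to 3 decimals first — the reporting precision used
throughout — which matters at one boundary: the minimal set {S, M}
gives 0.89991, which reads as 0.900 at reporting precision and is
therefore inside the likely-pathogenic range rather than a spurious
third inconsistency. On defaults exactly two rules are flagged:
"≥ 2 Strong = Pathogenic" (0.975, likely-pathogenic range) and
"1 Very Strong AND 1 Moderate = Likely pathogenic" (0.994, pathogenic
range).

## Input formats

JSON is the primary format (single record, list, or `{"records": [...]}`;
gene context inline or as a symbol resolved against the gene config).
TSV uses a flat 41-column schema (booleans 0/1, `.` for missing) with
compact encodings for list-valued evidence: frequencies
`POP|AC|AN|FOUNDER`, prior variants `CODON|ALT|EQUIV|CLASS|REPORTS`,
recessive observations as tokens (`in_trans`, `phase_unknown`, `hom`,
`hom_consang`), de novo observations `confirmed|<phenotype>`. A minimal
annotated VCF (4.2, read via pysam) carries the same fields as
uppercased INFO keys with `&` as the item separator and integers 0/1 for
tri-state booleans. Cross-format equivalence is a tested contract:
identical evidence through JSON, TSV or VCF yields identical
classifications. Reports (JSON audit + TSV summary) are byte-identical
across repeated runs; there is no randomness anywhere in the
classification path.

## Synthetic data

The fixtures module is first-class code. `gold_fixture_set()` builds
~90 hand-written records, each with its expected applied calls, tier and
combining rule, constructed clause by clause so that every branch of
every implemented criterion and all 19 combining rules are exercised;
coverage is measured through the clause tags embedded in rationales and
asserted to be 100 % of the registry. `random_cohort(n, seed, prevalence)`
generates reproducible cohorts in which configured criterion clauses
fire with given prevalences (binomially, independently per record);
prevalences are guaranteed per clause only for compatible clause sets,
since some evidence injections are mutually contradictory by nature
(e.g. BA1-level frequency vs. absence from controls).

What the generator emulates: evidence-record structure, threshold
boundary cases, clause interactions. What it does not: realistic human
allele-frequency spectra, linkage between evidence types (real variants
with high REVEL also tend to be rare), literature curation noise, or
VCEP-specific rule sets. Green tests therefore certify the *engine
logic*, not concordance with any manual curation workflow on real data.

## Problem sizes and numerics

The test suite runs exhaustive small grids rather than sampled large
ones: all strength-count vectors with ≤ 6 calls against an independently
written rule matcher (~1,800 vectors), all PS1/PM5 report-count
combinations 0–3, in-silico score grids at 0.05 resolution, PM3
observation multisets up to size 5, and 1,000 random call multisets for
posterior monotonicity; the randomized-cohort prevalence check uses
n = 10,000 at a 3-sigma binomial tolerance. These sizes were chosen to
make each property exhaustive (or statistically decisive) at
sub-minute cost on one CPU.

Floating-point policy: frequencies are exact `Fraction`s; thresholds are
parsed as exact decimals; posteriors are kept at full precision in the
data model and rounded to 3 decimals only in reports and in the
rule-consistency audit; SS totals are sums of exactly representable
quarter points.

## Known limitations

- The PVS1 table is a deliberately compact decision table over stated
  inputs, not a re-derivation of the full published loss-of-function
  decision tree; laboratories with finer NMD/exon annotations should
  ship their own table.
- Functional-assay validation (PS3/BS3 strength assignment) and VCEP
  workflows are upstream concerns; the engine only passes strengths
  through, rejects proband-derived assays for PS3, and delegates
  VCEP-curated genes.
- Per-gene threshold overrides stand in for the externally curated
  gene-specific tables; none are bundled beyond a synthetic demo
  configuration.
- BP1/BP2/BP3 are policy-disabled; enabling them requires curated
  per-variant overrides, not a configuration switch.
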