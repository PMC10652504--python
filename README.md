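# acmg-engine

A deterministic, auditable rules engine for the classification of
constitutional (germline) sequence variants under the ACMG/AMP evidence
framework, with laboratory-style criterion-strength modulations, explicit
conflict resolution, the full set of combining rules, and a Bayesian
posterior probability of pathogenicity reported alongside the rule-based
tier.

It is written for clinical-genomics and bioinformatics teams who already
have annotated evidence (population frequencies, in-silico scores, curated
functional and case-level data) and need the *interpretation* step to be
reproducible: same evidence in, same classification and same audit trail
out, byte for byte.

## The model

Each of the 28 ACMG/AMP criteria (PVS1, PS1–4, PM1–6, PP1–5, BA1, BS1–4,
BP1–7) is evaluated with a direction (pathogenic/benign) and a modulated
strength: stand-alone (A), very strong (VS), strong (S), moderate (M) or
supporting (P). Highlights of the built-in modulations:

- **BA1/BS1/PM2** are mutually exclusive and evaluated on exact rational
  allele frequencies AC/AN over eligible populations (no founder effect,
  more than 2,000 alleles tested, and — for the benign direction — at
  least 5 observed alleles). Thresholds depend on gene category and
  inheritance, e.g. BS1_S at > 0.1 % for AD genes and > 1 % for the
  AR/AD-AR/XL group, with per-gene overrides for ClinGen-calibrated genes.
- **PVS1** is gated on an established loss-of-function mechanism
  (haploinsufficiency curation, else pLI > 0.9 or o/e < 0.35) and
  modulated by a shipped, editable decision table over NMD prediction,
  last-exon status, and criticality of the affected region.
- **PM3, PS2 and PM6** use additive proband scoring systems sharing the
  ladder SS ≥ 0.5 → P, ≥ 1 → M, ≥ 2 → S, ≥ 4 → VS; **PS4** counts
  unrelated probands (different ladders for cancer vs. other genes) and
  **PP1** counts segregating meioses.
- **PP3/BP4** use REVEL for missense (> 0.7 / < 0.4) and SpliceAI for
  other non-null consequences (≥ 0.8 / ≤ 0.2), with per-gene overrides;
  **BP7** requires SpliceAI ≤ 0.2 and GERP < 0 for synonymous variants.

After conflict resolution (mutual-exclusivity sets keep the strongest
call; overlapping "caution" groups are capped), two classifications are
produced side by side:

1. **Rule-based tier** from the 19 combining rules (1A–1B benign, 2A–2B
   likely benign, 3A–3G likely pathogenic, 4A–4H pathogenic).
2. **Bayesian posterior.** Evidence strengths map to exponentially scaled
   odds of pathogenicity, OddsPath = 350^(points/8) with points
   1/2/4/8 for P/M/S/VS (so supporting ≈ 2.08:1, moderate ≈ 4.33:1,
   strong ≈ 18.7:1, very strong 350:1), and

   Post_P = OddsPath · prior / ((OddsPath − 1) · prior + 1)

   with a default prior of 0.10. `acmg-engine audit-rules` checks every
   combining rule's minimal evidence set against its tier under this
   model and flags the two that are mathematically inconsistent
   (≥ 2 Strong → Post_P 0.975, inside the likely-pathogenic range;
   1 Very Strong + 1 Moderate → Post_P 0.994, inside the pathogenic
   range).

The engine consumes pre-annotated evidence only: it never queries
population databases or reference genomes, and genes curated by a ClinGen
Variant Curation Expert Panel are delegated (skipped with a marker)
rather than classified by the general rules.

## Worked example

`example.json` describes an NMD-predicted nonsense variant in a
constrained dominant gene (pLI 0.99), absent from a well-sampled control
population:

```json
[
  {
    "id": "demo-nonsense",
    "gene": {"symbol": "GENE_X", "inheritance": "AD", "category": "general",
             "clinical_validity": "definitive", "pli": 0.99},
    "variant": {"consequence": "nonsense", "nmd_predicted": true},
    "frequencies": [{"population": "overall", "allele_count": 0, "allele_number": 150000}]
  }
]
```

```sh
$ acmg-engine classify example.json --out demo_out
demo-nonsense	likely_pathogenic	3A	0.994
```

The JSON report (`demo_out.json`) shows both paths and the applied calls:

```text
tier           = likely_pathogenic    # rule 3A: 1 Very Strong AND 1 Moderate
matched_rule   = 3A
applied        = ['PM2_M', 'PVS1_VS']
points         = 10                   # 8 (very strong) + 2 (moderate)
post_p         = 0.994                # 350^(10/8)·0.1 / ((350^(10/8)−1)·0.1 + 1)
posterior_tier = pathogenic           # 0.994 > 0.99
```

The disagreement is intentional and informative: this very-strong-plus-
moderate combination is exactly one of the two combining rules whose
Bayesian posterior falls outside its rule-based tier.

Other entry points: `acmg-engine demo` classifies the bundled synthetic
fixture set (~90 records covering every criterion clause),
`acmg-engine audit-rules` prints the rule-consistency report, and
`acmg-engine validate-config` schema-checks gene/threshold tables.
Evidence may also arrive as TSV or a minimal annotated VCF (INFO-field
mapping documented in `docs/methods.md`).

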