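# Synthetic demo gene-context table.
# Stands in for the user-supplied gene configuration (inheritance modes,
# gene category, constraint metrics, list memberships). Symbols and
# settings are illustrative only, not curated gene facts.
DEMO_AD:
  inheritance: AD
  category: general
  clinical_validity: definitive
DEMO_AR:
  inheritance: AR
  category: general
  clinical_validity: strong
  complete_penetrance: true
DEMO_CANCER_AD:
  inheritance: AD
  category: cancer
  clinical_validity: definitive
DEMO_CANCER_AR:
  inheritance: AR
  category: cancer
  clinical_validity: strong
DEMO_LOF:
  inheritance: AD
  category: general
  clinical_validity: definitive
  pli: 0.99
  o_e: 0.1
DEMO_COLLAGEN:
  inheritance: AD
  category: general
  clinical_validity: definitive
  special_domain_class: collagen_glycine
DEMO_MISSENSE:
  inheritance: AD
  category: general
  clinical_validity: definitive
  pathogenic_missense_count: 5
  missense_constraint_z: 3.5
DEMO_XLD:
  inheritance: XLD
  category: general
  clinical_validity: moderate
DEMO_VCEP:
  inheritance: AD
  category: cancer
  clinical_validity: definitive
  vcep_curated: true
DEMO_DISPUTED:
  inheritance: AD
  category: general
  clinical_validity: disputed
DEMO_EXCEPTION:
  inheritance: AD
  category: general
  clinical_validity: definitive
  ba1_exception: true
  frequency_overrides:
    ba1: 0.10
    bs1_s: 0.01
    pm2_p: 0.0001
    pm2_m: 0.00001
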