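{
  "description": "Default PVS1 strength-modulation decision table for null variants in genes with an established loss-of-function mechanism. Rows are matched top-to-bottom; a row matches when every stated field equals the variant's value. Editable: ship a modified copy and point the engine at it to change the modulation.",
  "rows": [
    {"tag": "nmd_null", "consequence": ["nonsense", "frameshift"], "nmd_predicted": true, "strength": "VS"},
    {"tag": "last_exon_critical", "consequence": ["nonsense", "frameshift"], "nmd_predicted": false, "affected_region_critical": true, "strength": "S"},
    {"tag": "last_exon", "consequence": ["nonsense", "frameshift"], "nmd_predicted": false, "strength": "M"},
    {"tag": "splice_inframe_critical", "consequence": ["canonical_splice"], "exon_skip_inframe": true, "affected_region_critical": true, "strength": "S"},
    {"tag": "splice_inframe", "consequence": ["canonical_splice"], "exon_skip_inframe": true, "strength": "P"},
    {"tag": "splice_nmd", "consequence": ["canonical_splice"], "exon_skip_inframe": false, "nmd_predicted": true, "strength": "VS"},
    {"tag": "splice_no_nmd_critical", "consequence": ["canonical_splice"], "exon_skip_inframe": false, "nmd_predicted": false, "affected_region_critical": true, "strength": "S"},
    {"tag": "splice_no_nmd", "consequence": ["canonical_splice"], "exon_skip_inframe": false, "nmd_predicted": false, "strength": "M"},
    {"tag": "initiation", "consequence": ["initiation_codon"], "strength": "M"},
    {"tag": "exon_del_nmd", "consequence": ["single_multi_exon_deletion"], "nmd_predicted": true, "strength": "VS"},
    {"tag": "exon_del_critical", "consequence": ["single_multi_exon_deletion"], "nmd_predicted": false, "affected_region_critical": true, "strength": "S"},
    {"tag": "exon_del", "consequence": ["single_multi_exon_deletion"], "nmd_predicted": false, "strength": "M"}
  ]
}
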