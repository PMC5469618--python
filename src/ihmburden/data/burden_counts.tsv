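# published rare-variant carrier counts: HCM cases vs reference panel
site_label	carriers_cases	n_cases	carriers_controls	n_controls
MYH7 (whole gene)	854	6112	449	33364
priming-g + stabilizing-d1 (blocked head)	62	6112	0	33364
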