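# Corpus-level summary statistics from the reference evaluation, used as
# inputs when re-deriving the published ratios.
stat	value
assoc_workflow_precision	0.844
assoc_workflow_recall	0.930
names_found_total	585
names_representing_interactions	494
unique_names_found	583
old_names_reconciled	36
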