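variant	variant_class	flags	verdict	primary_reason	pvs1_max_strength	confirmation_required	audit
chr_clean_nonsense-270-G-T	nonsense	.	LoF	none	very_strong	0	no conservation track: weak-conservation rule skipped
chr_homopolymer_frameshift-275-GA-G	frameshift	homopolymer:technical:likely_not_LoF	likely_not_LoF	homopolymer	pending_confirmation	1	no conservation track: weak-conservation rule skipped
chr_last_exon-516-G-T	nonsense	last_exon_nmd:biological_relevance:likely_not_LoF	likely_not_LoF	last_exon_nmd	strong	0	no conservation track: weak-conservation rule skipped
chr_low_pext-291-G-T	nonsense	low_pext:biological_relevance:not_LoF	not_LoF	low_pext	not_applicable	0	no conservation track: weak-conservation rule skipped
chr_retained_stop-171-G-A	splice_donor	splice_retained_stop:rescue:LoF	LoF	splice_retained_stop	very_strong	0	no conservation track: weak-conservation rule skipped
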