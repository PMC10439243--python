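chr1	203800000	205300000	MDM4
chr12	57600000	61100000	CDK4
chr7	54200000	55700000	EGFR
chr17	35300000	37800000	ERBB2
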