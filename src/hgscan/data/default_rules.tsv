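family	rule_type	reference_id	position	allowed	pattern	min_count	label
hgcA	residue	hgcA_ref	93	C	.	.	hgcA:C93
hgcB	pattern	hgcB_ref	.	.	CX2CX2CX3C	2	hgcB:2xCX2CX2CX3C
merA	residue	merA_ref	207	C	.	.	merA:C207
merA	residue	merA_ref	212	C	.	.	merA:C212
merA	residue	merA_ref	264	Y	.	.	merA:Y264
merA	residue	merA_ref	605	YF	.	.	merA:Y605F
merA	residue	merA_ref	628	C	.	.	merA:C628
merA	residue	merA_ref	629	C	.	.	merA:C629
merB	residue	merB_ref	96	C	.	.	merB:C96
merB	residue	merB_ref	99	D	.	.	merB:D99
merB	residue	merB_ref	117	C	.	.	merB:C117
merB	residue	merB_ref	159	C	.	.	merB:C159
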