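#tax_id	GeneID	Symbol
9606	1	GENA
9606	2	GENB
9606	3	GENC
9606	4	GEND
10090	11	Gena
10090	12	Genb
10116	21	Gena_r
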