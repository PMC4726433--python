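mouse	11	MP:0000011	IAGP	PMID:2001
mouse	12	MP:0000020	ISO	PMID:2002
rat	21	MP:0000011	IEA	PMID:2003
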