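human	2	HP:0000010	IAGP	PMID:3001
human	4	HP:0000011	IEA	PMID:3002
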