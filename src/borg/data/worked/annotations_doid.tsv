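human	1	DOID:9711	IAGP	PMID:4001
human	3	DOID:651	IAGP	PMID:4002
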