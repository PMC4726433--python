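format-version: 1.2
ontology: worked-doid

[Term]
id: DOID:4
name: disease

[Term]
id: DOID:971
name: tendinitis
is_a: DOID:4

[Term]
id: DOID:9711
name: tenosynovitis
is_a: DOID:971

[Term]
id: DOID:65
name: connective tissue disease
is_a: DOID:4

[Term]
id: DOID:651
name: collagen disease
is_a: DOID:65

[Term]
id: DOID:652
name: bursitis
is_a: DOID:65
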