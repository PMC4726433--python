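format-version: 1.2
ontology: worked-hp

[Term]
id: HP:0000001
name: human phenotype root

[Term]
id: HP:0000010
name: thickened tendon
is_a: HP:0000001

[Term]
id: HP:0000011
name: decoy finding alpha
is_a: HP:0000001

[Term]
id: HP:0000012
name: decoy finding beta
is_a: HP:0000011

[Term]
id: HP:0000013
name: decoy finding gamma
is_a: HP:0000001
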