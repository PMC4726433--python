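format-version: 1.2
ontology: worked-mp

[Term]
id: MP:0000001
name: mammalian phenotype root

[Term]
id: MP:0000010
name: calcified tendon
is_a: MP:0000001

[Term]
id: MP:0000011
name: tendon rupture
is_a: MP:0000010

[Term]
id: MP:0000020
name: decoy phenotype alpha
is_a: MP:0000001

[Term]
id: MP:0000021
name: decoy phenotype beta
is_a: MP:0000001
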