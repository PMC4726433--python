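format-version: 1.2
ontology: worked-go

[Term]
id: GO:0000001
name: biological process root

[Term]
id: GO:0000010
name: matrix organisation
is_a: GO:0000001

[Term]
id: GO:0000011
name: fibril organisation
is_a: GO:0000010

[Term]
id: GO:0000012
name: regulation of fibril organisation
is_a: GO:0000011

[Term]
id: GO:0000020
name: decoy process alpha
is_a: GO:0000001

[Term]
id: GO:0000021
name: decoy process beta
is_a: GO:0000001

[Term]
id: GO:0000022
name: decoy process gamma
is_a: GO:0000021

[Term]
id: GO:0000023
name: obsolete decoy process
is_obsolete: true
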