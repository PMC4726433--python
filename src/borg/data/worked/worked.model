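# Disease model for the worked fixture: one feature term per domain.
disease: DOID:971
label: worked tendinopathy model
features:
  GO: [GO:0000010]
  MP: [MP:0000010]
  HP: [HP:0000010]
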