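# Cross-ontology semantic model of tendinopathy.
# Feature terms from three knowledge domains are wired feature_of -> "tendinitis".
disease: DOID:971
label: tendinopathy
features:
  GO:
    - GO:0035989   # tendon development
    - GO:0030199   # collagen fibril organization
    - GO:0045766   # positive regulation of angiogenesis
    - GO:0060055   # angiogenesis involved in wound healing
    - GO:0044346   # fibroblast apoptotic process
    - GO:0030203   # glycosaminoglycan metabolic process
    - GO:0006029   # proteoglycan metabolic process
    - GO:0032963   # collagen metabolic process
    - GO:0009100   # glycoprotein metabolic process
    - GO:0030198   # extracellular matrix organization
  MP:
    - MP:0003198   # calcified tendon
    - MP:0011643   # abnormal tendon collagen fibril morphology
    - MP:0005503   # tendon dysplasia
    - MP:0003907   # abnormal tendon stiffness
    - MP:0005601   # increased angiogenesis
    - MP:0003710   # abnormal physiological neovascularization
    - MP:0011475   # abnormal glycosaminoglycan level
  HP:
    - HP:0004690   # thickened Achilles tendon
    - HP:0005197   # generalized morning stiffness
    - HP:0011988   # ectopic ossification in tendon tissue
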