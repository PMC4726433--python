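Worked fixture: a hand-written synthetic 30-node bundle (7 genes, 23 terms)
small enough to trace every allowed path by eye. Used by the test suite as
the frozen reference for the path engine and by the examples.

Hand-traced expected paths to DOID:971 (max length 6):

GENA (human gene 1): 5 independent paths, 4 unique signatures,
                     domains {GO, MP, DOID}; related-disease: no
  1. GENA -involved_in-> GO:0000010 -feature_of-> DOID:971              (len 2)
  2. GENA -involved_in-> GO:0000011 -is_a-> GO:0000010 -feature_of-> .. (len 3)
  3. GENA -implicated_in-> DOID:9711 -is_a-> DOID:971                   (len 2)
  4. GENA -orthologous_to-> Gena(mouse) -has_phenotype-> MP:0000011
          -is_a-> MP:0000010 -feature_of-> DOID:971                     (len 4)
  5. GENA -orthologous_to-> Gena_r(rat) -has_phenotype-> MP:0000011
          -is_a-> MP:0000010 -feature_of-> DOID:971                     (len 4)
  (4 and 5 share one signature)

GENB (human gene 2): 2 independent paths, 2 unique, domains {GO, HP}
  1. GENB -involved_in-> GO:0000012 -is_a-> GO:0000011 -is_a-> GO:0000010
          -feature_of-> DOID:971                                        (len 4)
  2. GENB -has_phenotype-> HP:0000010 -feature_of-> DOID:971            (len 2)

GENC (human gene 3): 0 paths; implicated in DOID:651 (under DOID:65),
                     so it is a related-disease gene without tendinopathy links.
GEND (human gene 4): 0 paths; decoy annotations only.
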