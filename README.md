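# borg-kg

A **BioOntological Relationship Graph** (BORG) toolkit: a gene-centric,
multi-ontology semantic knowledge graph with a guilt-by-indirect-association
discovery engine for candidate disease-gene identification.

## The problem

Candidate-gene association studies depend on choosing good candidates, and
genes with only *transitive* links to a disease — a knockout phenotype in the
mouse ortholog, membership in a biological process that is itself a feature
of the disease — are easy to miss by reading the literature gene by gene.
This package data-mines that indirect knowledge systematically. It was built
around tendinopathy (modelled by the Disease Ontology term "tendinitis",
DOID:971) but the machinery is disease-agnostic: any disease term plus a
curated feature-term list defines a model.

## The method

1. **Semantic graph.** Human, mouse and rat genes sit at the centre, each
   linked to its orthologs. Ontology terms (GO, Disease Ontology, Human and
   Mammalian Phenotype Ontologies, Pathway Ontology) sit at the periphery as
   per-namespace DAGs. Every fact — an annotation `gene —involved_in→ term`,
   an orthology relation, a hierarchy edge — is stored as a pair of opposing
   directed edges carrying evidence codes (IAGP, IEA, IMP, ISO, ISS) and
   PubMed provenance. Loading is stepwise: genes → orthology → ontologies →
   annotations → disease model.
2. **Disease model.** Curated feature terms from several knowledge domains
   are wired to the disease term with `feature_of` edges. The packaged
   tendinopathy model links 20 terms (10 GO + 7 MP + 3 HP) to DOID:971.
3. **Path discovery.** A directed walk enumerates all allowed simple paths
   from a gene to the disease: away from the gene only, one orthology hop at
   most (first step), annotation edges gene→term, hierarchy edges child→parent,
   and `feature_of` into the disease. Genes annotated to *descendants* of a
   feature term are caught by walking the hierarchy upward (transitive
   closure at query time), so a "tenosynovitis" gene surfaces for
   "tendinitis". Query modes: shortest, fixed length, or all paths.
4. **Prioritization.** Per gene: *n* independent paths (distinct walks),
   *n* unique paths (distinct signatures = mechanistically distinct routes),
   and the set of knowledge domains. Strong candidates have >10 independent
   paths, ≥2 domains, and prior implication in a related-disease subtree
   (connective tissue disease, DOID:65). Candidate sets are checked by a
   one-sided hypergeometric over-representation test with Bonferroni control
   (significance at adjusted p < 0.01).
5. **Expression filter.** On a paired diseased/healthy matrix, a per-gene
   paired t-test on log2 ratios with Benjamini–Hochberg correction; a gene is
   differentially expressed iff |FC| > 1.5 (signed linear ratio) and
   adjusted p < 0.05. The final shortlist is the intersection: genes both
   differentially expressed and semantically linked.

A seeded synthetic-fixture generator (`borg.simulate`) emits every input the
pipeline consumes — mini-ontologies, catalogues, annotations, paired
expression matrices — with exact ground truth, so everything above is
testable without downloads.

## Worked example

```bash
python examples/01_build_and_query.py
```

builds the committed 30-node worked fixture and prints:

```
5 path(s) from GENA to tendinitis
GENA -[implicated_in]-> DOID:9711(tenosynovitis) (evidence: IAGP; PMID:4001) -[is_a]-> tendinitis
GENA -[involved_in]-> GO:0000010(matrix organisation) (evidence: IMP; PMID:1001) -[feature_of]-> tendinitis
GENA -[involved_in]-> GO:0000011(fibril organisation) (evidence: IEA; PMID:1002) -[is_a]-> GO:0000010(matrix organisation) -[feature_of]-> tendinitis
GENA -[orthologous_to]-> Gena -[has_phenotype]-> MP:0000011(tendon rupture) (evidence: IAGP; PMID:2001) -[is_a]-> MP:0000010(calcified tendon) -[feature_of]-> tendinitis
GENA -[orthologous_to]-> Gena_r -[has_phenotype]-> MP:0000011(tendon rupture) (evidence: IEA; PMID:2003) -[is_a]-> MP:0000010(calcified tendon) -[feature_of]-> tendinitis
```

Each line is one independent path; GENA has 5 of them in 4 distinct shapes
across three knowledge domains — a direct disease implication (via the child
term "tenosynovitis"), two functional routes through the GO hierarchy, and
two knockout-phenotype routes inherited from its mouse and rat orthologs.
`examples/02–04` continue through screening, prioritization, differential
expression and the final intersection.

The same operations are available from the shell:

```bash
borg ontology validate go.obo
borg build --genes genes.tsv --orthology orth.tsv --ontology GO=go.obo \
     --annotations GO=gene2go.tsv --model tendinopathy.model --out graph.json.gz
borg query --graph graph.json.gz --gene GENA --disease DOID:971 --mode all
borg prioritize --graph graph.json.gz --disease DOID:971 --related-disease DOID:65 --out cand.tsv
borg de --matrix expr.tsv --pairs pairs.tsv --out de.tsv
```

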