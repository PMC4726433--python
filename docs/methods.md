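# Methods

## The semantic graph

The graph is a typed multi-digraph (networkx `MultiDiGraph`) whose nodes are
genes (human, mouse, rat) and ontology terms, and whose edges come in
opposing pairs: one fact — "gene X is involved in process Y" — materialises
as `X —involved_in→ Y` and `Y —involves→ X`, both carrying the same evidence
code, provenance (PubMed ids) and knowledge domain (the namespace of the
non-gene endpoint, or `orthology`). Storing both directions keeps every unit
of knowledge traversable from either end while the discovery walk uses only
the disease-ward half.

Loading is stepwise and monotone — genes, then orthology, then ontologies
(terms + hierarchy edges), then annotations, then the disease model — and an
out-of-order call raises before mutating anything. Identical facts are
idempotent on re-insertion; the same gene–term pair with a *different*
evidence code is a distinct fact (path reports show evidence per edge, so
evidence identity matters). The graph serialises to a single JSON document
(optionally gzipped) and answers neighbour-by-label queries in memory;
the design target is ~10^5 edges, far above anything the fixtures produce.

Each ontology namespace is an isolated DAG; the only cross-namespace joints
are the seeded `feature_of` edges and gene annotations. Closure queries
follow `is_a` and `part_of` by default; the relation set is an argument
because OBO files carry other relations (`regulates`, ...) whose transitive
meaning is context-dependent. Obsolete OBO stanzas are dropped at parse
time (counted, reported by `borg ontology validate`); unknown tags are
ignored; the parser validates referential integrity and acyclicity of the
hierarchy before the ontology is usable.

## Disease models and closure semantics

A disease model is data: one disease term plus curated feature terms from
any number of namespaces (the packaged tendinopathy model: DOID:971 with 10
GO + 7 MP + 3 HP terms). Seeding adds one `feature_of`/`has_feature` pair
per feature and is idempotent.

Child-term coverage is deliberately **not** materialised as extra edges.
A gene annotated to a descendant of a feature term reaches the disease
because the walk ascends the hierarchy until it hits the feature term and
then takes its `feature_of` edge. This keeps the seeded model minimal (20
edges, not 20 plus every descendant) and makes coverage automatic when an
ontology gains new child terms. Only descendants are covered; ancestors of
a feature term do not inherit the link, since a broader term is not implied
by its narrower child.

## The discovery walk

`find_paths` enumerates **simple** paths (no node repeats) under direction
rules that only ever move away from the gene:

* from a gene: one orthology edge (first step only, at most once per path)
  or any gene→term annotation edge;
* from a term: `is_a`/`part_of` child→parent, or `feature_of` into the
  queried disease term (which terminates the path);
* term→gene edges are never taken.

Restricting orthology to a single leading hop prevents human→mouse→human
ping-pong from inflating path counts while preserving the intended
semantics: a gene inherits the knowledge attached to its orthologs.
The default length cap is 6 edges — enough for
gene → ortholog → term → is_a → is_a → feature term → disease — because
unbounded simple-path enumeration is exponential; the cap is a query
parameter. Paths are ordered by (length, signature, node sequence), making
reports byte-reproducible. The engine is verified against an independent
exhaustive enumerator on randomized micro-graphs and on a committed
hand-traced fixture (see `tests/`).

## Scoring and prioritization

*Independent paths* are distinct simple walks; *unique paths* are distinct
path **signatures**, the ordered list of (edge label, target namespace)
pairs — two walks through different collagen-related GO terms at the same
depth share a signature, i.e. they are the same kind of evidence. Knowledge
domains are ontology namespaces; orthology is transport, not evidence, and
is not counted as a domain. The three criteria are: strictly more than
`min_paths` (default 10) independent paths; at least `min_domains` (default
2) domains; membership in the related-disease gene set (genes annotated,
directly or via an ortholog, to the configured related-disease term or any
descendant — DOID:65, connective tissue disease, by default). A strong
candidate passes all three.

Over-representation uses the one-sided hypergeometric upper tail
(`scipy.stats.hypergeom.sf`) with Bonferroni adjustment `min(1, p·m)` over
the m non-empty categories, significant at adjusted p < 0.01. The test
family is a deliberate, simple replacement for external enrichment services;
it is exact, local and configurable.

## Differential expression

Input is a gene-level matrix of positive linear-scale intensities with an
explicit diseased/healthy pairing (the emulated design: 23 tendon pairs).
Per gene, a two-sided paired t-test on log2 differences; Benjamini–Hochberg
step-up across genes (statsmodels); fold change is the ratio of linear-scale
means reported signed (+r / −1/r), matching the reporting convention of
microarray studies. The DE rule is strict at both boundaries: |FC| > 1.5
and adjusted p < 0.05. A zero-variance row (possible in noiseless synthetic
data) has an undefined t statistic; it is assigned p = 1 when the mean log
difference is 0 and p = 0 otherwise. The moderated-statistics machinery of
microarray pipelines (normalisation, empirical-Bayes shrinkage) is out of
scope: input is assumed gene-level and normalised; a max-variance probe
collapse utility is provided. The fold-change threshold is applied to
linear-scale averages and boundaries are strict — the natural reading of
"> 1.5" — and both choices are isolated in one function should a user need
the alternative.

## Synthetic fixtures: what they emulate and what they do not

The knowledge generator keeps the real tendinopathy model as its backbone
(the 20 curated feature terms with their curated identifiers and names, a
DOID tree containing the disease and a connective-tissue subtree) and
surrounds it with synthetic structure: single-parent descendant chains under
feature terms (to exercise closure), layered random decoy DAGs outside the
closure (to test specificity — decoy annotations can never produce a path),
and three-species gene catalogues with partial orthology.

Planted candidates follow a fixed schedule of (path count, domain count,
related-disease) profiles chosen to straddle every decision boundary: 10
vs 11 paths, one vs several domains, related vs not, yielding exactly 3
strong candidates among 8 planted by default. GO and HP routes annotate the
human gene (at depth 0–2 under a feature term per the configured path
lengths); MP routes always run through the mouse ortholog, as mammalian-
phenotype annotations do in the real data. Because descendant chains are
single-parent, no feature term is an ancestor of another, and every planted
annotation carries fresh provenance, each planted annotation yields exactly
one path — expected counts are exact, not approximate, and the test suite
asserts them exactly.

The expression generator draws per-gene log2 baselines uniform on [4, 12],
adds a per-subject baseline effect (σ = 0.3 log2 units; cancelled by the
paired design, present so pairing matters), cell-level noise (σ = 0.2 log2
units, the study condition), and shifts planted genes by log2 of the planted
fold change (default +2.5) in the diseased member of each pair. What passing
tests show: the pipeline recovers planted effects of that size essentially
perfectly at n = 23 pairs. What they do not show: robustness to the
realities of microarray data — probe-level artefacts, intensity-dependent
variance, batch effects, correlated genes — none of which the log-normal
model contains.

All generation is driven by one integer seed (Python `random` for discrete
structure, numpy `default_rng` for the matrix); identical seeds give
byte-identical files, which the suite asserts end to end.

## Numerical and design choices

* Hierarchy acyclicity is validated with networkx cycle detection at parse
  time; closure queries are plain BFS over parent/child indexes.
* Path identity includes evidence and provenance, so two annotations of the
  same pair with different evidence are two independent paths (they are two
  units of knowledge); they still share one signature.
* `screen_genes` accepts symbols or node keys, skips unknown references
  (logged), and returns only genes with ≥ 1 path.
* Bonferroni is computed as `min(1, p·m)` exactly rather than through a
  library call, because the definition is pinned and m (non-empty categories
  tested) is decided locally after skipping empty categories.
* Fixture sizes default to 40/25/12 genes and ~20 decoy terms per namespace:
  large enough for decoy structure and boundary candidates, small enough
  that the full suite and the acceptance script each run in seconds.

## Known limitations

* The walk's allowed-edge rules are configuration (`PathQuery.allowed_labels`),
  but the direction rules themselves are fixed; exotic schemas (term→gene
  facts meant to be traversable) are out of scope.
* Real headline counts from any particular database snapshot are not
  reproducible here by design: screening outcomes depend entirely on the
  annotation corpus loaded, and the packaged corpora are synthetic.
* No weighted or probabilistic path ranking: a path is a path; certainty is
  expressed only through counts, domains and evidence codes.
* On-disk persistence is a JSON dump/load round trip, not a database; graphs
  far beyond ~10^5 edges would want a real store behind the same interface.
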