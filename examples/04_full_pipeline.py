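"""The complete candidate-gene workflow: graph screen x expression filter.

Knowledge side: screen all human genes for paths to the disease and apply
the three prioritization criteria. Expression side: paired differential
expression with the strong candidates planted as truly regulated genes.
The intersection - genes that are differentially expressed AND semantically
linked AND pass all criteria - is the pipeline's final shortlist, the
pattern that yielded four strong tendinopathy risk genes on real data.
"""

import tempfile

from borg import (
    FixtureSpec,
    PairedExpressionMatrix,
    apply_criteria,
    build_graph,
    generate_expression_fixture,
    generate_knowledge_fixture,
    intersect_with_candidates,
    paired_de,
    related_disease_genes,
    score_candidates,
    screen_genes,
)

with tempfile.TemporaryDirectory() as tmp:
    spec = FixtureSpec(seed=5)
    bundle, truth = generate_knowledge_fixture(spec, tmp + "/kb")
    graph, model = build_graph(bundle)
    symbols = sorted(graph.node(k)["symbol"] for k in graph.genes("human"))

    path_map = screen_genes(graph, symbols, "DOID:971")
    scores = score_candidates(path_map)
    apply_criteria(scores, related_disease_genes(graph, "DOID:65"))
    strong = sorted(s.gene for s in scores if s.strong)
    print(f"graph screen: {len(path_map)} candidates, {len(strong)} strong {strong}")

    matrix_path, pairs_path, de_truth = generate_expression_fixture(
        spec, tmp + "/expr", symbols=symbols, ensure_de=strong
    )
    de = paired_de(PairedExpressionMatrix.from_tsv(matrix_path, pairs_path))
    print(f"expression: {sum(r.is_de for r in de)} of {len(de)} genes DE")

    table = intersect_with_candidates(de, scores)
    print(f"\nintersection ({len(table)} genes both DE and semantically linked):")
    print(table.to_string(index=False))
    final = table[table["strong"]]["symbol"].tolist()
    print(f"\nfinal shortlist (DE + all three criteria): {final}")
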