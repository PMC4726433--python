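"""Shared fixtures: the worked bundle, generated bundles and random micro-graphs."""

from __future__ import annotations

import random

import pytest

from borg import (
    AnnotationRow,
    DiseaseModel,
    FixtureSpec,
    GeneRow,
    SemanticGraph,
    build_graph,
    seed_model,
    worked_fixture,
)
from borg.ontology import Ontology, OntologyTerm


@pytest.fixture(scope="session")
def worked_graph():
    graph, model = build_graph(worked_fixture())
    return graph


@pytest.fixture()
def small_bundle(tmp_path):
    from borg import generate_knowledge_fixture

    spec = FixtureSpec(seed=11)
    return generate_knowledge_fixture(spec, tmp_path / "bundle")


def make_ontology(namespace: str, edges: dict[str, list[str]],
                  relation: str = "is_a") -> Ontology:
    """Build an Ontology from a child -> [parents] mapping."""
    onto = Ontology(namespace)
    nodes = set(edges) | {p for ps in edges.values() for p in ps}
    for node in sorted(nodes):
        onto.add_term(
            OntologyTerm(node, f"name of {node}", namespace,
                         [(relation, p) for p in edges.get(node, [])])
        )
    onto.validate()
    return onto


def random_micro_graph(seed: int) -> tuple[SemanticGraph, list[str]]:
    """A random seeded semantic graph of <= 30 nodes for oracle comparison.

    Structure: 2 term namespaces with layered random DAGs, a tiny DOID tree,
    human+mouse genes with partial orthology, random annotations (some to
    feature-term descendants, some to decoys) and a random 1-3 term disease
    model.  Returns the graph and the human gene node keys.
    """
    rng = random.Random(seed)
    graph = SemanticGraph()
    n_h = rng.randint(2, 4)
    n_m = rng.randint(1, 3)
    genes = [GeneRow(9606, str(100 + i), f"HG{i}") for i in range(n_h)]
    genes += [GeneRow(10090, str(200 + i), f"Mg{i}") for i in range(n_m)]
    graph.load_genes(genes)
    pairs = [
        ("human", str(100 + i), "mouse", str(200 + i))
        for i in range(min(n_h, n_m))
        if rng.random() < 0.8
    ]
    graph.load_orthology(pairs)

    term_ids: dict[str, list[str]] = {}
    for ns in ("GO", "MP"):
        n_terms = rng.randint(4, 8)
        ids = [f"{ns}:{i}" for i in range(n_terms)]
        edges = {ids[0]: []}
        for i, tid in enumerate(ids[1:], start=1):
            n_parents = 1 + (rng.random() < 0.3)
            parents = rng.sample(ids[:i], min(n_parents, i))
            edges[tid] = parents
        graph.load_ontology(make_ontology(ns, edges))
        term_ids[ns] = ids
    graph.load_ontology(
        make_ontology("DOID", {"DOID:4": [], "DOID:971": ["DOID:4"],
                               "DOID:9711": ["DOID:971"]})
    )

    rows = []
    for i in range(n_h):
        for _ in range(rng.randint(0, 4)):
            ns = rng.choice(("GO", "MP", "DOID"))
            pool = term_ids.get(ns, ["DOID:9711", "DOID:4"])
            rows.append(
                AnnotationRow("human", str(100 + i), rng.choice(pool),
                              rng.choice(("IEA", "IMP")), (f"PMID:{rng.randint(1, 99)}",))
            )
    for i in range(n_m):
        for _ in range(rng.randint(0, 3)):
            ns = rng.choice(("GO", "MP"))
            rows.append(
                AnnotationRow("mouse", str(200 + i), rng.choice(term_ids[ns]),
                              "IAGP", ())
            )
    graph.load_annotations(rows)

    features = sorted(
        set(rng.sample(term_ids["GO"], rng.randint(1, 2))
            + rng.sample(term_ids["MP"], 1))
    )
    seed_model(graph, DiseaseModel("DOID:971", features, "random micro model"))
    return graph, [f"gene:human:{100 + i}" for i in range(n_h)]
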