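"""Path discovery: direction rules, query modes, reports, screening."""

import pytest

from borg import (
    AnnotationRow,
    DiseaseModel,
    GeneRow,
    PathQuery,
    SemanticGraph,
    find_paths,
    render_report,
    screen_genes,
    seed_model,
)
from borg.errors import GraphLookupError, InputError, StateError
from borg.graph import ORTHOLOGY_LABEL

from .conftest import make_ontology
from .oracles import enumerate_allowed_paths, path_step_set

DISEASE = "DOID:971"


@pytest.fixture()
def toy_graph():
    """The 7-node toy: three routes of lengths 2, 3 and 3.

    gene -> GO:A -feature_of-> disease                    (direct, length 2)
    gene -> GO:C -is_a-> GO:A -feature_of-> disease       (closure, length 3)
    gene -> mouse ortholog -> MP:B -feature_of-> disease  (orthology, length 3)
    """
    graph = SemanticGraph()
    graph.load_genes([GeneRow(9606, "1", "GENE"), GeneRow(10090, "2", "Gene")])
    graph.load_orthology([("human", "1", "mouse", "2")])
    graph.load_ontology(make_ontology("GO", {"GO:A": [], "GO:C": ["GO:A"]}))
    graph.load_ontology(make_ontology("MP", {"MP:B": []}))
    graph.load_ontology(make_ontology("DOID", {DISEASE: []}))
    graph.load_annotations([
        AnnotationRow("human", "1", "GO:A", "IMP", ("PMID:1",)),
        AnnotationRow("human", "1", "GO:C", "IEA", ("PMID:2",)),
        AnnotationRow("mouse", "2", "MP:B", "IAGP", ("PMID:3",)),
    ])
    seed_model(graph, DiseaseModel(DISEASE, ["GO:A", "MP:B"], "toy"))
    return graph


def test_toy_graph_has_exactly_three_paths(toy_graph):
    paths = find_paths(toy_graph, PathQuery("GENE", DISEASE))
    assert [p.length for p in paths] == [2, 3, 3]
    oracle = enumerate_allowed_paths(toy_graph, "gene:human:1", DISEASE, 6)
    assert path_step_set(paths) == oracle


def test_shortest_mode_keeps_only_minimum_length(toy_graph):
    paths = find_paths(toy_graph, PathQuery("GENE", DISEASE, mode="shortest"))
    assert [p.length for p in paths] == [2]


def test_fixed_length_mode(toy_graph):
    paths = find_paths(toy_graph, PathQuery("GENE", DISEASE, mode=3))
    assert [p.length for p in paths] == [3, 3]
    all_paths = find_paths(toy_graph, PathQuery("GENE", DISEASE))
    assert path_step_set(paths) <= path_step_set(all_paths)


def test_gene_without_edges_yields_no_paths(toy_graph):
    # mouse gene has no outgoing annotation of its own graph-entry rules?
    # use a fresh unannotated human gene instead
    graph = SemanticGraph()
    graph.load_genes([GeneRow(9606, "1", "LONER")])
    graph.load_ontology(make_ontology("GO", {"GO:A": []}))
    graph.load_ontology(make_ontology("DOID", {DISEASE: []}))
    graph.load_annotations([])
    seed_model(graph, DiseaseModel(DISEASE, ["GO:A"]))
    assert find_paths(graph, PathQuery("LONER", DISEASE)) == []


def test_unseeded_graph_is_a_state_error():
    graph = SemanticGraph()
    graph.load_genes([GeneRow(9606, "1", "G")])
    graph.load_ontology(make_ontology("DOID", {DISEASE: []}))
    with pytest.raises(StateError):
        find_paths(graph, PathQuery("G", DISEASE))


def test_unknown_gene_and_disease_lookup_errors(toy_graph):
    with pytest.raises(GraphLookupError):
        find_paths(toy_graph, PathQuery("NOPE", DISEASE))
    with pytest.raises(GraphLookupError):
        find_paths(toy_graph, PathQuery("GENE", "DOID:404"))


def test_direction_soundness(worked_graph):
    """No term->gene step; at most one orthology step, always first."""
    paths = find_paths(worked_graph, PathQuery("GENA", "DOID:971"))
    assert paths
    for path in paths:
        orth_positions = [
            i for i, s in enumerate(path.steps) if s.label == ORTHOLOGY_LABEL
        ]
        assert len(orth_positions) <= 1
        assert all(i == 0 for i in orth_positions)
        for step in path.steps[1:]:
            assert worked_graph.node(step.source)["kind"] == "term" or (
                step is path.steps[1] and path.steps[0].label == ORTHOLOGY_LABEL
            )


def test_max_length_monotonicity(worked_graph):
    previous: set = set()
    for cap in range(1, 7):
        current = path_step_set(
            find_paths(worked_graph, PathQuery("GENA", "DOID:971", max_length=cap))
        )
        assert previous <= current
        previous = current


def test_mode_outputs_are_subsets_of_all(worked_graph):
    everything = path_step_set(find_paths(worked_graph, PathQuery("GENA", "DOID:971")))
    shortest = path_step_set(
        find_paths(worked_graph, PathQuery("GENA", "DOID:971", mode="shortest"))
    )
    assert shortest <= everything
    for k in range(1, 7):
        fixed = path_step_set(
            find_paths(worked_graph, PathQuery("GENA", "DOID:971", mode=k))
        )
        assert fixed <= everything


def test_reports_are_deterministic(worked_graph):
    def render():
        paths = find_paths(worked_graph, PathQuery("GENA", "DOID:971"))
        return render_report(paths, "GENA", "tendinitis", worked_graph).text()

    assert render() == render()


def test_report_rendering_rules(toy_graph):
    empty = render_report([], "GENE", "tendinitis", toy_graph)
    assert empty.lines == []
    paths = find_paths(toy_graph, PathQuery("GENE", DISEASE, mode="shortest"))
    report = render_report(paths, "GENE", "tendinitis", toy_graph)
    assert len(report.lines) == 1
    assert report.lines[0].count("IMP") == 1
    assert "tendinitis" in report.lines[0]
    assert "PMID:1" in report.lines[0]


def test_report_rejects_foreign_paths(toy_graph, worked_graph):
    paths = find_paths(worked_graph, PathQuery("GENB", "DOID:971"))
    with pytest.raises(InputError):
        render_report(paths, "GENA", "tendinitis", worked_graph)


def test_report_json_schema(toy_graph):
    import json

    paths = find_paths(toy_graph, PathQuery("GENE", DISEASE))
    payload = json.loads(render_report(paths, "GENE", "tendinitis", toy_graph).to_json())
    assert payload["gene"] == "GENE"
    assert len(payload["paths"]) == 3
    step = payload["paths"][0]["steps"][0]
    assert set(step) == {"from", "label", "to", "evidence", "pmids"}


def test_screen_genes_keeps_only_linked_genes(worked_graph):
    result = screen_genes(
        worked_graph, ["GENA", "GENB", "GENC", "GEND", "ABSENT"], "DOID:971"
    )
    assert set(result) == {"GENA", "GENB"}
    assert len(result["GENA"]) == 5
    assert len(result["GENB"]) == 2


def test_screen_empty_list(worked_graph):
    assert screen_genes(worked_graph, [], "DOID:971") == {}


def test_ortholog_only_gene_still_screens(toy_graph):
    """A gene whose only disease link is its mouse ortholog's annotation."""
    graph = SemanticGraph()
    graph.load_genes([GeneRow(9606, "1", "HUM"), GeneRow(10090, "2", "Mus")])
    graph.load_orthology([("human", "1", "mouse", "2")])
    graph.load_ontology(make_ontology("MP", {"MP:B": []}))
    graph.load_ontology(make_ontology("DOID", {DISEASE: []}))
    graph.load_annotations([AnnotationRow("mouse", "2", "MP:B", "IAGP")])
    seed_model(graph, DiseaseModel(DISEASE, ["MP:B"]))
    result = screen_genes(graph, ["HUM"], DISEASE)
    assert set(result) == {"HUM"}
    (path,) = result["HUM"]
    assert path.steps[0].label == ORTHOLOGY_LABEL
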