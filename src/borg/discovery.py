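"""Guilt-by-indirect-association path discovery.

The engine enumerates *allowed* simple paths from a gene to the seeded
disease term by a directed walk that only ever moves away from the gene and
towards the disease:

* from a **gene** node the walk may take one orthology edge (only as the
  first step, at most once per path) or any gene-to-term annotation edge;
* from a **term** node it may ascend the ontology hierarchy (``is_a`` /
  ``part_of``, child to parent) or take a ``feature_of`` edge to the queried
  disease term;
* term-to-gene edges are never taken, so the inverse half of each fact pair
  is invisible to the walk.

Because feature_of edges are seeded only on the curated feature terms, a
gene annotated to a *descendant* of a feature term reaches the disease by
ascending the hierarchy until it hits the feature term — the query-time
transitive-closure semantics ("tenosynovitis" genes surface for
"tendinitis").

Three query modes mirror the original tool: shortest path(s) only, all
paths of one fixed length, or all paths up to a length cap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import GraphLookupError, InputError, StateError
from .graph import ORTHOLOGY_LABEL, SemanticGraph
from .model import FEATURE_OF

#: default cap on path length (edges); admits
#: gene -> ortholog -> term -> is_a -> is_a -> feature term -> disease
DEFAULT_MAX_LENGTH = 6

HIERARCHY_LABELS = frozenset({"is_a", "part_of"})

#: evidence-code vocabulary rendered in reports
EVIDENCE_CODES = {
    "IAGP": "Inferred by association of genotype with phenotype",
    "IEA": "Inferred from electronic annotation",
    "IMP": "Inferred from mutant phenotype",
    "ISO": "Inferred from sequence orthology",
    "ISS": "Inferred from sequence or structural similarity",
}


@dataclass(frozen=True)
class PathStep:
    source: str
    label: str
    target: str
    evidence: str = ""
    provenance: tuple[str, ...] = ()
    knowledge_domain: str = ""


@dataclass(frozen=True)
class Path:
    """One allowed walk from a gene to the disease term."""

    steps: tuple[PathStep, ...]

    @property
    def length(self) -> int:
        return len(self.steps)

    @property
    def nodes(self) -> tuple[str, ...]:
        return (self.steps[0].source,) + tuple(s.target for s in self.steps)

    @property
    def domains(self) -> frozenset[str]:
        """Knowledge domains traversed (may include 'orthology')."""
        return frozenset(s.knowledge_domain for s in self.steps if s.knowledge_domain)

    @property
    def signature(self) -> tuple[tuple[str, str], ...]:
        """Ordered (edge_label, target_namespace) pairs — the path's shape."""
        return tuple((s.label, s.knowledge_domain) for s in self.steps)

    def sort_key(self):
        return (self.length, self.signature, self.nodes)


@dataclass
class PathQuery:
    """A path query: gene, disease, mode and traversal constraints.

    ``mode`` is ``"all"``, ``"shortest"`` or an integer k (all paths of
    exactly k edges).  ``allowed_labels``, when given, whitelists the edge
    labels the walk may use.
    """

    gene: str
    disease_term: str
    mode: str | int = "all"
    max_length: int = DEFAULT_MAX_LENGTH
    allowed_labels: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.max_length < 1:
            raise InputError("max_length must be >= 1")
        if isinstance(self.mode, int):
            if not 1 <= self.mode <= self.max_length:
                raise InputError(
                    f"fixed length {self.mode} outside [1, max_length={self.max_length}]"
                )
        elif self.mode not in ("all", "shortest"):
            raise InputError(f"unknown mode {self.mode!r}")
        if self.allowed_labels is not None:
            self.allowed_labels = frozenset(self.allowed_labels)


def _resolve_gene(graph: SemanticGraph, gene: str) -> str:
    """Accept a node key or a (human) symbol."""
    if gene in graph and graph.node(gene).get("kind") == "gene":
        return gene
    key = graph.find_gene(gene)
    if key is None:
        raise GraphLookupError(f"gene {gene!r} not in graph")
    return key


def find_paths(graph: SemanticGraph, query: PathQuery) -> list[Path]:
    """Enumerate allowed simple paths for one gene, deterministically ordered.

    Paths are sorted by (length, signature, node sequence).  Raises
    :class:`StateError` if no disease model has been seeded and
    :class:`GraphLookupError` for unknown endpoints.
    """
    if graph.disease_model is None:
        raise StateError("no disease model seeded; call seed_model first")
    gene_node = _resolve_gene(graph, query.gene)
    if query.disease_term not in graph:
        raise GraphLookupError(f"disease term {query.disease_term!r} not in graph")

    disease = query.disease_term
    allowed = query.allowed_labels
    found: list[Path] = []
    # iterative DFS: (node, steps-so-far, orthology-used)
    stack: list[tuple[str, tuple[PathStep, ...], bool]] = [(gene_node, (), False)]
    while stack:
        node, steps, orth_used = stack.pop()
        if node == disease:
            if steps:
                found.append(Path(steps))
            continue
        if len(steps) >= query.max_length:
            continue
        visited = {gene_node} | {s.target for s in steps}
        node_kind = graph.node(node)["kind"]
        for target, data in graph.out_edges(node):
            label = data["label"]
            if allowed is not None and label not in allowed:
                continue
            if target in visited:
                continue
            target_kind = graph.node(target)["kind"]
            if node_kind == "gene":
                if target_kind == "gene":
                    # orthology: first step only, at most once
                    if label != ORTHOLOGY_LABEL or orth_used or steps:
                        continue
                elif label in HIERARCHY_LABELS or label == FEATURE_OF:
                    continue  # genes carry no hierarchy edges; be defensive
            else:  # term node
                if target_kind != "term":
                    continue  # term -> gene is never taken
                if label == FEATURE_OF:
                    if target != disease:
                        continue
                elif label not in HIERARCHY_LABELS:
                    continue
            step = PathStep(
                node, label, target, data["evidence"], data["provenance"],
                data["knowledge_domain"],
            )
            stack.append((target, steps + (step,), orth_used or target_kind == "gene"))

    found.sort(key=Path.sort_key)
    if query.mode == "shortest" and found:
        shortest = found[0].length
        found = [p for p in found if p.length == shortest]
    elif isinstance(query.mode, int):
        found = [p for p in found if p.length == query.mode]
    return found


def screen_genes(
    graph: SemanticGraph,
    genes: Iterable[str],
    disease_term: str,
    max_length: int = DEFAULT_MAX_LENGTH,
) -> dict[str, list[Path]]:
    """Screen a gene list; keep only genes with at least one path.

    ``genes`` may mix node keys and symbols; references absent from the
    graph are skipped and their count logged.  Only genes with >= 1 allowed
    path appear in the result, keyed by the reference as given.
    """
    result: dict[str, list[Path]] = {}
    skipped = 0
    for gene in genes:
        try:
            paths = find_paths(
                graph, PathQuery(gene, disease_term, "all", max_length)
            )
        except GraphLookupError:
            skipped += 1
            continue
        if paths:
            result[gene] = paths
    if skipped:
        import logging

        logging.getLogger(__name__).info(
            "screen_genes: %d reference(s) absent from the graph", skipped
        )
    return result


# ---------------------------------------------------------------------------
# reporting


@dataclass
class PathReport:
    """Figure-style per-gene evidence report: one line per path."""

    gene: str
    disease: str
    paths: list[Path]
    lines: list[str] = field(default_factory=list)

    def text(self) -> str:
        header = f"{len(self.paths)} path(s) from {self.gene} to {self.disease}"
        return "\n".join([header, *self.lines])

    def to_json(self) -> str:
        return json.dumps(
            {
                "gene": self.gene,
                "disease": self.disease,
                "paths": [
                    {
                        "length": p.length,
                        "domains": sorted(p.domains),
                        "steps": [
                            {
                                "from": s.source,
                                "label": s.label,
                                "to": s.target,
                                "evidence": s.evidence,
                                "pmids": list(s.provenance),
                            }
                            for s in p.steps
                        ],
                    }
                    for p in self.paths
                ],
            },
            indent=2,
            sort_keys=True,
        )


def _node_display(graph: SemanticGraph, key: str) -> str:
    data = graph.node(key)
    if data["kind"] == "gene":
        return data["symbol"]
    name = data.get("name", "")
    return f"{key}({name})" if name else key


def render_report(
    paths: Sequence[Path],
    gene: str,
    disease_label: str,
    graph: SemanticGraph,
) -> PathReport:
    """Render paths as natural-language lines.

    Line grammar (documented contract)::

        GENE -[label]-> NODE(name) (evidence: CODE; PMID:...) -[label]-> ... DISEASE

    The evidence clause is omitted on edges with neither an evidence code nor
    provenance.  All paths must start at ``gene``.
    """
    gene_node = _resolve_gene(graph, gene)
    lines = []
    for path in paths:
        if path.steps[0].source != gene_node:
            raise InputError(
                f"path starting at {path.steps[0].source!r} does not belong to {gene!r}"
            )
        parts = [_node_display(graph, gene_node)]
        for step in path.steps:
            target = (
                disease_label if step is path.steps[-1]
                else _node_display(graph, step.target)
            )
            parts.append(f"-[{step.label}]-> {target}")
            clauses = []
            if step.evidence:
                clauses.append(f"evidence: {step.evidence}")
            if step.provenance:
                clauses.append(", ".join(step.provenance))
            if clauses:
                parts.append(f"({'; '.join(clauses)})")
        lines.append(" ".join(parts))
    return PathReport(gene=gene, disease=disease_label, paths=list(paths), lines=lines)
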