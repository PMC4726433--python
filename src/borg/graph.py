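"""The integration substrate: a typed, attributed, directed semantic graph.

Human, mouse and rat genes sit at the centre; ontology terms from several
knowledge domains sit at the periphery.  Every fact (an orthology relation, a
gene-to-term annotation, a term-to-term hierarchy edge, a disease-model link)
is materialised as a *pair of opposing directed edges* — one carrying the
relation label, the other its inverse — so the unit of knowledge is explicit
and traversable from either end.

Loading is stepwise and order-enforced: genes first, then orthology edges,
then ontologies (terms + hierarchy edges), then gene-to-term annotations and
finally the disease model.  A violation raises :class:`~borg.errors.LoadOrderError`
before the graph is mutated.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx

from .errors import (
    GraphLookupError,
    LoadOrderError,
    ReferentialError,
    StateError,
)
from .ontology import Ontology

logger = logging.getLogger(__name__)

#: NCBI taxonomy id -> species label for the three central species
DEFAULT_TAX_MAP = {9606: "human", 10090: "mouse", 10116: "rat"}

ORTHOLOGY_LABEL = "orthologous_to"
ORTHOLOGY_DOMAIN = "orthology"

#: default annotation labels per knowledge domain (label, inverse)
DEFAULT_ANNOTATION_LABELS: dict[str, tuple[str, str]] = {
    "GO": ("involved_in", "involves"),
    "MP": ("has_phenotype", "phenotype_of"),
    "HP": ("has_phenotype", "phenotype_of"),
    "PW": ("participates_in", "has_participant"),
    "DOID": ("implicated_in", "has_implicated_gene"),
}

#: inverse labels for ontology hierarchy edges
HIERARCHY_INVERSES = {"is_a": "has_subclass", "part_of": "has_part"}

# load stages, in the mandated order
STAGE_GENES, STAGE_ORTHOLOGY, STAGE_ONTOLOGY, STAGE_ANNOTATIONS, STAGE_MODEL = range(5)
_STAGE_NAMES = ["genes", "orthology", "ontology", "annotations", "disease_model"]


@dataclass(frozen=True)
class GeneRow:
    """One gene-catalogue row (gene_info dialect, already species-resolved)."""

    tax_id: int
    gene_id: str
    symbol: str


@dataclass(frozen=True)
class AnnotationRow:
    """One gene-to-term annotation fact."""

    species: str
    gene_id: str
    term_id: str
    evidence: str = ""
    provenance: tuple[str, ...] = ()


@dataclass
class AnnotationLoadResult:
    added: int
    skipped_terms: int

    def __int__(self) -> int:  # the headline count is "pairs added"
        return self.added


def gene_key(species: str, gene_id: str) -> str:
    """Canonical node key for a gene: ``gene:<species>:<gene_id>``."""
    return f"gene:{species}:{gene_id}"


class SemanticGraph:
    """Typed multi-digraph of genes, terms and opposing fact-edge pairs."""

    def __init__(self, tax_map: Mapping[int, str] | None = None) -> None:
        self._g = nx.MultiDiGraph()
        self.tax_map = dict(DEFAULT_TAX_MAP if tax_map is None else tax_map)
        self.load_log: list[str] = []
        self._stage = -1
        self._fact_keys: set[tuple] = set()
        self.ontologies: dict[str, Ontology] = {}
        self.disease_model = None  # set by borg.model.seed_model
        # (species, symbol) -> node key; symbols assumed unique per species
        self._symbol_index: dict[tuple[str, str], str] = {}

    # -- introspection -------------------------------------------------------

    @property
    def nx_graph(self) -> nx.MultiDiGraph:
        return self._g

    def __contains__(self, node: str) -> bool:
        return node in self._g

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        """Directed edge count; always even (two per fact)."""
        return self._g.number_of_edges()

    @property
    def n_facts(self) -> int:
        return len(self._fact_keys)

    def node(self, key: str) -> dict:
        try:
            return self._g.nodes[key]
        except KeyError:
            raise GraphLookupError(f"node {key!r} not in graph") from None

    def is_gene(self, key: str) -> bool:
        return self.node(key)["kind"] == "gene"

    def genes(self, species: str | None = None) -> Iterator[str]:
        for key, data in self._g.nodes(data=True):
            if data["kind"] == "gene" and (species is None or data["species"] == species):
                yield key

    def find_gene(self, symbol: str, species: str = "human") -> str | None:
        """Resolve a symbol to a node key, or None if absent."""
        return self._symbol_index.get((species, symbol))

    def out_edges(
        self, node: str, labels: Iterable[str] | None = None
    ) -> Iterator[tuple[str, dict]]:
        """Neighbour-by-label query: yields (target, edge attributes)."""
        wanted = None if labels is None else set(labels)
        for _, target, data in self._g.out_edges(node, data=True):
            if wanted is None or data["label"] in wanted:
                yield target, data

    # -- stage machine -------------------------------------------------------

    def _require_stage(self, stage: int) -> None:
        if self._stage > stage:
            raise LoadOrderError(
                f"cannot load {_STAGE_NAMES[stage]} after "
                f"{_STAGE_NAMES[self._stage]}: the mandated order is "
                + " -> ".join(_STAGE_NAMES)
            )

    def _enter_stage(self, stage: int, detail: str) -> None:
        self._stage = max(self._stage, stage)
        self.load_log.append(f"{_STAGE_NAMES[stage]}: {detail}")

    # -- fact insertion ------------------------------------------------------

    def add_fact(
        self,
        source: str,
        target: str,
        label: str,
        inverse_label: str,
        evidence: str = "",
        provenance: Sequence[str] = (),
        knowledge_domain: str = "",
    ) -> bool:
        """Insert one fact as an opposing edge pair.

        Returns True if inserted, False if the identical fact (same endpoints,
        label, evidence and provenance) was already present (idempotent no-op).
        """
        for endpoint in (source, target):
            if endpoint not in self._g:
                raise ReferentialError(
                    f"fact {source} -[{label}]-> {target}: "
                    f"endpoint {endpoint!r} not in graph"
                )
        prov = tuple(provenance)
        key = (source, target, label, evidence, prov)
        if key in self._fact_keys:
            logger.debug("duplicate fact skipped: %s", key)
            return False
        attrs = dict(
            evidence=evidence, provenance=prov, knowledge_domain=knowledge_domain
        )
        self._g.add_edge(source, target, label=label, inverse_label=inverse_label, **attrs)
        self._g.add_edge(target, source, label=inverse_label, inverse_label=label, **attrs)
        self._fact_keys.add(key)
        return True

    # -- load steps ----------------------------------------------------------

    def load_genes(self, rows: Iterable[GeneRow]) -> int:
        """Step 1: insert gene nodes. Rows from taxa outside the map are skipped."""
        self._require_stage(STAGE_GENES)
        staged = []
        seen_here = set()
        skipped = 0
        for row in rows:
            species = self.tax_map.get(int(row.tax_id))
            if species is None:
                skipped += 1
                continue
            key = gene_key(species, str(row.gene_id))
            if key in self._g or key in seen_here:
                raise ReferentialError(
                    f"duplicate gene ({species}, {row.gene_id})"
                )
            if not row.symbol:
                raise ReferentialError(f"gene {row.gene_id} has an empty symbol")
            seen_here.add(key)
            staged.append((key, species, str(row.gene_id), row.symbol))
        for key, species, gid, symbol in staged:
            self._g.add_node(
                key, kind="gene", species=species, gene_id=gid,
                symbol=symbol, namespace=species,
            )
            self._symbol_index[(species, symbol)] = key
        if skipped:
            logger.warning("load_genes: skipped %d rows from unmapped taxa", skipped)
        self._enter_stage(STAGE_GENES, f"{len(staged)} genes ({skipped} skipped)")
        return len(staged)

    def load_orthology(
        self, pairs: Iterable[tuple[str, str, str, str]]
    ) -> int:
        """Step 2: orthology edge pairs. Each row is (species_a, gene_a, species_b, gene_b)."""
        self._require_stage(STAGE_ORTHOLOGY)
        staged = []
        for i, (sp_a, ga, sp_b, gb) in enumerate(pairs):
            if sp_a == sp_b:
                raise ReferentialError(
                    f"orthology row {i}: same-species pair ({sp_a}, {ga}, {gb})"
                )
            ka, kb = gene_key(sp_a, str(ga)), gene_key(sp_b, str(gb))
            for k in (ka, kb):
                if k not in self._g:
                    raise ReferentialError(f"orthology row {i}: unknown gene {k!r}")
            staged.append((ka, kb))
        added = sum(
            self.add_fact(
                ka, kb, ORTHOLOGY_LABEL, ORTHOLOGY_LABEL,
                knowledge_domain=ORTHOLOGY_DOMAIN,
            )
            for ka, kb in staged
        )
        self._enter_stage(STAGE_ORTHOLOGY, f"{added} orthology pairs")
        return added

    def load_ontology(self, ontology: Ontology) -> int:
        """Step 3: import a validated ontology's terms and hierarchy edges."""
        self._require_stage(STAGE_ONTOLOGY)
        ns = ontology.namespace
        if ns in self.ontologies:
            raise LoadOrderError(f"ontology {ns!r} already loaded")
        for term in ontology:
            self._g.add_node(
                term.term_id, kind="term", namespace=ns, name=term.name
            )
        n_edges = 0
        for term in ontology:
            for rel, parent in term.parents:
                inverse = HIERARCHY_INVERSES.get(rel, f"inverse_{rel}")
                n_edges += self.add_fact(
                    term.term_id, parent, rel, inverse, knowledge_domain=ns
                )
        self.ontologies[ns] = ontology
        self._enter_stage(STAGE_ONTOLOGY, f"{ns}: {len(ontology)} terms, {n_edges} edges")
        return n_edges

    def load_annotations(
        self,
        rows: Iterable[AnnotationRow],
        relation_label: str | None = None,
        inverse_label: str | None = None,
    ) -> AnnotationLoadResult:
        """Step 4: gene-to-term annotation facts.

        Labels default per the target term's namespace
        (:data:`DEFAULT_ANNOTATION_LABELS`).  Rows whose term is unknown are
        skipped and counted; an unknown gene is an error.
        """
        if not self.ontologies:
            raise LoadOrderError("annotations loaded before any ontology")
        self._require_stage(STAGE_ANNOTATIONS)
        staged = []
        skipped = 0
        for i, row in enumerate(rows):
            gk = gene_key(row.species, str(row.gene_id))
            if gk not in self._g:
                raise ReferentialError(
                    f"annotation row {i}: unknown gene ({row.species}, {row.gene_id})"
                )
            if row.term_id not in self._g or self._g.nodes[row.term_id]["kind"] != "term":
                skipped += 1
                continue
            ns = self._g.nodes[row.term_id]["namespace"]
            label, inverse = relation_label, inverse_label
            if label is None or inverse is None:
                label, inverse = DEFAULT_ANNOTATION_LABELS.get(
                    ns, ("annotated_to", "has_annotation")
                )
            staged.append((gk, row.term_id, label, inverse, row.evidence, row.provenance, ns))
        added = sum(
            self.add_fact(gk, tid, label, inverse, ev, prov, ns)
            for gk, tid, label, inverse, ev, prov, ns in staged
        )
        self._enter_stage(
            STAGE_ANNOTATIONS, f"{added} annotation pairs ({skipped} unknown-term rows skipped)"
        )
        return AnnotationLoadResult(added, skipped)

    def enter_model_stage(self, detail: str) -> None:
        """Step 5 bookkeeping; used by :func:`borg.model.seed_model`."""
        self._require_stage(STAGE_MODEL)
        self._enter_stage(STAGE_MODEL, detail)

    # -- closure over the materialised hierarchy ------------------------------

    def term_descendants(self, term_id: str, include_self: bool = False) -> set[str]:
        """Descendants of a term computed on the graph's own is_a/part_of edges."""
        if term_id not in self._g:
            raise GraphLookupError(f"term {term_id!r} not in graph")
        seen: set[str] = set()
        frontier = [term_id]
        while frontier:
            current = frontier.pop()
            for child, _, data in self._g.in_edges(current, data=True):
                if data["label"] in ("is_a", "part_of") and child not in seen:
                    seen.add(child)
                    frontier.append(child)
        seen.discard(term_id)
        if include_self:
            seen.add(term_id)
        return seen

    # -- symmetry audit -------------------------------------------------------

    def check_edge_symmetry(self) -> None:
        """Assert the opposing-pair invariant graph-wide (raises StateError)."""
        edges = set()
        for u, v, data in self._g.edges(data=True):
            edges.add(
                (u, v, data["label"], data["evidence"], data["provenance"],
                 data["knowledge_domain"])
            )
        for u, v, data in self._g.edges(data=True):
            mirror = (
                v, u, data["inverse_label"], data["evidence"], data["provenance"],
                data["knowledge_domain"],
            )
            if mirror not in edges:
                raise StateError(f"edge {u}->{v} [{data['label']}] has no opposing twin")

    # -- serialization --------------------------------------------------------

    def dump(self, path: str) -> None:
        """Write the graph as JSON (gzipped when the path ends in .gz)."""
        payload = {
            "tax_map": {str(k): v for k, v in self.tax_map.items()},
            "stage": self._stage,
            "load_log": self.load_log,
            "nodes": [
                {"key": k, **data} for k, data in sorted(self._g.nodes(data=True))
            ],
            "edges": [
                {
                    "source": u, "target": v, "label": d["label"],
                    "inverse_label": d["inverse_label"], "evidence": d["evidence"],
                    "provenance": list(d["provenance"]),
                    "knowledge_domain": d["knowledge_domain"],
                }
                for u, v, d in sorted(
                    self._g.edges(data=True), key=lambda e: (e[0], e[1], e[2]["label"])
                )
            ],
            "disease_model": None
            if self.disease_model is None
            else self.disease_model.to_dict(),
        }
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "wt", encoding="utf-8") as handle:
            json.dump(payload, handle, indent=0)

    @classmethod
    def load(cls, path: str) -> "SemanticGraph":
        from .model import DiseaseModel  # local import to avoid a cycle

        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "rt", encoding="utf-8") as handle:
            payload = json.load(handle)
        graph = cls(tax_map={int(k): v for k, v in payload["tax_map"].items()})
        for node in payload["nodes"]:
            key = node.pop("key")
            graph._g.add_node(key, **node)
            if node.get("kind") == "gene":
                graph._symbol_index[(node["species"], node["symbol"])] = key
        seen_facts = set()
        for edge in payload["edges"]:
            fact = (
                edge["source"], edge["target"], edge["label"], edge["evidence"],
                tuple(edge["provenance"]),
            )
            mirror = (
                edge["target"], edge["source"], edge["inverse_label"],
                edge["evidence"], tuple(edge["provenance"]),
            )
            if fact in seen_facts or mirror in seen_facts:
                continue
            seen_facts.add(fact)
            graph.add_fact(
                edge["source"], edge["target"], edge["label"], edge["inverse_label"],
                edge["evidence"], tuple(edge["provenance"]), edge["knowledge_domain"],
            )
        graph._stage = payload["stage"]
        graph.load_log = list(payload["load_log"])
        if payload["disease_model"] is not None:
            graph.disease_model = DiseaseModel.from_dict(payload["disease_model"])
        return graph
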