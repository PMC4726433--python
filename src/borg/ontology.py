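"""In-memory ontology store: OBO 1.2 parsing and DAG closure queries.

An :class:`Ontology` holds the terms of a single namespace (GO, DOID, HP, MP,
PW, ...) as a directed acyclic graph whose edges run from child to parent.
Closure queries (:meth:`Ontology.ancestors` / :meth:`Ontology.descendants`)
follow a configurable set of hierarchical relations, by default ``is_a`` and
``part_of``.

The parser understands the subset of OBO 1.2 that carries graph semantics:
``id``, ``name``, ``is_a``, ``relationship`` and ``is_obsolete`` tags inside
``[Term]`` stanzas.  Tags with no graph meaning here (``def``, ``synonym``,
``xref``, ...) are ignored with a debug log line.  Obsolete stanzas are
dropped (they would carry no parents and are excluded from closures anyway);
their count is kept on the ontology for reporting.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import networkx as nx

from .errors import CycleError, DuplicateTermError, OboParseError, UnknownTermError

logger = logging.getLogger(__name__)

#: relations followed by closure queries unless the caller overrides them
DEFAULT_CLOSURE_RELATIONS = frozenset({"is_a", "part_of"})

_GRAPH_TAGS = {"id", "name", "namespace", "is_a", "relationship", "is_obsolete"}


@dataclass
class OntologyTerm:
    """One ontology concept.

    ``parents`` is a list of ``(relation_label, parent_term_id)`` pairs; the
    relation label is kept verbatim from the OBO file, so non-hierarchical
    relations (``regulates``, ...) are retained even though closure queries do
    not follow them by default.
    """

    term_id: str
    name: str
    namespace: str
    parents: list[tuple[str, str]] = field(default_factory=list)
    is_obsolete: bool = False


class Ontology:
    """A single-namespace DAG of :class:`OntologyTerm` objects."""

    def __init__(
        self,
        namespace: str,
        closure_relations: Iterable[str] = DEFAULT_CLOSURE_RELATIONS,
    ) -> None:
        self.namespace = namespace
        self.closure_relations = frozenset(closure_relations)
        self._terms: dict[str, OntologyTerm] = {}
        # child -> [(relation, parent)] and the reverse index
        self._children: dict[str, list[tuple[str, str]]] = defaultdict(list)
        self.n_obsolete = 0
        self.relation_labels: set[str] = set()

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self._terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._terms

    def __iter__(self) -> Iterator[OntologyTerm]:
        return iter(self._terms.values())

    def __getitem__(self, term_id: str) -> OntologyTerm:
        try:
            return self._terms[term_id]
        except KeyError:
            raise UnknownTermError(
                f"term {term_id!r} not in ontology {self.namespace}"
            ) from None

    @property
    def term_ids(self) -> set[str]:
        return set(self._terms)

    # -- construction -------------------------------------------------------

    def add_term(self, term: OntologyTerm) -> None:
        if term.term_id in self._terms:
            raise DuplicateTermError(
                f"duplicate term id {term.term_id!r} in ontology {self.namespace}"
            )
        if term.is_obsolete and term.parents:
            raise OboParseError(
                f"obsolete term {term.term_id!r} must not carry parents"
            )
        self._terms[term.term_id] = term
        for rel, parent in term.parents:
            self.relation_labels.add(rel)
            self._children[parent].append((rel, term.term_id))
        self.relation_labels.update({"is_a", "part_of"})

    def validate(self) -> None:
        """Check referential integrity and acyclicity of the hierarchy.

        Raises
        ------
        UnknownTermError
            if any parent id does not resolve within this ontology.
        CycleError
            if the is_a/part_of structure contains a directed cycle; the
            message names one cycle member.
        """
        missing = sorted(
            {
                parent
                for term in self._terms.values()
                for _, parent in term.parents
                if parent not in self._terms
            }
        )
        if missing:
            raise UnknownTermError(
                f"{len(missing)} unresolved parent term(s) in ontology "
                f"{self.namespace}: {', '.join(missing)}"
            )
        dag = nx.DiGraph()
        dag.add_nodes_from(self._terms)
        for term in self._terms.values():
            for rel, parent in term.parents:
                if rel in self.closure_relations:
                    dag.add_edge(term.term_id, parent)
        try:
            cycle = nx.find_cycle(dag)
        except nx.NetworkXNoCycle:
            return
        raise CycleError(
            f"ontology {self.namespace} has a {'/'.join(sorted(self.closure_relations))} "
            f"cycle through {cycle[0][0]!r}"
        )

    # -- closure queries -----------------------------------------------------

    def ancestors(
        self,
        term_id: str,
        include_self: bool = False,
        relations: Iterable[str] | None = None,
    ) -> set[str]:
        """All terms reachable from ``term_id`` by walking child -> parent."""
        return self._closure(term_id, include_self, relations, up=True)

    def descendants(
        self,
        term_id: str,
        include_self: bool = False,
        relations: Iterable[str] | None = None,
    ) -> set[str]:
        """All terms from which ``term_id`` is reachable walking upward."""
        return self._closure(term_id, include_self, relations, up=False)

    def _closure(
        self,
        term_id: str,
        include_self: bool,
        relations: Iterable[str] | None,
        up: bool,
    ) -> set[str]:
        if term_id not in self._terms:
            raise UnknownTermError(
                f"term {term_id!r} not in ontology {self.namespace}"
            )
        rels = self.closure_relations if relations is None else frozenset(relations)
        seen: set[str] = set()
        frontier = [term_id]
        while frontier:
            current = frontier.pop()
            if up:
                nexts = (p for r, p in self._terms[current].parents if r in rels)
            else:
                nexts = (c for r, c in self._children.get(current, ()) if r in rels)
            for nxt in nexts:
                if nxt not in seen and nxt != term_id:
                    seen.add(nxt)
                    frontier.append(nxt)
        if include_self:
            seen.add(term_id)
        return seen


def parse_obo(
    stream: IO[str] | Iterable[str],
    namespace: str,
    closure_relations: Iterable[str] = DEFAULT_CLOSURE_RELATIONS,
) -> Ontology:
    """Parse an OBO 1.2 text stream into a validated :class:`Ontology`.

    Parameters
    ----------
    stream
        Text stream (or iterable of lines) of OBO 1.2 content.
    namespace
        Domain label stamped onto every parsed term (GO, DOID, HP, MP, PW...);
        this is the knowledge-domain identity, independent of the OBO file's
        own ``namespace`` tag (which GO uses for its sub-ontologies).

    Raises
    ------
    OboParseError
        on a ``[Term]`` stanza without an ``id`` tag (the message names the
        line the stanza starts on).
    DuplicateTermError, UnknownTermError, CycleError
        per :meth:`Ontology.add_term` / :meth:`Ontology.validate`.
    """
    ontology = Ontology(namespace, closure_relations)
    stanza_lines: list[tuple[int, str]] = []
    in_term = False
    stanza_start = 0

    def flush() -> None:
        if in_term:
            term = _parse_term_stanza(stanza_lines, stanza_start, namespace)
            if term.is_obsolete:
                ontology.n_obsolete += 1
            else:
                ontology.add_term(term)

    for lineno, raw in enumerate(stream, start=1):
        line = raw.split("!", 1)[0].strip() if not raw.startswith("!") else ""
        if line.startswith("["):
            flush()
            in_term = line == "[Term]"
            stanza_start = lineno
            stanza_lines = []
        elif in_term and line:
            stanza_lines.append((lineno, line))
    flush()

    ontology.validate()
    return ontology


def _parse_term_stanza(
    lines: list[tuple[int, str]], stanza_start: int, namespace: str
) -> OntologyTerm:
    term_id = None
    name = ""
    parents: list[tuple[str, str]] = []
    obsolete = False
    for lineno, line in lines:
        if ":" not in line:
            raise OboParseError(f"line {lineno}: tag line without ':' ({line!r})")
        tag, _, value = line.partition(":")
        tag = tag.strip()
        value = value.strip()
        if tag == "id":
            term_id = value
        elif tag == "name":
            name = value
        elif tag == "is_a":
            parents.append(("is_a", value.split()[0]))
        elif tag == "relationship":
            try:
                rel, target = value.split()[:2]
            except ValueError:
                raise OboParseError(
                    f"line {lineno}: malformed relationship line {line!r}"
                ) from None
            parents.append((rel, target))
        elif tag == "is_obsolete":
            obsolete = value.lower() == "true"
        elif tag not in _GRAPH_TAGS:
            logger.debug("ignoring OBO tag %r (line %d)", tag, lineno)
    if term_id is None:
        raise OboParseError(
            f"[Term] stanza starting at line {stanza_start} has no id tag"
        )
    if obsolete:
        parents = []
    return OntologyTerm(term_id, name, namespace, parents, obsolete)


def parse_obo_file(path, namespace: str, **kwargs) -> Ontology:
    """Convenience wrapper: :func:`parse_obo` on a file path."""
    with open(path, "r", encoding="utf-8") as handle:
        return parse_obo(handle, namespace, **kwargs)
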