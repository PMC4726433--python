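"""Candidate scoring, prioritization criteria and over-representation tests.

A screened gene is scored by the number of *independent* paths linking it to
the disease (distinct simple walks), the number of *unique* paths (distinct
path signatures, i.e. mechanistically distinct routes) and the set of
knowledge domains contributing.  Three criteria then prioritise candidates:

* ``many_paths`` — strictly more than ``min_paths`` (default 10) independent
  paths;
* ``multi_domain`` — at least ``min_domains`` (default 2) knowledge domains,
  where a domain is an ontology namespace (orthology edges do not count as a
  domain of their own);
* ``related_disease`` — prior implication in a configured related-disease
  subtree (connective tissue disease, DOID:65, in the tendinopathy study).

A gene satisfying all three is a *strong* candidate.  Candidate-set quality
is assessed with a one-sided hypergeometric over-representation test with
Bonferroni control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy.stats import hypergeom

from .discovery import Path
from .errors import InputError, ParameterError
from .graph import ORTHOLOGY_DOMAIN, ORTHOLOGY_LABEL, SemanticGraph

logger = logging.getLogger(__name__)

CRITERIA = ("many_paths", "multi_domain", "related_disease")


@dataclass
class CandidateScore:
    gene: str
    n_independent_paths: int
    n_unique_paths: int
    domains: frozenset[str]
    in_related_disease: bool | None = None
    passes: dict[str, bool] = field(default_factory=dict)

    @property
    def strong(self) -> bool:
        return bool(self.passes) and all(self.passes[c] for c in CRITERIA)


def score_candidates(path_map: Mapping[str, Sequence[Path]]) -> list[CandidateScore]:
    """Score each screened gene from its path list.

    Domains are the union of per-path knowledge domains minus orthology.
    Output is sorted by (-n_independent_paths, gene), and is a pure function
    of the mapping's contents (input order never matters).
    """
    scores = []
    for gene, paths in path_map.items():
        domains = frozenset().union(*(p.domains for p in paths)) - {ORTHOLOGY_DOMAIN}
        scores.append(
            CandidateScore(
                gene=gene,
                n_independent_paths=len(paths),
                n_unique_paths=len({p.signature for p in paths}),
                domains=domains,
            )
        )
    scores.sort(key=lambda s: (-s.n_independent_paths, s.gene))
    return scores


def apply_criteria(
    scores: Iterable[CandidateScore],
    related_disease_genes: set[str],
    min_paths: int = 10,
    min_domains: int = 2,
) -> list[CandidateScore]:
    """Fill the three prioritization flags on each score (returns the list).

    ``many_paths`` is strict: a gene with exactly ``min_paths`` paths fails.
    """
    if min_paths < 0:
        raise ParameterError("min_paths must be >= 0")
    if min_domains < 1:
        raise ParameterError("min_domains must be >= 1")
    out = []
    for score in scores:
        score.in_related_disease = score.gene in related_disease_genes
        score.passes = {
            "many_paths": score.n_independent_paths > min_paths,
            "multi_domain": len(score.domains) >= min_domains,
            "related_disease": score.in_related_disease,
        }
        out.append(score)
    return out


def at_least_k_links(scores: Iterable[CandidateScore], k: int = 2) -> set[str]:
    """Genes with at least k independent paths to the disease."""
    if k < 1:
        raise ParameterError("k must be >= 1")
    return {s.gene for s in scores if s.n_independent_paths >= k}


def related_disease_genes(
    graph: SemanticGraph, disease_term: str, species: str = "human"
) -> set[str]:
    """Symbols of genes implicated in a disease term or any of its descendants.

    A gene counts if it is annotated (any annotation label) to a term in the
    subtree, either directly or through an ortholog in another species —
    the orthology-inheritance rule applied to prior disease implication.
    """
    subtree = graph.term_descendants(disease_term, include_self=True)
    implicated: set[str] = set()  # gene node keys, any species
    for term in subtree:
        for target, data in graph.out_edges(term):
            if graph.node(target)["kind"] == "gene" and data["label"] not in (
                "has_subclass", "has_part",
            ):
                implicated.add(target)
    symbols: set[str] = set()
    for key in implicated:
        data = graph.node(key)
        if data["species"] == species:
            symbols.add(data["symbol"])
        else:
            for ortho, edata in graph.out_edges(key, labels=[ORTHOLOGY_LABEL]):
                odata = graph.node(ortho)
                if odata["species"] == species:
                    symbols.add(odata["symbol"])
    return symbols


# ---------------------------------------------------------------------------
# over-representation


@dataclass
class EnrichmentResult:
    category_id: str
    k: int  # candidates in category
    K: int  # background genes in category
    n: int  # candidate set size
    N: int  # background size
    p_value: float
    p_adjusted: float
    significant: bool


def enrichment_test(
    candidates: set[str],
    background: set[str],
    categories: Mapping[str, set[str]],
    alpha: float = 0.01,
) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation per category.

    p = P[X >= k] with X ~ Hypergeom(N, K, n); Bonferroni adjustment
    p_adj = min(1, p * m) over the m non-empty categories tested;
    ``significant`` iff p_adj < alpha.  Results sorted by (p_value, category).
    """
    if not candidates <= background:
        raise InputError("candidate set is not a subset of the background")
    tested = []
    for cat_id in sorted(categories):
        members = categories[cat_id]
        if not members:
            logger.warning("enrichment_test: empty category %r skipped", cat_id)
            continue
        if not members <= background:
            raise InputError(f"category {cat_id!r} is not a subset of the background")
        tested.append((cat_id, members))
    m = len(tested)
    N, n = len(background), len(candidates)
    results = []
    for cat_id, members in tested:
        K = len(members)
        k = len(candidates & members)
        p = float(hypergeom.sf(k - 1, N, K, n))  # upper tail P[X >= k]
        p = min(p, 1.0)
        p_adj = min(1.0, p * m)
        results.append(
            EnrichmentResult(cat_id, k, K, n, N, p, p_adj, p_adj < alpha)
        )
    results.sort(key=lambda r: (r.p_value, r.category_id))
    return results
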