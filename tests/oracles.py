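"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive each computation from its definition rather
than reusing any code path from the package.
"""

from __future__ import annotations

import itertools
from math import comb

HIERARCHY = ("is_a", "part_of")
ORTHOLOGY = "orthologous_to"
FEATURE_OF = "feature_of"


def reachable_up(parents: dict[str, list[tuple[str, str]]], start: str,
                 relations=HIERARCHY) -> set[str]:
    """Transitive ancestors by naive repeated expansion over a parent map."""
    out: set[str] = set()
    frontier = {start}
    while frontier:
        nxt = set()
        for node in frontier:
            for rel, parent in parents.get(node, []):
                if rel in relations and parent not in out and parent != start:
                    out.add(parent)
                    nxt.add(parent)
        frontier = nxt
    return out


def enumerate_allowed_paths(graph, gene_node: str, disease: str, max_length: int):
    """Exhaustive recursive enumeration of allowed simple gene->disease walks.

    Applies the stated direction rules from scratch:
    orthology only as the very first edge and at most once; gene->term
    annotation edges; term->term only upward is_a/part_of or feature_of into
    the queried disease; never term->gene.  Returns a set of step-tuples,
    each step ``(source, label, target, evidence, provenance)``.
    """
    g = graph.nx_graph
    kind = {n: d["kind"] for n, d in g.nodes(data=True)}
    found = set()

    def recurse(node, steps, seen):
        if node == disease:
            if steps:
                found.add(tuple(steps))
            return
        if len(steps) >= max_length:
            return
        for _, target, data in g.out_edges(node, data=True):
            label = data["label"]
            if target in seen:
                continue
            if kind[node] == "gene":
                if kind[target] == "gene":
                    if not (label == ORTHOLOGY and len(steps) == 0):
                        continue
                else:
                    if label in HIERARCHY or label == FEATURE_OF:
                        continue
            else:
                if kind[target] == "gene":
                    continue
                if label in HIERARCHY:
                    pass
                elif label == FEATURE_OF:
                    if target != disease:
                        continue
                else:
                    continue
            step = (node, label, target, data["evidence"], data["provenance"])
            recurse(target, steps + [step], seen | {target})

    recurse(gene_node, [], {gene_node})
    return found


def path_step_set(paths):
    """Engine Path objects -> the oracle's step-tuple representation."""
    return {
        tuple((s.source, s.label, s.target, s.evidence, s.provenance) for s in p.steps)
        for p in paths
    }


def bh_step_up(p_values):
    """Benjamini-Hochberg from the definition: sort, q_i = p_(i) m/i, enforce
    monotonicity from the largest rank down, cap at 1, restore input order."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p_values[idx] * m / rank)
        q[idx] = min(running_min, 1.0)
    return q


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P[X >= k] by direct combinatorial summation."""
    total = comb(N, n)
    return sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1)) / total


def hypergeom_by_enumeration(background, category, candidates) -> float:
    """P[X >= k] by enumerating every n-subset of the background (N <= 12)."""
    background = sorted(background)
    n = len(candidates)
    k_obs = len(set(candidates) & set(category))
    hits = total = 0
    for draw in itertools.combinations(background, n):
        total += 1
        if len(set(draw) & set(category)) >= k_obs:
            hits += 1
    return hits / total
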