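"""Candidate scoring, criteria boundaries and over-representation tests."""

import random

import pytest

from borg import (
    apply_criteria,
    at_least_k_links,
    enrichment_test,
    related_disease_genes,
    score_candidates,
)
from borg.discovery import Path, PathStep
from borg.errors import InputError, ParameterError

from .oracles import hypergeom_by_enumeration, hypergeom_upper_tail


def fake_path(labels_domains, gene="G"):
    steps = []
    node = gene
    for i, (label, domain) in enumerate(labels_domains):
        nxt = f"N{i}"
        steps.append(PathStep(node, label, nxt, "IEA", (), domain))
        node = nxt
    return Path(tuple(steps))


GO_SIG = (("involved_in", "GO"), ("feature_of", "GO"))
MP_SIG = (("orthologous_to", "orthology"), ("has_phenotype", "MP"), ("feature_of", "MP"))


def test_single_path_score():
    (score,) = score_candidates({"G": [fake_path(GO_SIG)]})
    assert (score.n_independent_paths, score.n_unique_paths) == (1, 1)
    assert score.domains == frozenset({"GO"})


def test_shared_signature_counts_once():
    paths = [fake_path(GO_SIG) for _ in range(3)]
    (score,) = score_candidates({"G": paths})
    assert (score.n_independent_paths, score.n_unique_paths) == (3, 1)


def test_orthology_is_not_a_knowledge_domain():
    (score,) = score_candidates({"G": [fake_path(MP_SIG)]})
    assert score.domains == frozenset({"MP"})


def test_ordering_by_path_count_then_symbol():
    path_map = {
        "B": [fake_path(GO_SIG) for _ in range(9)],
        "A": [fake_path(GO_SIG) for _ in range(11)],
        "C": [fake_path(GO_SIG) for _ in range(9)],
    }
    scores = score_candidates(path_map)
    assert [s.gene for s in scores] == ["A", "B", "C"]


def test_score_is_invariant_to_input_order():
    path_map = {"A": [fake_path(GO_SIG)], "B": [fake_path(MP_SIG)] * 2}
    reversed_map = dict(reversed(list(path_map.items())))
    as_tuples = lambda scores: [
        (s.gene, s.n_independent_paths, s.n_unique_paths, s.domains) for s in scores
    ]
    assert as_tuples(score_candidates(path_map)) == as_tuples(
        score_candidates(reversed_map)
    )


@pytest.mark.parametrize("n_paths,passes", [(9, False), (10, False), (11, True)])
def test_many_paths_boundary_is_strict(n_paths, passes):
    (score,) = score_candidates({"G": [fake_path(GO_SIG)] * n_paths})
    apply_criteria([score], set())
    assert score.passes["many_paths"] is passes


def test_single_domain_fails_multi_domain():
    (score,) = score_candidates({"G": [fake_path(GO_SIG)] * 12})
    apply_criteria([score], {"G"})
    assert score.passes["multi_domain"] is False
    assert score.passes["related_disease"] is True
    assert not score.strong


def test_parameter_validation():
    with pytest.raises(ParameterError):
        apply_criteria([], set(), min_paths=-1)
    with pytest.raises(ParameterError):
        apply_criteria([], set(), min_domains=0)
    with pytest.raises(ParameterError):
        at_least_k_links([], k=0)


def test_at_least_k_links_thresholds():
    path_map = {
        "A": [fake_path(GO_SIG)],
        "B": [fake_path(GO_SIG)] * 2,
        "C": [fake_path(GO_SIG)] * 5,
    }
    scores = score_candidates(path_map)
    assert at_least_k_links(scores, 1) == {"A", "B", "C"}
    assert at_least_k_links(scores, 2) == {"B", "C"}
    assert at_least_k_links(scores, 2) <= at_least_k_links(scores, 1)


def test_strong_set_shrinks_as_thresholds_tighten():
    rng = random.Random(0)
    path_map = {}
    for i in range(12):
        n = rng.randint(1, 15)
        sigs = [GO_SIG, MP_SIG, (("has_phenotype", "HP"), ("feature_of", "HP"))]
        n_domains = rng.randint(1, 3)
        path_map[f"G{i}"] = [fake_path(sigs[j % n_domains]) for j in range(n)]
    related = {f"G{i}" for i in range(0, 12, 2)}

    def strong_set(min_paths, min_domains):
        scores = score_candidates(path_map)
        apply_criteria(scores, related, min_paths, min_domains)
        return {s.gene for s in scores if s.strong}

    for mp_, md in [(2, 1), (5, 1), (5, 2), (10, 2), (10, 3)]:
        assert strong_set(mp_ + 1, md) <= strong_set(mp_, md)
        assert strong_set(mp_, md + 1) <= strong_set(mp_, md)


def test_related_disease_genes_via_subtree_and_orthology(worked_graph):
    # GENC is annotated to a child of DOID:65; no other human gene is
    assert related_disease_genes(worked_graph, "DOID:65") == {"GENC"}
    # the tendinitis subtree catches GENA directly (DOID:9711 annotation)
    assert "GENA" in related_disease_genes(worked_graph, "DOID:971")


# ---------------------------------------------------------------------------
# enrichment


def test_zero_overlap_has_p_one():
    res = enrichment_test({"a"}, {"a", "b", "c"}, {"cat": {"b"}})
    assert res[0].p_value == 1.0


def test_exact_hypergeometric_example():
    background = {f"g{i}" for i in range(10)}
    category = {f"g{i}" for i in range(5)}
    candidates = {"g0", "g1", "g2", "g3"}
    (res,) = enrichment_test(candidates, background, {"cat": category})
    assert res.p_value == pytest.approx(5 / 210, abs=1e-12)
    assert (res.k, res.K, res.n, res.N) == (4, 5, 4, 10)


def test_bonferroni_arithmetic_and_threshold():
    background = {f"g{i}" for i in range(12)}
    # three categories; adjusted p = raw * 3
    cats = {f"c{i}": set(random.Random(i).sample(sorted(background), 4))
            for i in range(3)}
    results = enrichment_test(set(list(background)[:4]), background, cats, alpha=0.01)
    for r in results:
        assert r.p_adjusted == pytest.approx(min(1.0, r.p_value * 3), abs=1e-12)
        assert r.significant == (r.p_adjusted < 0.01)
    # the documented boundary: raw 0.004 over 3 tests -> 0.012, not significant
    assert not (0.004 * 3 < 0.01)


def test_enrichment_input_validation():
    with pytest.raises(InputError):
        enrichment_test({"x"}, {"a"}, {"c": {"a"}})
    with pytest.raises(InputError):
        enrichment_test({"a"}, {"a"}, {"c": {"zz"}})
    res = enrichment_test({"a"}, {"a", "b"}, {"empty": set(), "ok": {"a"}})
    assert [r.category_id for r in res] == ["ok"]  # empty skipped


@pytest.mark.parametrize("seed", range(6))
def test_enrichment_matches_enumeration_oracle(seed):
    """Hypergeometric tail equals exhaustive subset enumeration (N <= 12)."""
    rng = random.Random(seed)
    N = rng.randint(5, 12)
    background = {f"g{i}" for i in range(N)}
    category = set(rng.sample(sorted(background), rng.randint(1, N)))
    candidates = set(rng.sample(sorted(background), rng.randint(1, N - 1)))
    (res,) = enrichment_test(candidates, background, {"cat": category})
    enum_p = hypergeom_by_enumeration(background, category, candidates)
    closed_p = hypergeom_upper_tail(N, len(category), len(candidates),
                                    len(candidates & category))
    assert res.p_value == pytest.approx(enum_p, abs=1e-12)
    assert res.p_value == pytest.approx(closed_p, abs=1e-12)
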