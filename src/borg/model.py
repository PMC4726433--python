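"""Disease-specific semantic models.

A disease model picks one disease term (for tendinopathy, the Disease
Ontology term "tendinitis", DOID:971) and wires a curated set of feature
terms from other knowledge domains to it with ``feature_of`` edges — e.g.
GO "collagen fibril organisation" or MP "calcified tendon".  The seeded
edges are the only cross-ontology joints in the graph; child-term coverage
is *not* materialised as extra edges but resolved at query time by the
discovery engine walking the ontology hierarchy upward (closure semantics).

The model itself is data, shipped as a small human-editable config file::

    disease: DOID:971
    label: tendinopathy
    features:
      GO: [GO:0035989, GO:0030199, ...]
      MP: [MP:0003198, ...]
      HP: [HP:0004690, ...]
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import IO

import yaml

from .errors import ConfigError, ReferentialError
from .graph import SemanticGraph

logger = logging.getLogger(__name__)

FEATURE_OF = "feature_of"
HAS_FEATURE = "has_feature"


@dataclass
class DiseaseModel:
    """A disease term plus the feature terms wired to it."""

    disease_term: str
    feature_terms: list[str]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.feature_terms:
            raise ConfigError("disease model has an empty feature list")
        if self.disease_term in self.feature_terms:
            raise ConfigError(
                f"disease term {self.disease_term} cannot be its own feature"
            )
        if len(set(self.feature_terms)) != len(self.feature_terms):
            raise ConfigError("duplicate feature terms in disease model")

    def to_dict(self) -> dict:
        return {
            "disease_term": self.disease_term,
            "feature_terms": list(self.feature_terms),
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "DiseaseModel":
        return cls(payload["disease_term"], list(payload["feature_terms"]),
                   payload.get("label", ""))


def load_model_config(stream: IO[str] | str, graph: SemanticGraph | None = None) -> DiseaseModel:
    """Parse a model config stream and (optionally) validate it against a graph.

    Unknown CURIEs are reported all at once in a single :class:`ReferentialError`.
    """
    try:
        payload = yaml.safe_load(stream)
    except yaml.YAMLError as exc:
        raise ConfigError(f"unparseable model config: {exc}") from exc
    if not isinstance(payload, dict) or "disease" not in payload:
        raise ConfigError("model config must be a mapping with a 'disease' key")
    features_by_ns = payload.get("features") or {}
    if not isinstance(features_by_ns, dict):
        raise ConfigError("'features' must map namespace -> list of CURIEs")
    features: list[str] = []
    for ns in sorted(features_by_ns):
        terms = features_by_ns[ns] or []
        features.extend(str(t) for t in terms)
    model = DiseaseModel(str(payload["disease"]), features,
                         str(payload.get("label", "")))
    if graph is not None:
        unknown = [t for t in [model.disease_term, *model.feature_terms]
                   if t not in graph]
        if unknown:
            raise ReferentialError(
                f"{len(unknown)} model CURIE(s) not in graph: {', '.join(unknown)}"
            )
    return model


def load_model_file(path, graph: SemanticGraph | None = None) -> DiseaseModel:
    with open(path, "r", encoding="utf-8") as handle:
        return load_model_config(handle, graph)


def tendinopathy_model() -> DiseaseModel:
    """The packaged tendinopathy model: DOID:971 plus its 20 feature terms."""
    text = resources.files("borg.data").joinpath("tendinopathy.model").read_text()
    return load_model_config(text)


def seed_model(graph: SemanticGraph, model: DiseaseModel) -> int:
    """Wire feature terms to the disease term with opposing feature_of pairs.

    Each feature term gains ``feature -[feature_of]-> disease`` and
    ``disease -[has_feature]-> feature``; the edge's knowledge domain is the
    feature term's namespace.  Re-seeding the same model is an idempotent
    no-op.  Returns the number of new edge pairs (== number of feature terms
    on first seeding).
    """
    unknown = [t for t in [model.disease_term, *model.feature_terms] if t not in graph]
    if unknown:
        raise ReferentialError(
            f"{len(unknown)} model CURIE(s) not in graph: {', '.join(unknown)}"
        )
    added = 0
    for feature in model.feature_terms:
        ns = graph.node(feature)["namespace"]
        if graph.add_fact(feature, model.disease_term, FEATURE_OF, HAS_FEATURE,
                          knowledge_domain=ns):
            added += 1
    if added < len(model.feature_terms):
        logger.warning(
            "seed_model: %d of %d feature_of pairs already present (idempotent)",
            len(model.feature_terms) - added, len(model.feature_terms),
        )
    graph.disease_model = model
    graph.enter_model_stage(
        f"{model.disease_term} <- {len(model.feature_terms)} features ({added} new pairs)"
    )
    return added
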