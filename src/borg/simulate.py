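"""Ground-truthed synthetic fixture generation.

Everything the pipeline consumes can be generated here: mini-ontologies in
OBO 1.2 (GO / MP / HP / DOID namespaces), a gene_info-dialect catalogue for
human, mouse and rat, an orthology map, annotation tables, the disease-model
config and a paired expression matrix — together with a ``GroundTruth``
record of exactly what was planted.

The knowledge fixture keeps the real tendinopathy model as its backbone: the
20 curated feature terms (10 GO, 7 MP, 3 HP) are present with their curated
ids and names, wired to "tendinitis" (DOID:971), and a connective-tissue
disease subtree (DOID:65) supports the related-disease criterion.  Around
that backbone the generator plants candidate genes with controlled path
counts, signatures and knowledge domains:

* GO and HP routes annotate the human gene directly to a feature term or to
  a synthetic descendant (exercising query-time closure);
* MP routes always run through the mouse ortholog, mirroring how mammalian-
  phenotype annotations attach to mouse genes — every fixture therefore
  contains ortholog-mediated paths;
* decoy genes and decoy terms (attached outside the feature closure) make
  specificity testable: no planted decoy ever acquires a path.

Each planted annotation yields exactly one allowed path by construction
(synthetic descendants form single-parent chains under one feature term, and
no feature term is an ancestor of another), so expected path counts equal
planted annotation counts.

The expression fixture emulates the paired tendon design: log-normal
intensities with a per-subject baseline effect, and planted genes shifted by
log2 of the planted fold change in the diseased member of each pair.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path as FsPath
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .graph import SemanticGraph
from .io import read_annotations, read_gene2go, read_gene_info, read_orthology
from .model import DiseaseModel, load_model_file, seed_model
from .ontology import parse_obo_file

DISEASE = ("DOID:971", "tendinitis")
RELATED_DISEASE = ("DOID:65", "connective tissue disease")

#: the curated tendinopathy feature terms, by namespace
FEATURE_TERMS: dict[str, list[tuple[str, str]]] = {
    "GO": [
        ("GO:0035989", "tendon development"),
        ("GO:0030199", "collagen fibril organization"),
        ("GO:0045766", "positive regulation of angiogenesis"),
        ("GO:0060055", "angiogenesis involved in wound healing"),
        ("GO:0044346", "fibroblast apoptotic process"),
        ("GO:0030203", "glycosaminoglycan metabolic process"),
        ("GO:0006029", "proteoglycan metabolic process"),
        ("GO:0032963", "collagen metabolic process"),
        ("GO:0009100", "glycoprotein metabolic process"),
        ("GO:0030198", "extracellular matrix organization"),
    ],
    "MP": [
        ("MP:0003198", "calcified tendon"),
        ("MP:0011643", "abnormal tendon collagen fibril morphology"),
        ("MP:0005503", "tendon dysplasia"),
        ("MP:0003907", "abnormal tendon stiffness"),
        ("MP:0005601", "increased angiogenesis"),
        ("MP:0003710", "abnormal physiological neovascularization"),
        ("MP:0011475", "abnormal glycosaminoglycan level"),
    ],
    "HP": [
        ("HP:0004690", "thickened Achilles tendon"),
        ("HP:0005197", "generalized morning stiffness"),
        ("HP:0011988", "ectopic ossification in tendon tissue"),
    ],
}

_ROOTS = {
    "GO": ("GO:0008150", "biological_process"),
    "MP": ("MP:0000001", "mammalian phenotype"),
    "HP": ("HP:0000001", "all"),
    "DOID": ("DOID:4", "disease"),
}

_EVIDENCE = ("IEA", "IMP", "ISS", "ISO", "IAGP")
_TAX = {"human": 9606, "mouse": 10090, "rat": 10116}

# planting schedule: (n_paths, n_domains, implicated-in-related-disease)
_SCHEDULE = [
    (12, 3, True),   # strong
    (11, 2, True),   # strong, just over the >10 boundary
    (15, 2, True),   # strong
    (10, 3, True),   # exactly 10 paths: fails many_paths
    (11, 1, True),   # one domain: fails multi_domain
    (12, 2, False),  # not previously implicated: fails related_disease
    (2, 2, True),
    (1, 1, False),
]


@dataclass
class FixtureSpec:
    """Study-condition parameters for fixture generation."""

    seed: int = 0
    n_terms_per_ontology: int = 20  # synthetic decoy terms per namespace
    dag_branching: float = 1.3     # mean parents per decoy term
    n_genes: Mapping[str, int] = field(
        default_factory=lambda: {"human": 40, "mouse": 25, "rat": 12}
    )
    n_planted_candidates: int = 8
    planted_path_lengths: tuple[int, ...] = (2, 3, 3, 4)
    n_expression_genes: int = 1000
    n_pairs: int = 23
    n_planted_de: int = 20
    planted_fc: float = 2.5
    noise_sigma: float = 0.2
    subject_sigma: float = 0.3  # per-subject baseline spread (log2 scale)

    def validate_knowledge(self) -> None:
        n_orthologous = min(self.n_genes["human"], self.n_genes["mouse"])
        if self.n_planted_candidates > n_orthologous:
            raise ConfigError(
                f"cannot plant {self.n_planted_candidates} candidates: only "
                f"{n_orthologous} human genes have mouse orthologs"
            )
        if any(l < 2 for l in self.planted_path_lengths):
            raise ConfigError("planted path lengths must each be >= 2")
        if not (0 < self.dag_branching):
            raise ConfigError("dag_branching must be positive")

    def validate_expression(self) -> None:
        if self.n_pairs < 2:
            raise ConfigError("paired design needs n_pairs >= 2")
        if self.planted_fc == 0 or abs(self.planted_fc) < 1:
            raise ConfigError("planted_fc must be a signed ratio with |fc| >= 1")
        if self.n_planted_de > self.n_expression_genes:
            raise ConfigError("more planted DE genes than genes in the matrix")


@dataclass
class PlantedCandidate:
    symbol: str
    n_paths: int
    n_unique_paths: int
    domains: tuple[str, ...]
    related: bool
    strong: bool


@dataclass
class GroundTruth:
    """What the generator planted, for exact downstream verification."""

    planted_candidates: dict[str, PlantedCandidate] = field(default_factory=dict)
    planted_de: dict[str, float] = field(default_factory=dict)  # symbol -> signed FC

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_candidates": {
                    s: asdict(c) for s, c in sorted(self.planted_candidates.items())
                },
                "planted_de": dict(sorted(self.planted_de.items())),
            },
            indent=2,
        )


@dataclass
class FixtureBundle:
    """Paths of one generated knowledge bundle."""

    root: FsPath
    genes: FsPath
    orthology: FsPath
    ontologies: dict[str, FsPath]  # namespace -> obo path
    annotations: dict[str, FsPath]  # namespace -> tsv path (GO in gene2go dialect)
    model: FsPath
    ground_truth: FsPath


# ---------------------------------------------------------------------------
# OBO emission


def _obo_text(namespace: str, terms: Sequence[tuple[str, str, list[str]]]) -> str:
    """Render (id, name, [parent ids]) triples as a minimal OBO 1.2 document."""
    blocks = ["format-version: 1.2", f"ontology: synthetic-{namespace.lower()}", ""]
    for term_id, name, parents in terms:
        blocks.append("[Term]")
        blocks.append(f"id: {term_id}")
        blocks.append(f"name: {name}")
        for parent in parents:
            blocks.append(f"is_a: {parent}")
        blocks.append("")
    return "\n".join(blocks) + "\n"


def _synthetic_descendants(ns: str, feature_idx: int, depth: int) -> list[str]:
    """Ids of the single-parent chain hanging under feature ``feature_idx``."""
    prefix = ns + ":9" + f"{feature_idx:02d}"
    return [f"{prefix}{d}" for d in range(1, depth + 1)]


def _model_config_text() -> str:
    lines = [f"disease: {DISEASE[0]}", "label: tendinopathy", "features:"]
    for ns in ("GO", "HP", "MP"):
        ids = ", ".join(t for t, _ in FEATURE_TERMS[ns])
        lines.append(f"  {ns}: [{ids}]")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# knowledge fixture


def generate_knowledge_fixture(
    spec: FixtureSpec, out_dir
) -> tuple[FixtureBundle, GroundTruth]:
    """Emit a complete, ground-truthed knowledge bundle under ``out_dir``."""
    spec.validate_knowledge()
    rng = random.Random(spec.seed)
    out = FsPath(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # -- genes and orthology ------------------------------------------------
    symbols = {
        "human": [f"HSA{i:03d}" for i in range(1, spec.n_genes["human"] + 1)],
        "mouse": [f"Msa{i:03d}" for i in range(1, spec.n_genes["mouse"] + 1)],
        "rat": [f"Rno{i:03d}" for i in range(1, spec.n_genes["rat"] + 1)],
    }
    gene_ids = {
        "human": {s: 1000 + i for i, s in enumerate(symbols["human"])},
        "mouse": {s: 2000 + i for i, s in enumerate(symbols["mouse"])},
        "rat": {s: 3000 + i for i, s in enumerate(symbols["rat"])},
    }
    gene_lines = ["#tax_id\tGeneID\tSymbol"]
    for species in ("human", "mouse", "rat"):
        for sym in symbols[species]:
            gene_lines.append(f"{_TAX[species]}\t{gene_ids[species][sym]}\t{sym}")

    ortho_lines = []
    mouse_of: dict[str, str] = {}
    for i, hsym in enumerate(symbols["human"]):
        if i < len(symbols["mouse"]):
            msym = symbols["mouse"][i]
            mouse_of[hsym] = msym
            ortho_lines.append(
                f"human\t{gene_ids['human'][hsym]}\tmouse\t{gene_ids['mouse'][msym]}"
            )
        if i < len(symbols["rat"]):
            rsym = symbols["rat"][i]
            ortho_lines.append(
                f"human\t{gene_ids['human'][hsym]}\trat\t{gene_ids['rat'][rsym]}"
            )

    # -- planting plan ------------------------------------------------------
    orthologous = [s for s in symbols["human"] if s in mouse_of]
    planted_symbols = sorted(rng.sample(orthologous, spec.n_planted_candidates))
    ground = GroundTruth()
    # routes: (human symbol, namespace, feature_idx, depth, via_ortholog)
    routes: list[tuple[str, str, int, int, bool]] = []
    related_planted: list[str] = []
    for idx, sym in enumerate(planted_symbols):
        n_paths, n_domains, related = _SCHEDULE[idx % len(_SCHEDULE)]
        domains = ("GO", "MP", "HP")[:n_domains] if n_domains > 1 else ("GO",)
        signatures = set()
        for r in range(n_paths):
            ns = domains[r % len(domains)]
            length = spec.planted_path_lengths[r % len(spec.planted_path_lengths)]
            via_orth = ns == "MP"
            depth = max(0, length - (3 if via_orth else 2))
            feature_idx = r % len(FEATURE_TERMS[ns])
            routes.append((sym, ns, feature_idx, depth, via_orth))
            signatures.add((ns, depth, via_orth))
        if related:
            related_planted.append(sym)
        ground.planted_candidates[sym] = PlantedCandidate(
            symbol=sym,
            n_paths=n_paths,
            n_unique_paths=len(signatures),
            domains=tuple(sorted(set(domains))),
            related=related,
            strong=(n_paths > 10 and len(set(domains)) >= 2 and related),
        )

    # -- ontologies ----------------------------------------------------------
    needed_depth: dict[tuple[str, int], int] = {}
    for _, ns, fidx, depth, _ in routes:
        key = (ns, fidx)
        needed_depth[key] = max(needed_depth.get(key, 0), depth)

    obo_paths: dict[str, FsPath] = {}
    decoy_terms: dict[str, list[str]] = {}
    for ns in ("GO", "MP", "HP"):
        root_id, root_name = _ROOTS[ns]
        terms: list[tuple[str, str, list[str]]] = [(root_id, root_name, [])]
        for fidx, (fid, fname) in enumerate(FEATURE_TERMS[ns]):
            terms.append((fid, fname, [root_id]))
            chain = _synthetic_descendants(ns, fidx, needed_depth.get((ns, fidx), 0))
            parent = fid
            for d, cid in enumerate(chain, start=1):
                terms.append((cid, f"synthetic descendant {d} of {fname}", [parent]))
                parent = cid
        # layered decoy DAG outside the feature closure
        decoys: list[str] = []
        for j in range(spec.n_terms_per_ontology):
            tid = f"{ns}:8{j:03d}"
            pool = decoys[-5:] if decoys else []
            parents = [rng.choice(pool)] if pool and rng.random() < 0.6 else [root_id]
            if pool and rng.random() < (spec.dag_branching - 1.0):
                extra = rng.choice(pool)
                if extra not in parents:
                    parents.append(extra)
            terms.append((tid, f"decoy term {j} ({ns})", parents))
            decoys.append(tid)
        decoy_terms[ns] = decoys
        obo_paths[ns] = out / f"{ns.lower()}.obo"
        obo_paths[ns].write_text(_obo_text(ns, terms))

    doid_terms = [
        (_ROOTS["DOID"][0], _ROOTS["DOID"][1], []),
        (DISEASE[0], DISEASE[1], [_ROOTS["DOID"][0]]),
        ("DOID:97101", "tenosynovitis", [DISEASE[0]]),
        ("DOID:97102", "patellar tendinitis", [DISEASE[0]]),
        (RELATED_DISEASE[0], RELATED_DISEASE[1], [_ROOTS["DOID"][0]]),
        ("DOID:6501", "collagen disease", [RELATED_DISEASE[0]]),
        ("DOID:6502", "bursitis", [RELATED_DISEASE[0]]),
        ("DOID:6503", "enthesopathy", [RELATED_DISEASE[0]]),
    ]
    obo_paths["DOID"] = out / "doid.obo"
    obo_paths["DOID"].write_text(_obo_text("DOID", doid_terms))

    # -- annotations ---------------------------------------------------------
    pmid = 10000
    go_lines = ["#tax_id\tGeneID\tGO_ID\tEvidence\tQualifier\tGO_term\tPubMed\tCategory"]
    generic: dict[str, list[str]] = {"MP": [], "HP": [], "DOID": []}

    def route_target(ns: str, fidx: int, depth: int) -> str:
        if depth == 0:
            return FEATURE_TERMS[ns][fidx][0]
        return _synthetic_descendants(ns, fidx, depth)[-1]

    for i, (sym, ns, fidx, depth, via_orth) in enumerate(routes):
        term = route_target(ns, fidx, depth)
        ev = _EVIDENCE[i % len(_EVIDENCE)]
        pmid += 1
        if ns == "GO":
            go_lines.append(
                f"9606\t{gene_ids['human'][sym]}\t{term}\t{ev}\t-\t-\t{pmid}\tProcess"
            )
        elif via_orth:
            msym = mouse_of[sym]
            generic["MP"].append(
                f"mouse\t{gene_ids['mouse'][msym]}\t{term}\t{ev}\tPMID:{pmid}"
            )
        else:
            generic[ns].append(
                f"human\t{gene_ids['human'][sym]}\t{term}\t{ev}\tPMID:{pmid}"
            )

    related_subtree = ["DOID:6501", "DOID:6502", "DOID:6503", RELATED_DISEASE[0]]
    for sym in related_planted:
        pmid += 1
        term = rng.choice(related_subtree)
        generic["DOID"].append(
            f"human\t{gene_ids['human'][sym]}\t{term}\tIAGP\tPMID:{pmid}"
        )

    # decoy annotations: non-planted genes to decoy terms (no path possible)
    planted_set = set(planted_symbols)
    decoy_genes = [s for s in symbols["human"] if s not in planted_set]
    for sym in decoy_genes:
        for _ in range(rng.randint(1, 3)):
            ns = rng.choice(("GO", "MP", "HP"))
            term = rng.choice(decoy_terms[ns])
            ev = rng.choice(_EVIDENCE)
            pmid += 1
            if ns == "GO":
                go_lines.append(
                    f"9606\t{gene_ids['human'][sym]}\t{term}\t{ev}\t-\t-\t{pmid}\tProcess"
                )
            else:
                generic[ns].append(
                    f"human\t{gene_ids['human'][sym]}\t{term}\t{ev}\tPMID:{pmid}"
                )
    # a couple of decoy related-disease genes (related but pathless)
    for sym in decoy_genes[:2]:
        pmid += 1
        generic["DOID"].append(
            f"human\t{gene_ids['human'][sym]}\tDOID:6502\tIAGP\tPMID:{pmid}"
        )

    # -- write bundle ---------------------------------------------------------
    genes_path = out / "genes.tsv"
    genes_path.write_text("\n".join(gene_lines) + "\n")
    ortho_path = out / "orthology.tsv"
    ortho_path.write_text("\n".join(ortho_lines) + "\n")
    ann_paths: dict[str, FsPath] = {"GO": out / "annotations_go.tsv"}
    ann_paths["GO"].write_text("\n".join(go_lines) + "\n")
    for ns in ("MP", "HP", "DOID"):
        ann_paths[ns] = out / f"annotations_{ns.lower()}.tsv"
        ann_paths[ns].write_text("\n".join(generic[ns]) + "\n" if generic[ns] else "")
    model_path = out / "tendinopathy.model"
    model_path.write_text(_model_config_text())
    truth_path = out / "ground_truth.json"
    truth_path.write_text(ground.to_json() + "\n")

    bundle = FixtureBundle(
        root=out, genes=genes_path, orthology=ortho_path, ontologies=obo_paths,
        annotations=ann_paths, model=model_path, ground_truth=truth_path,
    )
    return bundle, ground


def build_graph(bundle: FixtureBundle) -> tuple[SemanticGraph, DiseaseModel]:
    """Load a bundle into a seeded :class:`SemanticGraph` (stepwise order)."""
    graph = SemanticGraph()
    graph.load_genes(read_gene_info(bundle.genes))
    graph.load_orthology(read_orthology(bundle.orthology))
    for ns in sorted(bundle.ontologies):
        graph.load_ontology(parse_obo_file(bundle.ontologies[ns], ns))
    for ns in sorted(bundle.annotations):
        path = bundle.annotations[ns]
        rows = read_gene2go(path) if ns == "GO" else read_annotations(path)
        graph.load_annotations(rows)
    model = load_model_file(bundle.model, graph)
    seed_model(graph, model)
    return graph, model


def worked_fixture() -> FixtureBundle:
    """The committed hand-written 30-node synthetic bundle (see its README)."""
    from importlib import resources

    root = FsPath(str(resources.files("borg.data").joinpath("worked")))
    return FixtureBundle(
        root=root,
        genes=root / "genes.tsv",
        orthology=root / "orthology.tsv",
        ontologies={ns: root / f"{ns.lower()}.obo" for ns in ("GO", "MP", "HP", "DOID")},
        annotations={
            "GO": root / "annotations_go.tsv",
            "MP": root / "annotations_mp.tsv",
            "HP": root / "annotations_hp.tsv",
            "DOID": root / "annotations_doid.tsv",
        },
        model=root / "worked.model",
        ground_truth=root / "README.txt",
    )


# ---------------------------------------------------------------------------
# expression fixture


def generate_expression_fixture(
    spec: FixtureSpec,
    out_dir,
    symbols: Sequence[str] | None = None,
    ensure_de: Sequence[str] = (),
) -> tuple[FsPath, FsPath, GroundTruth]:
    """Emit a paired expression matrix + pairing file; returns the planted set.

    ``symbols`` seeds the gene list (padded with synthetic EXPnnnn symbols up
    to ``n_expression_genes``); ``ensure_de`` forces specific symbols into
    the planted set so graph candidates can be made differentially expressed.
    """
    spec.validate_expression()
    out = FsPath(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    genes = list(symbols or [])
    genes += [f"EXP{i:04d}" for i in range(len(genes) + 1, spec.n_expression_genes + 1)]
    genes = genes[: spec.n_expression_genes]

    ensure = [g for g in ensure_de if g in genes]
    missing = [g for g in ensure_de if g not in genes]
    if missing:
        raise ConfigError(f"ensure_de symbols not in the matrix: {missing}")
    pool = [g for g in genes if g not in set(ensure)]
    n_extra = spec.n_planted_de - len(ensure)
    if n_extra < 0:
        raise ConfigError("ensure_de longer than n_planted_de")
    extra = sorted(rng.choice(len(pool), size=n_extra, replace=False).tolist())
    planted = set(ensure) | {pool[i] for i in extra}

    n_genes, n_pairs = len(genes), spec.n_pairs
    mu = rng.uniform(4.0, 12.0, size=n_genes)  # per-gene log2 baseline
    subject = rng.normal(0.0, spec.subject_sigma, size=n_pairs)
    eps_d = rng.normal(0.0, spec.noise_sigma, size=(n_genes, n_pairs))
    eps_h = rng.normal(0.0, spec.noise_sigma, size=(n_genes, n_pairs))
    delta = np.zeros(n_genes)
    sign = 1.0 if spec.planted_fc > 0 else -1.0
    shift = sign * np.log2(abs(spec.planted_fc))
    for i, g in enumerate(genes):
        if g in planted:
            delta[i] = shift
    log_d = mu[:, None] + subject[None, :] + delta[:, None] + eps_d
    log_h = mu[:, None] + subject[None, :] + eps_h

    d_cols = [f"D{p:02d}" for p in range(1, n_pairs + 1)]
    h_cols = [f"H{p:02d}" for p in range(1, n_pairs + 1)]
    frame = pd.DataFrame(
        np.hstack([2.0 ** log_d, 2.0 ** log_h]), index=genes, columns=d_cols + h_cols
    )
    frame.index.name = "gene"
    matrix_path = out / "expression.tsv"
    # full-precision floats so noiseless fixtures reproduce planted FCs exactly
    frame.to_csv(matrix_path, sep="\t", float_format="%.17g", lineterminator="\n")
    pairs_path = out / "pairs.tsv"
    pairs_path.write_text(
        "".join(f"{d}\t{h}\n" for d, h in zip(d_cols, h_cols))
    )
    truth = GroundTruth(
        planted_de={g: float(sign * abs(spec.planted_fc)) for g in sorted(planted)}
    )
    return matrix_path, pairs_path, truth
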