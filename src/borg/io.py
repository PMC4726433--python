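"""Readers for the flat-file dialects the graph is built from.

All inputs are plain tab-separated text:

* gene catalogue — NCBI ``gene_info`` dialect: ``#`` header line, columns
  ``tax_id``, ``GeneID``, ``Symbol``; ``-`` marks a missing value.
* GO annotations — ``gene2go`` dialect: ``tax_id  GeneID  GO_ID  Evidence
  Qualifier  GO_term  PubMed  Category`` (PubMed pipe-separated, ``-`` empty).
* generic annotations (non-GO ontologies) — 5 columns:
  ``species  gene_id  term_id  evidence  pmids`` (pipe-separated pmids).
* orthology — 4 columns: ``species_a  gene_a  species_b  gene_b``.
"""

from __future__ import annotations

import pandas as pd

from .errors import InputError
from .graph import DEFAULT_TAX_MAP, AnnotationRow, GeneRow


def _read_tsv(path, n_min_cols: int, comment: str = "#") -> pd.DataFrame:
    try:
        frame = pd.read_csv(
            path, sep="\t", comment=comment, header=None, dtype=str,
            keep_default_na=False,
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame()
    if len(frame) and frame.shape[1] < n_min_cols:
        raise InputError(
            f"{path}: expected at least {n_min_cols} tab-separated columns, "
            f"found {frame.shape[1]}"
        )
    return frame


def read_gene_info(path) -> list[GeneRow]:
    """Parse a gene_info-dialect catalogue into :class:`GeneRow` records."""
    frame = _read_tsv(path, 3)
    rows = []
    for tax, gid, symbol in frame.iloc[:, :3].itertuples(index=False):
        if symbol == "-" or not symbol:
            continue
        rows.append(GeneRow(int(tax), gid, symbol))
    return rows


def _split_pmids(raw: str) -> tuple[str, ...]:
    if raw in ("", "-"):
        return ()
    return tuple(p if p.startswith("PMID:") else f"PMID:{p}" for p in raw.split("|"))


def read_gene2go(path, tax_map=None) -> list[AnnotationRow]:
    """Parse gene2go-dialect GO annotations; rows from unmapped taxa are dropped."""
    tax_map = DEFAULT_TAX_MAP if tax_map is None else tax_map
    frame = _read_tsv(path, 4)
    rows = []
    for record in frame.itertuples(index=False):
        species = tax_map.get(int(record[0]))
        if species is None:
            continue
        pmids = _split_pmids(record[6]) if len(record) > 6 else ()
        rows.append(AnnotationRow(species, record[1], record[2], record[3], pmids))
    return rows


def read_annotations(path) -> list[AnnotationRow]:
    """Parse the generic 5-column annotation dialect."""
    frame = _read_tsv(path, 5)
    return [
        AnnotationRow(r[0], r[1], r[2], r[3], _split_pmids(r[4]))
        for r in frame.itertuples(index=False)
    ]


def read_orthology(path) -> list[tuple[str, str, str, str]]:
    """Parse the 4-column orthology dialect."""
    frame = _read_tsv(path, 4)
    return [tuple(r[:4]) for r in frame.itertuples(index=False)]
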