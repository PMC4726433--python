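"""Paired differential-expression stage.

Input is a gene-level expression matrix (linear-scale intensities) with
explicitly paired diseased/healthy sample columns — the design of the
tendinopathy expression study (23 surgical patients, one diseased and one
healthy tendon each).  Per gene, a two-sided paired t-test is run on the
log2 diseased-minus-healthy differences; p-values are Benjamini–Hochberg
adjusted across genes; fold change is the linear-scale ratio of means,
reported signed (+r for up-regulation, -1/r for down).  A gene is called
differentially expressed iff |FC| > 1.5 (strict) and adjusted p < 0.05.

The microarray preprocessing upstream of a gene-level matrix (CEL reading,
normalisation, probe summarisation) is out of scope; a max-variance probe
collapse utility is provided for convenience.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .prioritize import CandidateScore

logger = logging.getLogger(__name__)

FC_THRESHOLD = 1.5
ALPHA = 0.05


@dataclass
class PairedExpressionMatrix:
    """Gene x sample intensities plus the diseased/healthy pairing."""

    values: pd.DataFrame  # index: gene symbols; columns: sample ids
    pairs: list[tuple[str, str]]  # (diseased_sample_id, healthy_sample_id)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise InputError(f"duplicate gene symbols: {list(dupes)[:5]}")
        for d, h in self.pairs:
            if d == h:
                raise InputError(f"pair ({d}, {h}) references one sample twice")
            for col in (d, h):
                if col not in self.values.columns:
                    raise InputError(f"pair column {col!r} not in matrix")
        bad = (self.values <= 0) | ~np.isfinite(self.values)
        if bad.to_numpy().any():
            gene = self.values.index[bad.any(axis=1)][0]
            col = self.values.columns[bad.loc[gene]][0]
            raise InputError(
                f"non-positive or non-finite intensity at gene {gene!r}, sample {col!r}"
                " (linear positive scale required for the log transform)"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @classmethod
    def from_tsv(cls, matrix_path, pairs_path) -> "PairedExpressionMatrix":
        """Read the TSV dialect: matrix (gene column first) + 2-column pairing."""
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        pair_frame = pd.read_csv(pairs_path, sep="\t", header=None, dtype=str,
                                 comment="#")
        pairs = [tuple(r[:2]) for r in pair_frame.itertuples(index=False)]
        return cls(values, pairs)


@dataclass
class DEResult:
    gene: str
    fold_change: float  # signed linear ratio, |fc| >= 1
    p_value: float
    p_adjusted: float
    is_de: bool


def signed_fold_change(ratio: float) -> float:
    """Map a linear ratio r to the signed convention: r>=1 -> +r, r<1 -> -1/r."""
    return float(ratio) if ratio >= 1 else float(-1.0 / ratio)


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def paired_de(matrix: PairedExpressionMatrix) -> list[DEResult]:
    """Per-gene paired t-test on log2 ratios + BH + threshold rule.

    Degenerate rows whose log2 differences have zero variance get p = 1.0
    when the mean difference is zero and p = 0.0 otherwise (the t statistic
    is undefined there).
    """
    if len(matrix.pairs) < 2:
        raise InputError("paired test needs at least 2 sample pairs")
    d_cols = [d for d, _ in matrix.pairs]
    h_cols = [h for _, h in matrix.pairs]
    diseased = matrix.values[d_cols].to_numpy(dtype=float)
    healthy = matrix.values[h_cols].to_numpy(dtype=float)
    diffs = np.log2(diseased) - np.log2(healthy)

    with warnings.catch_warnings():
        # zero-variance rows trigger a precision warning; they are handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.ttest_1samp(diffs, 0.0, axis=1).pvalue
    degenerate = np.isclose(diffs.std(axis=1, ddof=1), 0.0)
    mean_diff = diffs.mean(axis=1)
    p = np.where(degenerate, np.where(np.isclose(mean_diff, 0.0), 1.0, 0.0), p)

    ratio = diseased.mean(axis=1) / healthy.mean(axis=1)
    fc = np.where(ratio >= 1, ratio, -1.0 / ratio)
    p_adj = np.asarray(bh_adjust(p))
    is_de = (np.abs(fc) > FC_THRESHOLD) & (p_adj < ALPHA)

    return [
        DEResult(g, float(fc[i]), float(p[i]), float(p_adj[i]), bool(is_de[i]))
        for i, g in enumerate(matrix.genes)
    ]


def collapse_probes(
    values: pd.DataFrame, probe_to_gene: Mapping[str, str]
) -> pd.DataFrame:
    """Collapse probe-level rows to gene level, keeping the max-variance probe."""
    mapped = values.loc[[p for p in values.index if p in probe_to_gene]].copy()
    genes = pd.Series({p: probe_to_gene[p] for p in mapped.index})
    variances = mapped.var(axis=1)
    best = variances.groupby(genes).idxmax()
    out = mapped.loc[best.values]
    out.index = best.index
    return out.sort_index()


def intersect_with_candidates(
    de: Sequence[DEResult], scores: Sequence[CandidateScore]
) -> pd.DataFrame:
    """Join DE calls with graph candidates (symbols in both, DE-positive only).

    Returns one row per gene that is differentially expressed *and* has at
    least one path to the disease, carrying the fold change, the path
    counts/domains and the prioritization flags; ``strong`` marks genes
    meeting all three criteria.
    """
    de_hits = {r.gene: r for r in de if r.is_de}
    rows = []
    for score in scores:
        hit = de_hits.get(score.gene)
        if hit is None:
            continue
        rows.append(
            {
                "symbol": score.gene,
                "fold_change": hit.fold_change,
                "p_adjusted": hit.p_adjusted,
                "n_independent_paths": score.n_independent_paths,
                "n_unique_paths": score.n_unique_paths,
                "domains": ",".join(sorted(score.domains)),
                **{c: score.passes.get(c, False) for c in
                   ("many_paths", "multi_domain", "related_disease")},
                "strong": score.strong if score.passes else False,
            }
        )
    unmatched = len(de_hits) - len(rows)
    if unmatched:
        logger.info("intersect: %d DE gene(s) without graph paths", unmatched)
    columns = [
        "symbol", "fold_change", "p_adjusted", "n_independent_paths",
        "n_unique_paths", "domains", "many_paths", "multi_domain",
        "related_disease", "strong",
    ]
    frame = pd.DataFrame(rows, columns=columns)
    return frame.sort_values("symbol", ignore_index=True)
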