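"""Coexpression inside functional neighborhoods vs the rest of the genome.

For a term with called neighborhoods, pairwise Pearson correlations among
member genes of each neighborhood (pairs never cross neighborhoods) are
compared with the correlations among same-term genes lying in no
neighborhood of that term, using a two-sided Kolmogorov–Smirnov test.
Per-term results and a pooled species-level result (all within-pairs vs all
outside-pairs across terms) are both produced.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .genome_io import AnnotationSet, ExpressionMatrix
from .neighborhood_enrichment import Neighborhood

__all__ = [
    "CoexpressionResult",
    "InsufficientGenesError",
    "pairwise_pearson",
    "ks_two_sample",
    "coexpression_test",
]


class InsufficientGenesError(ValueError):
    pass


@dataclass
class CoexpressionResult:
    term_id: str
    n_within_pairs: int
    n_outside_pairs: int
    ks_D: float
    ks_p: float
    mean_r_within: float
    mean_r_outside: float
    na: bool = False

    @classmethod
    def not_available(cls, term_id: str) -> "CoexpressionResult":
        return cls(term_id, 0, 0, math.nan, math.nan, math.nan, math.nan, na=True)


def pairwise_pearson(
    gene_ids: Sequence[str], matrix: ExpressionMatrix, min_samples: int = 3
) -> list[float]:
    """Pearson r for every unordered pair of genes present in the matrix.

    Correlations use pairwise-complete samples; genes with fewer than
    ``min_samples`` complete values and pairs where either gene has zero
    variance are dropped (with a warning).
    """
    rows = matrix.rows(gene_ids)
    if rows.shape[0] < 2:
        raise InsufficientGenesError(
            f"need >= 2 genes in the matrix, found {rows.shape[0]}"
        )
    X = rows.to_numpy(dtype=float)
    ids = list(rows.index)
    keep = np.isfinite(X).sum(axis=1) >= min_samples
    X, ids = X[keep], [g for g, k in zip(ids, keep) if k]
    if len(ids) < 2:
        raise InsufficientGenesError("fewer than 2 genes with enough complete samples")

    rs: list[float] = []
    n_dropped = 0
    if np.isfinite(X).all():
        with np.errstate(invalid="ignore"):
            C = np.corrcoef(X)
        iu = np.triu_indices(len(ids), k=1)
        for r in C[iu]:
            if np.isfinite(r):
                rs.append(float(r))
            else:
                n_dropped += 1
    else:
        for i, j in itertools.combinations(range(len(ids)), 2):
            ok = np.isfinite(X[i]) & np.isfinite(X[j])
            if ok.sum() < min_samples:
                n_dropped += 1
                continue
            xi, xj = X[i, ok], X[j, ok]
            if xi.std() == 0 or xj.std() == 0:
                n_dropped += 1
                continue
            rs.append(float(np.corrcoef(xi, xj)[0, 1]))
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} gene pairs with zero variance or too few samples",
                      stacklevel=2)
    return rs


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided two-sample KS: D = sup|ECDF_x - ECDF_y|, asymptotic p."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("KS test needs non-empty samples")
    res = stats.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return float(res.statistic), float(min(1.0, res.pvalue))


def _within_pairs_for_term(
    term: str, neighborhoods: Sequence[Neighborhood], matrix: ExpressionMatrix
) -> tuple[list[float], int]:
    rs: list[float] = []
    for n in neighborhoods:
        if n.term_id != term or len(n.member_gene_ids) < 2:
            continue
        try:
            rs.extend(pairwise_pearson(n.member_gene_ids, matrix))
        except InsufficientGenesError:
            continue
    return rs, len(rs)


def coexpression_test(
    neighborhoods: Sequence[Neighborhood],
    annotation: AnnotationSet,
    matrix: ExpressionMatrix,
    mode: str = "pooled",
    terms: Sequence[str] | None = None,
) -> list[CoexpressionResult]:
    """KS comparison of within-neighborhood vs outside pair correlations.

    mode='per_term': one result per term with called neighborhoods.
    mode='pooled': a single species-level result pooling pair correlations
    across terms (term_id='pooled') — the headline statistic.
    Terms with an empty within or outside side yield an NA result.
    """
    if mode not in ("per_term", "pooled"):
        raise ValueError("mode must be 'per_term' or 'pooled'")
    if terms is None:
        terms = sorted({n.term_id for n in neighborhoods})

    per_term: dict[str, tuple[list[float], list[float]]] = {}
    for term in terms:
        term_neigh = [n for n in neighborhoods if n.term_id == term]
        if not term_neigh:
            continue
        within, _ = _within_pairs_for_term(term, term_neigh, matrix)
        member_union: set[str] = set()
        for n in term_neigh:
            member_union |= set(n.member_gene_ids)
        outside_genes = sorted(annotation.genes_with_term(term) - member_union)
        try:
            outside = pairwise_pearson(outside_genes, matrix) if len(outside_genes) >= 2 else []
        except InsufficientGenesError:
            outside = []
        per_term[term] = (within, outside)

    def make_result(term_id: str, within: list[float], outside: list[float]) -> CoexpressionResult:
        if not within or not outside:
            return CoexpressionResult.not_available(term_id)
        D, p = ks_two_sample(within, outside)
        return CoexpressionResult(
            term_id, len(within), len(outside), D, p,
            float(np.mean(within)), float(np.mean(outside)),
        )

    if mode == "per_term":
        return [make_result(t, w, o) for t, (w, o) in sorted(per_term.items())]
    pooled_w = [r for w, _ in per_term.values() for r in w]
    pooled_o = [r for _, o in per_term.values() for r in o]
    return [make_result("pooled", pooled_w, pooled_o)]
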